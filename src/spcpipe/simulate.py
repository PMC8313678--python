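"""Synthetic shotgun-proteomics data with known ground truth.

Everything the analysis stages consume can be fabricated here: a protein
sequence database (FASTA-writable), per-group relative abundance profiles
on the simplex with planted fold-changes and group-exclusive proteins,
multinomial spectral counts, a scored target/decoy PSM table, and GMT
gene-set collections with planted enrichment. Each generator is a pure
function of its arguments and an integer seed, and the returned
:class:`GroundTruth` ledger records which proteins are differential, which
are exclusive and which sets are enriched, so every downstream stage has a
verifiable acceptance surface.

The sampling model: a sample's spectral counts are one multinomial draw of
fixed depth with per-protein probability proportional to abundance x
length. Dividing counts by length and renormalising (NSAF) therefore
recovers the abundance simplex in expectation. Every counted spectrum
yields one correct-match PSM; incorrect matches are planted on top,
assigned uniformly across target and decoy records (the target-decoy
exchangeability assumption), with scores drawn from a separate, lower
trivariate normal law.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import StudyDesign
from .genesets import GeneSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "charge",
    "accessions",
    "xcorr",
    "delta_cn",
    "zscore",
    "ppm_error",
    "n_tryptic_termini",
    "label",
]


@dataclass(frozen=True)
class Protein:
    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# protein database
# ---------------------------------------------------------------------------

def generate_protein_db(
    n_proteins: int,
    mean_length: float = 300.0,
    cv_length: float = 0.3,
    min_length: int = 7,
    seed: int = 0,
) -> list[Protein]:
    """Random protein database: unique accessions, uppercase 20-letter
    sequences, lognormal lengths (mean ``mean_length``, coefficient of
    variation ``cv_length``) floored at ``min_length``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mean_length <= 0 or cv_length < 0 or min_length < 1:
        raise ValueError("degenerate length law: lengths must be positive")
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(cv_length**2)
    mu = math.log(mean_length) - sigma2 / 2
    lengths = np.maximum(
        min_length, np.rint(rng.lognormal(mu, math.sqrt(sigma2), n_proteins))
    ).astype(int)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    width = max(5, len(str(n_proteins)))
    return [
        Protein(f"P{i + 1:0{width}d}", bytes(aa[rng.integers(0, 20, L)]).decode())
        for i, L in enumerate(lengths)
    ]


def write_fasta(db: Sequence[Protein], path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.accession, description="") for p in db]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[Protein]:
    return [Protein(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# cohort ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Simulation ledger: what was planted, so recovery can be scored.

    ``abundance`` holds one column per group, each a non-negative vector
    summing to 1. ``differential`` maps an accession to (effect_group,
    direction) for proteins whose abundance was fold-changed in one group;
    ``exclusive`` maps an accession to the only group where it is present.
    """

    design: StudyDesign
    abundance: pd.DataFrame
    lengths: pd.Series
    differential: dict[str, tuple[str, str]]
    exclusive: dict[str, str]
    enriched_sets: set[str] = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        sums = self.abundance.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("group abundance columns must sum to 1")
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        for acc, grp in self.exclusive.items():
            others = [g for g in self.abundance.columns if g != grp]
            if self.abundance.loc[acc, others].to_numpy().sum() != 0:
                raise ValueError(f"exclusive protein {acc} has mass outside {grp}")

    @property
    def accessions(self) -> pd.Index:
        return self.abundance.index

    def differential_labels(self, group_a: str, group_b: str) -> dict[str, str]:
        """Planted direction of group_b relative to group_a per accession."""
        flip = {"up": "down", "down": "up"}
        out: dict[str, str] = {}
        for acc, (grp, direction) in self.differential.items():
            if grp == group_b:
                out[acc] = direction
            elif grp == group_a:
                out[acc] = flip[direction]
        return out

    def true_set(self, group_a: str, group_b: str) -> set[str]:
        """All proteins truly differing between the two groups: planted
        fold-changes plus proteins exclusive to either group."""
        true = set(self.differential_labels(group_a, group_b))
        true |= {a for a, g in self.exclusive.items() if g in (group_a, group_b)}
        return true


def generate_cohort_truth(
    db: Sequence[Protein],
    design: StudyDesign,
    frac_differential: float = 0.10,
    fold_effect: float = 4.0,
    frac_exclusive: float = 0.02,
    effect_group: str | None = None,
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Plant fold-changes and group-exclusive proteins on a lognormal
    baseline abundance profile shared by all groups.

    ``floor(frac_differential * n)`` proteins get their abundance multiplied
    (half, rounded up) or divided (the rest) by ``fold_effect`` in
    ``effect_group`` (default: the second design group, i.e. the disease
    group). ``floor(frac_exclusive * n)`` further proteins are zeroed in all
    but one group, assigned round-robin over the groups. Every group column
    is then renormalised to the simplex; the renormalisation slightly
    perturbs non-differential proteins, mirroring the compositional nature
    of spectral counting.
    """
    for name, frac in (("frac_differential", frac_differential), ("frac_exclusive", frac_exclusive)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if frac_differential + frac_exclusive > 1:
        raise ValueError("frac_differential + frac_exclusive must be <= 1")
    if fold_effect < 1:
        raise ValueError("fold_effect must be >= 1")
    if len(db) == 0:
        raise ValueError("empty protein database")
    groups = design.group_names
    if effect_group is None:
        effect_group = groups[1] if len(groups) > 1 else groups[0]
    if effect_group not in groups:
        raise ValueError(f"effect_group {effect_group!r} not in design")

    rng = np.random.default_rng(seed)
    accs = pd.Index([p.accession for p in db], name="accession")
    lengths = pd.Series([p.length for p in db], index=accs, name="length")
    base = rng.lognormal(0.0, abundance_sigma, len(db))

    n = len(db)
    n_diff = int(frac_differential * n)
    n_excl = int(frac_exclusive * n)
    order = rng.permutation(n)
    diff_idx = order[:n_diff]
    excl_idx = order[n_diff : n_diff + n_excl]

    abund = pd.DataFrame({g: base.copy() for g in groups}, index=accs)
    differential: dict[str, tuple[str, str]] = {}
    if fold_effect > 1:
        n_up = math.ceil(n_diff / 2)
        for j, i in enumerate(diff_idx):
            acc = accs[i]
            if j < n_up:
                abund.loc[acc, effect_group] *= fold_effect
                differential[acc] = (effect_group, "up")
            else:
                abund.loc[acc, effect_group] /= fold_effect
                differential[acc] = (effect_group, "down")
    exclusive: dict[str, str] = {}
    for j, i in enumerate(excl_idx):
        acc = accs[i]
        own = groups[j % len(groups)]
        for g in groups:
            if g != own:
                abund.loc[acc, g] = 0.0
        exclusive[acc] = own

    abund = abund / abund.sum(axis=0)
    return GroundTruth(
        design=design,
        abundance=abund,
        lengths=lengths,
        differential=differential,
        exclusive=exclusive,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# spectral counts
# ---------------------------------------------------------------------------

def sample_spectral_counts(truth: GroundTruth, depth_per_sample: int, seed: int = 0) -> pd.DataFrame:
    """One multinomial draw per sample: protein probability is proportional
    to abundance x length, column sums equal ``depth_per_sample`` exactly.
    """
    if depth_per_sample < 1:
        raise ValueError("depth_per_sample must be >= 1")
    if len(truth.accessions) == 0:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(seed)
    L = truth.lengths.to_numpy(dtype=float)
    cols = {}
    for g in truth.design.group_names:
        w = truth.abundance[g].to_numpy() * L
        p = w / w.sum()
        for s in truth.design.samples_of(g):
            cols[s] = rng.multinomial(depth_per_sample, p)
    return pd.DataFrame(cols, index=truth.accessions, columns=list(truth.design.all_samples))


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class ScoreModelConfig:
    """Generative law for PSM quality scores.

    Correct and incorrect matches each draw (xcorr, delta_cn, zscore) from
    a trivariate normal; the defaults give visible but imperfect class
    separation so the discriminator has real work to do. xcorr is floored
    at 0 and delta_cn clipped to [0, 1] after drawing. Correct-match
    precursor mass errors are tight normals with a configurable outlier
    rate; incorrect matches get heavy-tailed uniform errors.
    """

    correct_mean: tuple[float, float, float] = (3.5, 0.35, 8.0)
    incorrect_mean: tuple[float, float, float] = (1.5, 0.05, 2.0)
    correct_cov: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    incorrect_cov: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    fraction_incorrect: float = 0.1
    ppm_scale: float = 1.5
    ppm_outlier_rate: float = 0.02
    ppm_outlier_scale: float = 40.0
    semi_tryptic_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fraction_incorrect", "ppm_outlier_rate", "semi_tryptic_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("correct_cov", "incorrect_cov"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(c).min() < -1e-9:
                raise ValueError(f"{name} must be positive semi-definite")


def simulate_psm_table(
    counts: pd.DataFrame,
    db_with_decoys: Sequence[Protein],
    score_model: ScoreModelConfig | None = None,
    seed: int = 0,
    decoy_prefix: str = "rev_",
    peptide_length: tuple[int, int] = (8, 20),
) -> pd.DataFrame:
    """Turn a count matrix into a scored target/decoy PSM table.

    One correct-match PSM is emitted per counted spectrum (so the number of
    correct PSMs equals the count-matrix total); on top, incorrect PSMs are
    planted so that they make up ``score_model.fraction_incorrect`` of the
    final table, each assigned uniformly to a target-or-decoy record of the
    concatenated database. Peptides are random substrings of the assigned
    record. The returned frame carries the standard PSM columns plus a
    boolean ``is_correct`` truth column (not part of the on-disk format).
    """
    cfg = score_model or ScoreModelConfig()
    accs_db = [p.accession for p in db_with_decoys]
    if not any(a.startswith(decoy_prefix) for a in accs_db):
        raise ValueError("database contains no decoy records")
    seq_of = {p.accession: p.sequence for p in db_with_decoys}
    missing = set(counts.index) - set(seq_of)
    if missing:
        raise ValueError(f"count matrix rows missing from database: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    stacked = counts.stack()
    nz = stacked[stacked > 0]
    acc_correct = np.repeat(nz.index.get_level_values(0).to_numpy(), nz.to_numpy())
    smp_correct = np.repeat(nz.index.get_level_values(1).to_numpy(), nz.to_numpy())
    n_correct = len(acc_correct)
    if cfg.fraction_incorrect >= 1:
        raise ValueError("fraction_incorrect must be < 1 when counts are present")
    n_inc = int(round(n_correct * cfg.fraction_incorrect / (1 - cfg.fraction_incorrect)))
    acc_inc = rng.choice(np.asarray(accs_db, dtype=object), n_inc)
    smp_inc = rng.choice(np.asarray(list(counts.columns), dtype=object), n_inc) if n_inc else np.array([], dtype=object)

    acc_all = np.concatenate([acc_correct, acc_inc])
    smp_all = np.concatenate([smp_correct, smp_inc])
    correct = np.concatenate([np.ones(n_correct, bool), np.zeros(n_inc, bool)])
    n = len(acc_all)

    # peptides: random substrings of the assigned record's sequence
    lo, hi = peptide_length
    codes, uniques = pd.factorize(acc_all)
    seqs = np.array([seq_of[a] for a in uniques], dtype=object)[codes]
    seq_len = np.fromiter((len(s) for s in seqs), dtype=int, count=n)
    plen = np.minimum(rng.integers(lo, hi + 1, n), seq_len)
    start = (rng.random(n) * (seq_len - plen + 1)).astype(int)
    peptides = [s[a : a + b] for s, a, b in zip(seqs, start, plen)]

    def draw_scores(mean, cov, k):
        return rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=k)

    scores = np.empty((n, 3))
    scores[:n_correct] = draw_scores(cfg.correct_mean, cfg.correct_cov, n_correct)
    scores[n_correct:] = draw_scores(cfg.incorrect_mean, cfg.incorrect_cov, n_inc)
    xcorr = np.clip(scores[:, 0], 0.0, None)
    delta_cn = np.clip(scores[:, 1], 0.0, 1.0)
    zscore = scores[:, 2]

    ppm = np.empty(n)
    ppm[:n_correct] = rng.normal(0.0, cfg.ppm_scale, n_correct)
    out_mask = rng.random(n_correct) < cfg.ppm_outlier_rate
    n_out = int(out_mask.sum())
    if n_out:
        mag = rng.uniform(5.0, cfg.ppm_outlier_scale, n_out)
        ppm[:n_correct][out_mask] = mag * rng.choice([-1.0, 1.0], n_out)
    ppm[n_correct:] = rng.uniform(-cfg.ppm_outlier_scale, cfg.ppm_outlier_scale, n_inc)

    termini = np.where(rng.random(n) < cfg.semi_tryptic_fraction, 1, 2)
    charge = rng.choice([2, 3], n, p=[0.7, 0.3])
    is_decoy = np.fromiter((a.startswith(decoy_prefix) for a in acc_all), bool, count=n)

    perm = rng.permutation(n)
    df = pd.DataFrame(
        {
            "spectrum_id": [f"{smp_all[i]}:{j}" for j, i in enumerate(perm)],
            "peptide": [peptides[i] for i in perm],
            "charge": charge[perm],
            "accessions": acc_all[perm],
            "xcorr": xcorr[perm],
            "delta_cn": delta_cn[perm],
            "zscore": zscore[perm],
            "ppm_error": ppm[perm],
            "n_tryptic_termini": termini[perm],
            "label": np.where(is_decoy[perm], "decoy", "target"),
            "is_correct": correct[perm],
        }
    )
    return df


def sample_of_spectrum(spectrum_id: str) -> str:
    """Recover the sample id encoded in a simulated spectrum id."""
    return spectrum_id.rsplit(":", 1)[0]


def write_psm_table(psms: pd.DataFrame, path) -> None:
    psms[PSM_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_psm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str, "accessions": str, "label": str})


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    truth: GroundTruth,
    n_sets: int = 20,
    set_size: int = 30,
    n_enriched: int = 3,
    enrichment_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[GeneSet], list[str]]:
    """Gene-set collection over the truth's accession universe.

    The first ``n_enriched`` sets draw ``ceil(enrichment_fraction *
    set_size)`` members from the true differential proteins (planted
    enrichment); all remaining members, and all other sets, are drawn
    uniformly from the universe without replacement. Updates
    ``truth.enriched_sets`` and returns (collection, enriched set names).
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched must be <= n_sets")
    if not 0 <= enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must be in [0, 1]")
    universe = list(truth.accessions)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    diff = sorted(truth.differential)
    n_planted = math.ceil(enrichment_fraction * set_size)
    if n_enriched > 0 and n_planted > len(diff):
        raise ValueError(
            f"enrichment_fraction*set_size = {n_planted} exceeds the "
            f"{len(diff)} available differential proteins"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_sets)))
    sets: list[GeneSet] = []
    enriched_names: list[str] = []
    for i in range(n_sets):
        name = f"SET{i + 1:0{width}d}"
        if i < n_enriched:
            members = list(rng.choice(diff, n_planted, replace=False))
            rest_pool = [a for a in universe if a not in set(members)]
            members += list(rng.choice(rest_pool, set_size - n_planted, replace=False))
            desc = "synthetic pathway (planted enrichment)"
            enriched_names.append(name)
        else:
            members = list(rng.choice(universe, set_size, replace=False))
            desc = "synthetic pathway"
        sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    truth.enriched_sets = set(enriched_names)
    return sets, enriched_names
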