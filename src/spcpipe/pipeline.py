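"""One-command orchestration of the full post-search analysis.

simulate -> identify -> quantify -> differential (both comparisons) ->
perturbation scoring -> enrichment, with a machine-readable report bundle
(per-stage counts, Venn cells, up/down calls, MDP scores, enriched sets)
and a checksummed file manifest for provenance. The master seed
deterministically derives one seed per stage, so any stage can be re-run
in isolation and a fixed (config, seed) pair reproduces every artifact
byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import differential as diff
from . import enrich as enr
from . import identify as idn
from . import perturb as per
from . import quantify as qnt
from . import simulate as sim
from .design import StudyDesign, write_design


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed.

    The defaults encode the study conditions the synthetic cohort
    emulates: a 1,000-protein database, 20,000 spectra per sample, a
    6/9/9 Control/Sepsis/Recovery design, 10% of proteins fold-changed
    4x in the Sepsis group, 2% group-exclusive proteins, and 3 of 20
    gene sets with planted enrichment.
    """

    n_proteins: int = 1000
    mean_length: float = 300.0
    depth: int = 20000
    frac_differential: float = 0.10
    fold_effect: float = 4.0
    frac_exclusive: float = 0.02
    score_model: sim.ScoreModelConfig = field(default_factory=sim.ScoreModelConfig)
    filter_cfg: idn.FilterConfig = field(default_factory=idn.FilterConfig)
    tfold: diff.TFoldConfig = field(default_factory=diff.TFoldConfig)
    mdp_fraction: float = 0.25
    n_sets: int = 20
    set_size: int = 30
    n_enriched: int = 3
    enrichment_fraction: float = 0.5
    min_replicates: int = 2
    comparisons: tuple[tuple[str, str], ...] = (("Control", "Sepsis"), ("Recovery", "Sepsis"))
    control_group: str = "Control"
    seed: int = 0


class IntegrityError(RuntimeError):
    """A bundle file does not match its recorded checksum."""


@dataclass
class ReportBundle:
    """Machine-readable run report: per-stage record counts, the Venn
    partition, up/down calls per comparison, MDP scores and the enriched
    sets, plus a checksummed manifest of every written artifact."""

    stage_counts: dict
    venn: dict
    comparisons: dict
    mdp: dict
    mdp_test: dict
    enriched: dict
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    classified: pd.DataFrame
    exclusives: pd.DataFrame
    ora: pd.DataFrame
    ora_skipped: list[str]
    selected: set[str]

    @property
    def name(self) -> str:
        return f"{self.group_b}_vs_{self.group_a}"


@dataclass
class PipelineResult:
    bundle: ReportBundle
    truth: sim.GroundTruth
    design: StudyDesign
    psms: pd.DataFrame
    counts: pd.DataFrame
    nsaf: pd.DataFrame
    partition: qnt.DetectionPartition
    groups: list[qnt.ProteinGroup]
    comparisons: dict[str, ComparisonResult]
    mdp: pd.Series
    gene_sets: list


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    design: StudyDesign | None = None,
) -> PipelineResult:
    """Execute every stage on a synthetic cohort and return results plus a
    consistency-checked report bundle; when ``outdir`` is given, write all
    intermediate artifacts and the checksummed report there."""
    cfg = config or PipelineConfig()
    design = design or StudyDesign.default()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        written[name] = path

    # --- simulate ---------------------------------------------------------
    db = sim.generate_protein_db(cfg.n_proteins, cfg.mean_length, seed=stage_seed(cfg.seed, "db"))
    full_db = idn.build_decoy_db(db, cfg.filter_cfg.decoy_prefix)
    truth = sim.generate_cohort_truth(
        db,
        design,
        frac_differential=cfg.frac_differential,
        fold_effect=cfg.fold_effect,
        frac_exclusive=cfg.frac_exclusive,
        seed=stage_seed(cfg.seed, "truth"),
    )
    counts_true = sim.sample_spectral_counts(truth, cfg.depth, seed=stage_seed(cfg.seed, "counts"))
    psms = sim.simulate_psm_table(
        counts_true,
        full_db,
        cfg.score_model,
        seed=stage_seed(cfg.seed, "psms"),
        decoy_prefix=cfg.filter_cfg.decoy_prefix,
    )
    n_enriched = cfg.n_enriched if truth.differential else 0
    gene_sets, enriched_names = sim.generate_gene_sets(
        truth,
        n_sets=cfg.n_sets,
        set_size=cfg.set_size,
        n_enriched=n_enriched,
        enrichment_fraction=cfg.enrichment_fraction,
        seed=stage_seed(cfg.seed, "sets"),
    )
    emit("database.fasta", lambda p: sim.write_fasta(full_db, p))
    emit("design.tsv", lambda p: write_design(design, p))
    emit("psms.tsv", lambda p: sim.write_psm_table(psms, p))
    emit("genesets.gmt", lambda p: enr.write_gmt(gene_sets, p))

    # --- identify ---------------------------------------------------------
    scored, _model = idn.discriminant_scores(psms)
    fdr_res = idn.fdr_filter(scored, cfg.filter_cfg.fdr_alpha)
    final, prot_counts = idn.quality_filter(fdr_res.accepted, cfg.filter_cfg)
    emit("psms_final.tsv", lambda p: sim.write_psm_table(final, p))

    # --- quantify ---------------------------------------------------------
    lengths = pd.Series({p.accession: p.length for p in db})
    pep_map = qnt.peptide_map_from_psms(final)
    groups = qnt.infer_parsimony_groups(pep_map, lengths)
    counts_obs, n_ambig = qnt.assemble_count_matrix(final, groups, design)
    leader_lengths = pd.Series({g.leader: g.leader_length for g in groups})
    nsaf = qnt.nsaf_normalize(counts_obs, leader_lengths)
    partition = qnt.detection_partition(counts_obs, design, cfg.min_replicates)
    emit("counts.tsv", lambda p: qnt.write_matrix(counts_obs, p))
    emit("nsaf.tsv", lambda p: qnt.write_matrix(nsaf, p))
    venn = {"+".join(k): sorted(v) for k, v in sorted(partition.cells.items())}
    emit(
        "venn.json",
        lambda p: p.write_text(json.dumps(venn, indent=2, sort_keys=True)),
    )

    # --- differential + enrichment per comparison -------------------------
    comparisons: dict[str, ComparisonResult] = {}
    for a, b in cfg.comparisons:
        stats = diff.tfold_stats(nsaf, counts_obs, design, a, b, cfg.tfold, cfg.min_replicates)
        classified = diff.tfold_classify(stats, cfg.tfold)
        exclusives = diff.call_exclusives(partition, a, b)
        selected = diff.selected_set(classified, exclusives)
        universe = set(stats.index) | set(exclusives.index)
        ora, skipped = enr.ora_hypergeometric(selected, universe, gene_sets)
        cr = ComparisonResult(a, b, classified, exclusives, ora, skipped, selected)
        comparisons[cr.name] = cr
        report = diff.differential_report(classified, exclusives)
        emit(
            f"differential_{cr.name}.tsv",
            lambda p, r=report: r.to_csv(p, sep="\t", float_format="%.12g"),
        )
        emit(
            f"ora_{cr.name}.tsv",
            lambda p, o=ora: o.to_csv(p, sep="\t", index=False, float_format="%.12g"),
        )

    # --- perturbation -----------------------------------------------------
    mdp = per.mdp_scores(nsaf, design, cfg.control_group, cfg.mdp_fraction)
    if design.paired_groups is not None:
        ga, gb = design.paired_groups  # e.g. Sepsis -> Recovery pairing
        a_scores = mdp[[design.pairing[s] for s in design.samples_of(ga)]].to_numpy()
        b_scores = mdp[list(design.samples_of(ga))].to_numpy()
        stat, pval = per.compare_mdp(a_scores, b_scores, paired=True)
        mdp_test = {"test": "wilcoxon-signed-rank", "groups": [ga, gb], "statistic": stat, "p": pval}
    else:
        mdp_test = {"test": "none", "groups": [], "statistic": None, "p": None}
    mdp_frame = pd.DataFrame(
        {"sample_id": mdp.index, "group": [design.group_of(s) for s in mdp.index], "mdp": mdp.values}
    )
    emit("mdp.tsv", lambda p: mdp_frame.to_csv(p, sep="\t", index=False, float_format="%.12g"))
    emit("mdp_test.json", lambda p: p.write_text(json.dumps(mdp_test, indent=2, sort_keys=True)))

    # --- clustering layout over the selected proteins ---------------------
    union_selected = sorted(set().union(*(c.selected for c in comparisons.values())) & set(nsaf.index))
    if len(union_selected) >= 2 and nsaf.shape[1] >= 2:
        layout = enr.cluster_rows_cols(nsaf.loc[union_selected], normalize_rows=True)
        emit(
            "cluster.json",
            lambda p: p.write_text(json.dumps(layout.to_dict(), indent=2)),
        )

    # --- report bundle ----------------------------------------------------
    stage_counts = {
        "psms_in": int(len(psms)),
        "psms_decoy_in": int((psms["label"] == "decoy").sum()),
        "fdr_thresholds": {str(k): v for k, v in fdr_res.thresholds.items()},
        "fdr_estimates": {str(k): v for k, v in fdr_res.fdr_estimates.items()},
        "psms_fdr_accepted": int(len(fdr_res.accepted)),
        "psms_final": int(len(final)),
        "psms_ambiguous_excluded": int(n_ambig),
        "proteins_confident": int(len(prot_counts)),
        "protein_groups": int(len(groups)),
        "detected_per_group": {g: len(partition.detected[g]) for g in design.group_names},
        "detected_total": len(partition.all_detected),
        "exclusive_total": len(partition.exclusives),
    }
    comp_summary = {}
    for name, cr in comparisons.items():
        cls_counts = cr.classified["volcano_class"].value_counts().to_dict()
        n_up = int((cr.classified["selected"] & (cr.classified["log2fc"] > 0)).sum()) + int(
            (cr.exclusives["direction"] == "up").sum()
        )
        n_down = int((cr.classified["selected"] & (cr.classified["log2fc"] < 0)).sum()) + int(
            (cr.exclusives["direction"] == "down").sum()
        )
        comp_summary[name] = {
            "n_tested": int(len(cr.classified)),
            "classes": {c: int(cls_counts.get(c, 0)) for c in diff.VOLCANO_CLASSES},
            "n_exclusive": int(len(cr.exclusives)),
            "n_selected": int(len(cr.selected)),
            "n_up": n_up,
            "n_down": n_down,
        }
    enriched_summary = {
        name: cr.ora.loc[cr.ora["q"] < cfg.tfold.q_alpha, "set_name"].tolist()
        for name, cr in comparisons.items()
    }
    bundle = ReportBundle(
        stage_counts=stage_counts,
        venn={k: len(v) for k, v in venn.items()},
        comparisons=comp_summary,
        mdp={s: float(v) for s, v in mdp.items()},
        mdp_test=mdp_test,
        enriched=enriched_summary,
    )
    _check_bundle(bundle)
    if out is not None:
        bundle.manifest = {name: _sha256(path) for name, path in sorted(written.items())}
        write_bundle(bundle, out)
    return PipelineResult(
        bundle=bundle,
        truth=truth,
        design=design,
        psms=psms,
        counts=counts_obs,
        nsaf=nsaf,
        partition=partition,
        groups=groups,
        comparisons=comparisons,
        mdp=mdp,
        gene_sets=gene_sets,
    )


def _check_bundle(bundle: ReportBundle) -> None:
    """Internal-consistency invariants of the report."""
    if sum(bundle.venn.values()) != bundle.stage_counts["detected_total"]:
        raise AssertionError("Venn cells do not sum to the detected total")
    for name, c in bundle.comparisons.items():
        if c["n_up"] + c["n_down"] != c["n_selected"]:
            raise AssertionError(f"{name}: up + down != selected")
        if sum(c["classes"].values()) != c["n_tested"]:
            raise AssertionError(f"{name}: volcano classes do not partition the tested set")


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(bundle.to_dict(), indent=2, sort_keys=True))
    return path


def read_bundle(outdir: str | Path) -> ReportBundle:
    """Load a report bundle and verify every manifest checksum."""
    out = Path(outdir)
    bundle = ReportBundle.from_dict(json.loads((out / "report.json").read_text()))
    for name, digest in bundle.manifest.items():
        path = out / name
        if not path.exists():
            raise IntegrityError(f"manifest file missing: {name}")
        if _sha256(path) != digest:
            raise IntegrityError(f"checksum mismatch for {name}")
    return bundle


# ---------------------------------------------------------------------------
# truth-based evaluation of a synthetic run
# ---------------------------------------------------------------------------

def evaluate_comparison(
    result: PipelineResult, group_a: str, group_b: str
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of the selected
    (blue + exclusive) set against the simulation's planted truth."""
    cr = result.comparisons[f"{group_b}_vs_{group_a}"]
    true = result.truth.true_set(group_a, group_b)
    found = cr.selected
    tp = len(found & true)
    sens = tp / len(true) if true else float("nan")
    fdp = (len(found) - tp) / len(found) if found else 0.0
    return {"sensitivity": sens, "fdp": fdp, "n_true": len(true), "n_found": len(found)}


def enriched_recovered(result: PipelineResult, comparison: str, q_alpha: float = 0.05) -> bool:
    """True when every planted gene set reaches q < q_alpha in the
    comparison's over-representation results."""
    planted = result.truth.enriched_sets
    if not planted:
        return True
    ora = result.comparisons[comparison].ora
    sig = set(ora.loc[ora["q"] < q_alpha, "set_name"])
    return planted <= sig
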