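"""Simulation benchmarks of the pipeline's error-control guarantees.

Each routine builds fresh synthetic data, runs the relevant stage(s) and
measures an operating characteristic against the simulation's planted
truth: the realized false-discovery proportion of the PSM filter at its
decoy-estimated 1% level, the null FDP of the differential stage at its
q-value cutoff, end-to-end recovery of planted effects, and the
separation of perturbation scores. All randomness derives from one base
seed via per-replicate stage seeds.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import differential as diff
from . import identify as idn
from . import perturb as per
from . import quantify as qnt
from . import simulate as sim
from .design import StudyDesign
from .pipeline import (
    PipelineConfig,
    enriched_recovered,
    evaluate_comparison,
    run_pipeline,
    stage_seed,
)


def _psm_benchmark_table(
    n_psms: int, fraction_incorrect: float, seed: int, n_proteins: int = 150
) -> pd.DataFrame:
    """One synthetic target/decoy PSM table of ``n_psms`` rows with known
    correct/incorrect labels, default score laws."""
    rng = np.random.default_rng(seed)
    db = sim.generate_protein_db(n_proteins, mean_length=120, seed=seed)
    full_db = idn.build_decoy_db(db)
    n_correct = int(round(n_psms * (1 - fraction_incorrect)))
    p = np.ones(n_proteins) / n_proteins
    counts = pd.DataFrame(
        {"S1": rng.multinomial(n_correct, p)}, index=[pr.accession for pr in db]
    )
    cfg = sim.ScoreModelConfig(fraction_incorrect=fraction_incorrect)
    return sim.simulate_psm_table(counts, full_db, cfg, seed=seed + 1)


def measure_psm_fdp(
    n_tables: int = 200,
    n_psms: int = 5000,
    fraction_incorrect: float = 0.5,
    alpha: float = 0.01,
    base_seed: int = 1,
) -> np.ndarray:
    """Realized false-discovery proportion of the accepted target PSMs,
    per replicate table, at the decoy-estimated FDR level ``alpha``."""
    fdps = np.empty(n_tables)
    for i in range(n_tables):
        seed = stage_seed(base_seed, f"psm-fdp-{i}")
        psms = _psm_benchmark_table(n_psms, fraction_incorrect, seed)
        scored, _ = idn.discriminant_scores(psms)
        res = idn.fdr_filter(scored, alpha)
        acc = res.accepted
        fdps[i] = 0.0 if len(acc) == 0 else float((~acc["is_correct"]).mean())
    return fdps


def _null_design() -> StudyDesign:
    return StudyDesign(
        samples={
            "Control": tuple(f"C{i}" for i in range(1, 7)),
            "Sepsis": tuple(f"S{i}" for i in range(1, 10)),
        }
    )


def measure_null_fdp(
    n_reps: int = 200,
    n_proteins: int = 1000,
    depth: int = 20000,
    base_seed: int = 1,
    cfg: diff.TFoldConfig | None = None,
) -> np.ndarray:
    """FDP of the selected (blue) differential set per replicate under a
    global null (identical group abundances, 6 vs 9 samples): 1 when any
    protein is selected, 0 when the selection is empty."""
    cfg = cfg or diff.TFoldConfig()
    design = _null_design()
    db = sim.generate_protein_db(n_proteins, seed=stage_seed(base_seed, "null-db"))
    fdps = np.empty(n_reps)
    for i in range(n_reps):
        seed = stage_seed(base_seed, f"null-{i}")
        truth = sim.generate_cohort_truth(
            db, design, frac_differential=0.0, fold_effect=1.0, frac_exclusive=0.0, seed=seed
        )
        counts = sim.sample_spectral_counts(truth, depth, seed=seed + 1)
        nsaf = qnt.nsaf_normalize(counts, truth.lengths)
        stats = diff.tfold_stats(nsaf, counts, design, "Control", "Sepsis", cfg)
        classified = diff.tfold_classify(stats, cfg)
        fdps[i] = 1.0 if classified["selected"].any() else 0.0
    return fdps


def measure_recovery(n_reps: int = 50, base_seed: int = 1) -> list[dict]:
    """Full-pipeline parameter recovery at the default study conditions:
    per replicate, the sensitivity/FDP of the selected set for the
    Sepsis-vs-Control comparison and whether every planted gene set
    reached q < 0.05 there."""
    out = []
    for i in range(n_reps):
        cfg = PipelineConfig(seed=stage_seed(base_seed, f"recovery-{i}"))
        res = run_pipeline(cfg)
        ev = evaluate_comparison(res, "Control", "Sepsis")
        ev["enriched_ok"] = enriched_recovered(res, "Sepsis_vs_Control")
        out.append(ev)
    return out


def measure_mdp_separation(
    n_reps: int = 500,
    n_proteins: int = 1000,
    depth: int = 20000,
    fold_effect: float = 4.0,
    base_seed: int = 1,
) -> np.ndarray:
    """Per replicate, 1 when the median Sepsis MDP exceeds the median
    Control (leave-one-out) self-MDP on an NSAF matrix with planted
    fold-changes, else 0."""
    design = StudyDesign.default()
    db = sim.generate_protein_db(n_proteins, seed=stage_seed(base_seed, "mdp-db"))
    hits = np.empty(n_reps)
    for i in range(n_reps):
        seed = stage_seed(base_seed, f"mdp-{i}")
        truth = sim.generate_cohort_truth(db, design, fold_effect=fold_effect, seed=seed)
        counts = sim.sample_spectral_counts(truth, depth, seed=seed + 1)
        nsaf = qnt.nsaf_normalize(counts, truth.lengths)
        scores = per.mdp_scores(nsaf, design)
        med_sepsis = scores[list(design.samples_of("Sepsis"))].median()
        med_control = scores[list(design.samples_of("Control"))].median()
        hits[i] = 1.0 if med_sepsis > med_control else 0.0
    return hits


def measure_mdp_power(
    n_reps: int = 500, n_pairs: int = 9, shift: float = 3.0, noise_sd: float = 0.5, base_seed: int = 1
) -> np.ndarray:
    """Per replicate, 1 when the paired Wilcoxon signed-rank test detects
    (p < 0.05) a strong MDP shift between n paired samples, else 0."""
    hits = np.empty(n_reps)
    for i in range(n_reps):
        rng = np.random.default_rng(stage_seed(base_seed, f"mdp-power-{i}"))
        a = rng.normal(1.0, noise_sd, n_pairs)
        b = a + shift + rng.normal(0.0, noise_sd, n_pairs)
        _, p = per.compare_mdp(a, b, paired=True)
        hits[i] = 1.0 if p < 0.05 else 0.0
    return hits
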