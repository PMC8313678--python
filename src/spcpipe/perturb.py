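"""Molecular degree of perturbation (MDP).

Each sample is summarised by how far its proteome sits from a healthy
reference: per-protein z-scores are computed against the Control group's
mean and standard deviation, and a sample's MDP is the average of its top
fraction (default 25%) of absolute z-scores. Control samples scored
alongside use leave-one-out references to avoid an optimistic zero bias.
Group scores are compared with Wilcoxon rank tests (signed-rank when
paired, rank-sum otherwise).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StudyDesign


def _control_reference(
    sub: pd.DataFrame, epsilon: float | None
) -> tuple[pd.Series, pd.Series]:
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if epsilon is None:
        pos = sd[sd > 0]
        epsilon = 1e-6 * float(pos.median()) if len(pos) else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return mu, sd.clip(lower=epsilon)


def reference_zscores(
    matrix: pd.DataFrame,
    control_samples,
    epsilon: float | None = None,
    restrict: bool = True,
    min_control_detected: int = 2,
) -> pd.DataFrame:
    """Per-protein z-scores against the control mean/SD.

    Control SDs below ``epsilon`` (default 1e-6 x the median positive
    control SD) are floored so every z is finite. With ``restrict`` (the
    default) rows are first limited to proteins quantified (non-zero) in at
    least ``min_control_detected`` control samples — z-scores of proteins
    never seen in controls are not interpretable.
    """
    controls = list(control_samples)
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples for a reference")
    sub = matrix
    if restrict:
        keep = (matrix[controls] > 0).sum(axis=1) >= min_control_detected
        sub = matrix.loc[keep]
    mu, sd = _control_reference(sub[controls], epsilon)
    return sub.sub(mu, axis=0).div(sd, axis=0)


def sample_mdp(z: pd.DataFrame, fraction: float = 0.25, signed: bool = False) -> pd.Series:
    """Per-sample MDP: mean of the top ``ceil(fraction * n)`` absolute
    z-scores (or signed z-scores with ``signed=True``)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(z)
    if n < math.ceil(1 / fraction):
        raise ValueError(f"need at least {math.ceil(1 / fraction)} proteins for fraction={fraction}")
    k = math.ceil(fraction * n)
    vals = z.to_numpy() if signed else np.abs(z.to_numpy())
    top = np.sort(vals, axis=0)[-k:, :]
    return pd.Series(top.mean(axis=0), index=z.columns, name="mdp")


def mdp_scores(
    matrix: pd.DataFrame,
    design: StudyDesign,
    control_group: str = "Control",
    fraction: float = 0.25,
    epsilon: float | None = None,
    min_control_detected: int = 2,
) -> pd.Series:
    """MDP for every sample in the design, with leave-one-out references
    for the control samples themselves: each control is z-scored against
    the remaining controls over the same protein set as everyone else."""
    controls = list(design.samples_of(control_group))
    if len(controls) < 3:
        raise ValueError("leave-one-out control scoring needs >= 3 control samples")
    keep = (matrix[controls] > 0).sum(axis=1) >= min_control_detected
    sub = matrix.loc[keep]

    z_cols: dict[str, pd.Series] = {}
    test_samples = [s for s in design.all_samples if s not in controls]
    mu, sd = _control_reference(sub[controls], epsilon)
    for s in test_samples:
        z_cols[s] = (sub[s] - mu) / sd
    for c in controls:
        rest = [x for x in controls if x != c]
        mu_c, sd_c = _control_reference(sub[rest], epsilon)
        z_cols[c] = (sub[c] - mu_c) / sd_c
    z = pd.DataFrame({s: z_cols[s] for s in design.all_samples})
    return sample_mdp(z, fraction=fraction)


def compare_mdp(scores_a, scores_b, paired: bool = True) -> tuple[float, float]:
    """Two-sided comparison of two groups of MDP scores.

    Paired mode: Wilcoxon signed-rank on (b - a) with zero differences
    dropped (p = 1 when all differences are zero). Unpaired mode:
    Mann-Whitney rank-sum. Returns (statistic, p-value).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length score vectors")
        d = b - a
        d = d[d != 0]
        if len(d) == 0:
            return 0.0, 1.0
        stat, p = sps.wilcoxon(d, alternative="two-sided")
        return float(stat), float(p)
    stat, p = sps.mannwhitneyu(b, a, alternative="two-sided")
    return float(stat), float(p)
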