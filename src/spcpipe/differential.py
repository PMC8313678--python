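"""TFold-style differential abundance on NSAF spectral counts.

For each protein detected in both groups of a comparison, the stage
computes a log2 fold change of mean NSAF (B over A), a two-sample t-test
on per-sample log2(NSAF + pseudo), Benjamini-Hochberg q-values, and a
four-way volcano classification:

    red    |log2FC| below the fold-change cutoff
    green  fold-change cutoff met, q-value cutoff missed
    orange both cutoffs met but pooled spectral counts below the
           low-abundance stringency floor
    blue   all filters met - the selected differential set

Group-exclusive proteins carry no p-value but are appended to the selected
set with a direction, since detection in only one biological condition
across replicates is itself strong evidence of differential regulation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign
from .quantify import DetectionPartition

VOLCANO_CLASSES = ("red", "green", "orange", "blue")


@dataclass(frozen=True)
class TFoldConfig:
    """q-value cutoff, |log2 fold change| cutoff, the pooled-count
    stringency floor for low-abundance proteins, and the pseudo-NSAF used
    for zeros (None: half the smallest non-zero NSAF in the tested
    submatrix). ``welch`` selects the unequal-variance t-test."""

    q_alpha: float = 0.05
    fc_cutoff: float = 1.0
    min_pooled_spc: int = 6
    pseudo_nsaf: float | None = None
    welch: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.q_alpha < 1:
            raise ValueError("q_alpha must be in (0, 1)")
        if self.fc_cutoff < 0 or self.min_pooled_spc < 0:
            raise ValueError("fc_cutoff and min_pooled_spc must be >= 0")
        if self.pseudo_nsaf is not None and self.pseudo_nsaf < 0:
            raise ValueError("pseudo_nsaf must be >= 0")


def tfold_stats(
    nsaf: pd.DataFrame,
    counts: pd.DataFrame,
    design: StudyDesign,
    group_a: str,
    group_b: str,
    cfg: TFoldConfig | None = None,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Per-protein (log2fc, p, pooled_spc) for proteins detected (non-zero
    counts in >= ``min_replicates`` samples) in BOTH groups; exclusives are
    handled separately. log2fc is group_b over group_a on mean NSAF."""
    cfg = cfg or TFoldConfig()
    sa = list(design.samples_of(group_a))
    sb = list(design.samples_of(group_b))
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples")
    det_a = (counts[sa] > 0).sum(axis=1) >= min_replicates
    det_b = (counts[sb] > 0).sum(axis=1) >= min_replicates
    idx = counts.index[det_a & det_b]
    sub = nsaf.loc[idx, sa + sb]
    pseudo = cfg.pseudo_nsaf
    if pseudo is None:
        nz = sub.to_numpy()
        nz = nz[nz > 0]
        pseudo = float(nz.min()) / 2 if len(nz) else 0.0

    A = np.log2(nsaf.loc[idx, sa].to_numpy() + pseudo)
    B = np.log2(nsaf.loc[idx, sb].to_numpy() + pseudo)
    log2fc = np.log2((nsaf.loc[idx, sb].mean(axis=1) + pseudo) / (nsaf.loc[idx, sa].mean(axis=1) + pseudo))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(B, A, axis=1, equal_var=not cfg.welch)
    p = np.asarray(p, dtype=float)
    # both groups constant: zero t-statistic when means agree, else certainty
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        equal = np.isclose(A.mean(axis=1), B.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "pooled_spc": counts.loc[idx, sa + sb].sum(axis=1).astype(int),
        },
        index=idx,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tfold_classify(stats: pd.DataFrame, cfg: TFoldConfig | None = None) -> pd.DataFrame:
    """Attach q-values and the four-way volcano class; ``selected`` marks
    the blue set."""
    cfg = cfg or TFoldConfig()
    out = stats.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    fc_ok = out["log2fc"].abs() >= cfg.fc_cutoff
    q_ok = out["q"] <= cfg.q_alpha
    spc_ok = out["pooled_spc"] >= cfg.min_pooled_spc
    cls = np.where(
        ~fc_ok, "red", np.where(~q_ok, "green", np.where(~spc_ok, "orange", "blue"))
    )
    out["volcano_class"] = cls
    out["selected"] = out["volcano_class"] == "blue"
    return out


def call_exclusives(
    partition: DetectionPartition, group_a: str, group_b: str
) -> pd.DataFrame:
    """Exclusive-detection candidates for one comparison: proteins
    exclusive to group_b are 'up' (in B), exclusive to group_a 'down'.
    No p-value or q-value is assigned."""
    rows = []
    for acc, grp in sorted(partition.exclusives.items()):
        if grp == group_b:
            rows.append({"accession": acc, "direction": "up"})
        elif grp == group_a:
            rows.append({"accession": acc, "direction": "down"})
    df = pd.DataFrame(rows, columns=["accession", "direction"]).set_index("accession")
    df["exclusive"] = True
    return df


def differential_report(classified: pd.DataFrame, exclusives: pd.DataFrame) -> pd.DataFrame:
    """Combined per-comparison table: shared (tested) proteins with their
    statistics plus exclusive candidates, one row per protein."""
    shared = classified.copy()
    shared["exclusive"] = False
    shared["direction"] = np.where(shared["log2fc"] > 0, "up", "down")
    excl = exclusives.copy()
    for col in ("log2fc", "p", "q"):
        excl[col] = np.nan
    excl["pooled_spc"] = pd.NA
    excl["volcano_class"] = "exclusive"
    excl["selected"] = True
    cols = ["log2fc", "p", "q", "pooled_spc", "volcano_class", "exclusive", "direction", "selected"]
    out = pd.concat([shared[cols], excl[cols]])
    out.index.name = "accession"
    return out


def selected_set(classified: pd.DataFrame, exclusives: pd.DataFrame) -> set[str]:
    """The combined differential call: blue proteins plus exclusives."""
    return set(classified.index[classified["selected"]]) | set(exclusives.index)
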