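"""Confident peptide-spectrum-match filtering via the target-decoy strategy.

A concatenated target+decoy (reversed-sequence) database lets the decoy hit
count estimate the false-discovery rate among accepted target PSMs. PSMs
are grouped by their number of enzymatically cleaved termini (fully tryptic
vs semi-tryptic), each subgroup gets its own discriminant model over the
(XCorr, DeltaCN, ZScore) triple, and each subgroup is thresholded
independently at the requested FDR. Three stringency rules then apply:
a precursor mass-error cut, a minimum number of independent spectra per
protein, and a score bar for single-spectrum ("one-hit wonder") proteins.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .simulate import Protein

SCORE_FEATURES = ["xcorr", "delta_cn", "zscore"]


@dataclass(frozen=True)
class FilterConfig:
    """Stringency knobs of the identification stage.

    fdr_alpha: decoy-estimated FDR ceiling per termini subgroup.
    max_ppm: accepted PSMs must have |precursor mass error| strictly below
        this many ppm.
    min_independent_ids: minimum distinct spectra supporting a protein.
    one_hit_min_xcorr: a single-spectrum protein survives only if its one
        PSM reaches this XCorr.
    """

    fdr_alpha: float = 0.01
    max_ppm: float = 5.0
    min_independent_ids: int = 2
    one_hit_min_xcorr: float = 2.0
    decoy_prefix: str = "rev_"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha <= 1:
            raise ValueError("fdr_alpha must be in (0, 1]")
        if self.max_ppm <= 0:
            raise ValueError("max_ppm must be > 0")
        if self.min_independent_ids < 1:
            raise ValueError("min_independent_ids must be >= 1")


def build_decoy_db(targets: Sequence[Protein], decoy_prefix: str = "rev_") -> list[Protein]:
    """Concatenate targets with one reversed-sequence decoy per target."""
    for p in targets:
        if p.accession.startswith(decoy_prefix):
            raise ValueError(f"accession {p.accession!r} already bears the decoy prefix")
    decoys = [Protein(decoy_prefix + p.accession, p.sequence[::-1]) for p in targets]
    return list(targets) + decoys


# ---------------------------------------------------------------------------
# discriminant
# ---------------------------------------------------------------------------

@dataclass
class _SubModel:
    mean: np.ndarray
    std: np.ndarray
    coef: np.ndarray
    intercept: float

    def score(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.std) @ self.coef + self.intercept


@dataclass
class DiscriminantModel:
    """Per-termini-subgroup two-class linear discriminant on the
    standardized (xcorr, delta_cn, zscore) triple, decoys as the negative
    class. Under shared-covariance Gaussian classes the linear discriminant
    is the Bayes rule, and its score is monotone in the posterior
    probability of a correct match."""

    submodels: dict[int, _SubModel] = field(default_factory=dict)
    pooled: _SubModel | None = None

    @classmethod
    def fit(
        cls,
        psms: pd.DataFrame,
        min_per_class: int = 20,
        allow_pooled: bool = False,
    ) -> "DiscriminantModel":
        model = cls()
        short: list[int] = []
        for g, sub in psms.groupby("n_tryptic_termini"):
            is_decoy = (sub["label"] == "decoy").to_numpy()
            n_dec, n_tgt = int(is_decoy.sum()), int((~is_decoy).sum())
            if min(n_dec, n_tgt) < min_per_class:
                short.append(int(g))
                continue
            model.submodels[int(g)] = _fit_lda(sub)
        if short:
            if not allow_pooled:
                raise ValueError(
                    f"termini subgroup(s) {short} lack {min_per_class} target and decoy "
                    "PSMs for fitting; pass allow_pooled=True to fall back to a pooled model"
                )
            model.pooled = _fit_lda(psms)
        return model

    def score(self, psms: pd.DataFrame) -> np.ndarray:
        out = np.full(len(psms), np.nan)
        grp = psms["n_tryptic_termini"].to_numpy()
        X = psms[SCORE_FEATURES].to_numpy(dtype=float)
        for g in np.unique(grp):
            sm = self.submodels.get(int(g), self.pooled)
            if sm is None:
                raise ValueError(f"no discriminant model for termini subgroup {g}")
            m = grp == g
            out[m] = sm.score(X[m])
        return out


def _fit_lda(sub: pd.DataFrame) -> _SubModel:
    X = sub[SCORE_FEATURES].to_numpy(dtype=float)
    y = (sub["label"] != "decoy").to_numpy(dtype=int)
    mean = X.mean(axis=0)
    std = np.maximum(X.std(axis=0), 1e-12)
    lda = LinearDiscriminantAnalysis()
    lda.fit((X - mean) / std, y)
    return _SubModel(mean=mean, std=std, coef=lda.coef_[0].copy(), intercept=float(lda.intercept_[0]))


def discriminant_scores(
    psms: pd.DataFrame,
    model: DiscriminantModel | None = None,
    min_per_class: int = 20,
    allow_pooled: bool = False,
) -> tuple[pd.DataFrame, DiscriminantModel]:
    """Attach a scalar ``discriminant`` column; fits a model from the table
    itself (targets vs decoys) when none is supplied."""
    if model is None:
        model = DiscriminantModel.fit(psms, min_per_class=min_per_class, allow_pooled=allow_pooled)
    scored = psms.copy()
    scored["discriminant"] = model.score(psms)
    return scored, model


# ---------------------------------------------------------------------------
# decoy-estimated FDR threshold
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    accepted: pd.DataFrame              # target PSMs only
    thresholds: dict[int, float]
    fdr_estimates: dict[int, float]
    n_targets: dict[int, int]
    n_decoys: dict[int, int]
    warning: bool = False               # some subgroup had no feasible threshold

    @property
    def fdr_estimate(self) -> float:
        t = sum(self.n_targets.values())
        d = sum(self.n_decoys.values())
        return d / t if t else 0.0


def fdr_filter(scored: pd.DataFrame, alpha: float = 0.01, score_col: str = "discriminant") -> FdrResult:
    """Largest score threshold per termini subgroup whose accepted set has
    decoy-estimated FDR (#decoys / #targets) <= alpha with maximal target
    count. Decoys are excluded from the returned accepted set; tied scores
    are accepted or rejected together."""
    if not (scored["label"] == "decoy").any():
        raise ValueError("PSM table contains no decoys; cannot estimate FDR")
    res = FdrResult(accepted=scored.iloc[0:0], thresholds={}, fdr_estimates={}, n_targets={}, n_decoys={})
    kept: list[pd.DataFrame] = []
    for g, sub in scored.groupby("n_tryptic_termini"):
        g = int(g)
        s = sub[score_col].to_numpy(dtype=float)
        dec = (sub["label"] == "decoy").to_numpy()
        order = np.argsort(-s, kind="mergesort")
        s_sorted, dec_sorted = s[order], dec[order]
        cum_d = np.cumsum(dec_sorted)
        cum_t = np.cumsum(~dec_sorted)
        # evaluate only at tie-block boundaries (accept whole tie blocks)
        boundary = np.ones(len(s_sorted), dtype=bool)
        boundary[:-1] = s_sorted[:-1] != s_sorted[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(cum_t > 0, cum_d / np.maximum(cum_t, 1), np.inf)
        feasible = np.flatnonzero(boundary & (fdr <= alpha))
        if len(feasible) == 0:
            res.thresholds[g] = np.inf
            res.fdr_estimates[g] = np.nan
            res.n_targets[g] = 0
            res.n_decoys[g] = 0
            res.warning = True
            continue
        i = feasible[-1]
        res.thresholds[g] = float(s_sorted[i])
        res.fdr_estimates[g] = float(fdr[i])
        res.n_targets[g] = int(cum_t[i])
        res.n_decoys[g] = int(cum_d[i])
        kept.append(sub[(s >= s_sorted[i]) & ~dec])
    if kept:
        res.accepted = pd.concat(kept).sort_index()
    return res


# ---------------------------------------------------------------------------
# post-FDR stringency rules
# ---------------------------------------------------------------------------

def quality_filter(
    accepted: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the mass-error and protein-support rules to FDR-accepted PSMs.

    Drops PSMs with |ppm_error| >= max_ppm; drops decoy accessions from
    mapping sets (a PSM mapping to both a target and a decoy counts as
    target); then drops proteins supported by fewer than
    ``min_independent_ids`` distinct spectra, except that a single-spectrum
    protein survives when that PSM's XCorr reaches ``one_hit_min_xcorr``.
    Returns the surviving PSMs (restricted to surviving proteins) and the
    per-protein distinct-spectrum counts.
    """
    cfg = cfg or FilterConfig()
    df = accepted[accepted["ppm_error"].abs() < cfg.max_ppm].copy()
    if df.empty:
        return df, pd.Series(dtype=int, name="n_spectra")
    multi = df["accessions"].str.contains(";").any()
    if multi:
        split = df["accessions"].str.split(";")
        split = split.map(lambda accs: [a for a in accs if not a.startswith(cfg.decoy_prefix)])
        df["accessions"] = split.map(";".join)
    else:
        df = df[~df["accessions"].str.startswith(cfg.decoy_prefix)]
    df = df[df["accessions"] != ""]
    if df.empty:
        return df, pd.Series(dtype=int, name="n_spectra")

    if multi:
        ex = df[["spectrum_id", "xcorr"]].copy()
        ex["accession"] = df["accessions"].str.split(";")
        ex = ex.explode("accession")
    else:
        ex = df[["spectrum_id", "xcorr"]].assign(accession=df["accessions"])
    per = ex.groupby("accession").agg(n=("spectrum_id", "nunique"), max_x=("xcorr", "max"))
    keep = (per["n"] >= cfg.min_independent_ids) | (
        (per["n"] == 1) & (per["max_x"] >= cfg.one_hit_min_xcorr)
    )
    surviving = set(per.index[keep])
    if multi:
        df["accessions"] = df["accessions"].map(
            lambda s: ";".join(a for a in s.split(";") if a in surviving)
        )
        df = df[df["accessions"] != ""]
    else:
        df = df[df["accessions"].isin(surviving)]
    counts = per.loc[keep, "n"].rename("n_spectra")
    return df, counts
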