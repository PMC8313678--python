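"""Target-decoy identification: decoy construction, discriminant scoring,
decoy-estimated FDR thresholding (against an exhaustive sweep oracle) and
the post-FDR stringency rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spcpipe.identify import (
    DiscriminantModel,
    FilterConfig,
    build_decoy_db,
    discriminant_scores,
    fdr_filter,
    quality_filter,
)
from spcpipe.simulate import (
    Protein,
    ScoreModelConfig,
    generate_cohort_truth,
    generate_protein_db,
    sample_spectral_counts,
    simulate_psm_table,
)


class TestDecoyDb:
    def test_reversal(self):
        out = build_decoy_db([Protein("A1", "PEPTIDE")])
        assert out[1].accession == "rev_A1"
        assert out[1].sequence == "EDITPEP"

    def test_counts_and_lengths(self, small_db):
        db50 = small_db[:50]
        out = build_decoy_db(db50)
        assert len(out) == 100
        assert sum(p.accession.startswith("rev_") for p in out) == 50
        for t, d in zip(out[:50], out[50:]):
            assert d.length == t.length

    def test_prefix_collision(self):
        with pytest.raises(ValueError, match="prefix"):
            build_decoy_db([Protein("rev_X", "AAAA")])


def _psm_table(design, db, depth, score_cfg, seed):
    truth = generate_cohort_truth(db, design, seed=seed)
    counts = sample_spectral_counts(truth, depth, seed=seed + 1)
    return simulate_psm_table(counts, build_decoy_db(db), score_cfg, seed=seed + 2)


class TestDiscriminant:
    def test_separated_laws_rank_perfectly(self, two_group_design, small_db):
        cfg = ScoreModelConfig(incorrect_mean=(0.0, 0.0, -50.0), fraction_incorrect=0.4)
        psms = _psm_table(two_group_design, small_db, 500, cfg, 30)
        scored, _ = discriminant_scores(psms)
        lo = scored.loc[scored["is_correct"], "discriminant"].min()
        hi = scored.loc[~scored["is_correct"], "discriminant"].max()
        assert lo > hi

    def test_identical_laws_auc_near_half(self, two_group_design, small_db):
        """When targets and decoys share one score law the discriminant
        carries no information: AUC against the truth labels ~ 0.5."""
        cfg = ScoreModelConfig(incorrect_mean=(3.5, 0.35, 8.0), fraction_incorrect=0.5)
        psms = _psm_table(two_group_design, small_db, 3500, cfg, 31)
        assert len(psms) >= 10_000
        scored, _ = discriminant_scores(psms)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(psms["is_correct"], scored["discriminant"])
        assert abs(auc - 0.5) < 0.03

    def test_fixed_model_scoring_is_deterministic(self, two_group_design, small_db):
        psms = _psm_table(
            two_group_design, small_db, 1500, ScoreModelConfig(fraction_incorrect=0.3), 32
        )
        model = DiscriminantModel.fit(psms)
        s1 = model.score(psms)
        s2 = model.score(psms)
        np.testing.assert_array_equal(s1, s2)

    def test_sparse_subgroup_raises_without_fallback(self):
        rng = np.random.default_rng(0)
        n = 100
        psms = pd.DataFrame(
            {
                "xcorr": rng.normal(3, 1, n).clip(0),
                "delta_cn": rng.random(n),
                "zscore": rng.normal(5, 2, n),
                "n_tryptic_termini": [1] * 5 + [2] * (n - 5),
                "label": ["target"] * (n - 20) + ["decoy"] * 20,
            }
        )
        with pytest.raises(ValueError, match="subgroup"):
            DiscriminantModel.fit(psms)
        model = DiscriminantModel.fit(psms, allow_pooled=True)
        assert np.isfinite(model.score(psms)).all()


def _scored_frame(scores, labels, termini=None):
    return pd.DataFrame(
        {
            "discriminant": scores,
            "label": labels,
            "n_tryptic_termini": termini if termini is not None else [2] * len(scores),
            "spectrum_id": [f"s:{i}" for i in range(len(scores))],
        }
    )


def _sweep_oracle(scores, is_decoy, alpha):
    """Exhaustive sweep over every observed score: largest target count
    whose accepted block has #decoys/#targets <= alpha."""
    best = None
    for t in np.unique(scores):
        acc = scores >= t
        n_t = int((acc & ~is_decoy).sum())
        n_d = int((acc & is_decoy).sum())
        if n_t > 0 and n_d / n_t <= alpha:
            if best is None or n_t > best[0]:
                best = (n_t, t, n_d)
    return best


class TestFdrFilter:
    def test_hand_estimate(self):
        # 1000 targets above the cut with 8 decoys among them -> 0.008
        scores = np.concatenate([np.linspace(10, 5, 1000), np.full(8, 7.0), np.full(300, 1.0)])
        labels = ["target"] * 1000 + ["decoy"] * 308
        res = fdr_filter(_scored_frame(scores, labels), alpha=0.01)
        assert res.fdr_estimate == pytest.approx(0.008)
        assert len(res.accepted) == 1000

    def test_vacuous_alpha_accepts_all_targets(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=500)
        labels = np.where(rng.random(500) < 0.3, "decoy", "target")
        res = fdr_filter(_scored_frame(scores, labels), alpha=1.0)
        assert len(res.accepted) == int((labels == "target").sum())

    def test_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for rep in range(20):
            n = int(rng.integers(200, 5000))
            is_decoy = rng.random(n) < 0.4
            scores = np.where(is_decoy, rng.normal(0, 1, n), rng.normal(1.5, 1, n))
            labels = np.where(is_decoy, "decoy", "target")
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            res = fdr_filter(_scored_frame(scores, labels), alpha=alpha)
            oracle = _sweep_oracle(scores, is_decoy, alpha)
            if oracle is None:
                assert res.warning and len(res.accepted) == 0
            else:
                assert len(res.accepted) == oracle[0]
                assert res.thresholds[2] == pytest.approx(oracle[1])

    def test_infeasible_alpha_warns_not_raises(self):
        # decoys outrank every target: no cutoff reaches 1% estimated FDR
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        labels = ["decoy", "decoy", "target", "target"]
        res = fdr_filter(_scored_frame(scores, labels), alpha=0.01)
        assert res.warning and len(res.accepted) == 0

    def test_no_decoys_rejected(self):
        with pytest.raises(ValueError, match="decoy"):
            fdr_filter(_scored_frame(np.ones(5), ["target"] * 5), alpha=0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_alpha_monotonicity(self, seed):
        """Raising alpha never shrinks the accepted set."""
        rng = np.random.default_rng(seed)
        n = 300
        is_decoy = rng.random(n) < 0.5
        scores = np.where(is_decoy, rng.normal(0, 1, n), rng.normal(1, 1, n))
        frame = _scored_frame(scores, np.where(is_decoy, "decoy", "target"))
        sizes = [len(fdr_filter(frame, alpha=a).accepted) for a in (0.01, 0.05, 0.2, 1.0)]
        assert sizes == sorted(sizes)

    def test_no_decoy_in_accepted_set(self, two_group_design, small_db):
        psms = _psm_table(two_group_design, small_db, 600, ScoreModelConfig(fraction_incorrect=0.4), 33)
        scored, _ = discriminant_scores(psms)
        res = fdr_filter(scored, alpha=0.05)
        assert not (res.accepted["label"] == "decoy").any()


def _quality_frame(rows):
    return pd.DataFrame(
        rows, columns=["spectrum_id", "peptide", "accessions", "xcorr", "ppm_error"]
    )


class TestQualityFilter:
    def test_ppm_rule(self):
        df = _quality_frame(
            [("s1", "PEP", "A", 3.0, 6.0), ("s2", "PEP", "A", 3.0, 4.0), ("s3", "QQQ", "A", 3.0, -4.9)]
        )
        out, counts = quality_filter(df)
        assert list(out["spectrum_id"]) == ["s2", "s3"]
        assert counts["A"] == 2

    @pytest.mark.parametrize("xcorr,kept", [(1.9, False), (2.1, True)])
    def test_one_hit_wonder_rule(self, xcorr, kept):
        df = _quality_frame(
            [("s1", "PEP", "A", xcorr, 1.0), ("s2", "X", "B", 0.5, 1.0), ("s3", "Y", "B", 0.5, 1.0)]
        )
        out, counts = quality_filter(df)
        assert ("A" in set(counts.index)) is kept
        # two independent spectra keep a protein at any score
        assert counts["B"] == 2

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        df = _quality_frame(
            [
                (f"s{i}", f"pep{i % 7}", f"P{i % 11}", float(rng.uniform(0, 5)), float(rng.normal(0, 3)))
                for i in range(60)
            ]
        )
        once, c1 = quality_filter(df)
        twice, c2 = quality_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_series_equal(c1, c2)

    def test_mixed_target_decoy_mapping_counts_as_target(self):
        df = _quality_frame(
            [("s1", "PEP", "A;rev_B", 3.0, 1.0), ("s2", "QEP", "A", 3.0, 1.0)]
        )
        out, counts = quality_filter(df)
        assert list(counts.index) == ["A"]
        assert not out["accessions"].str.contains("rev_").any()


def test_estimated_fdr_tracks_realized_fdp(two_group_design, small_db):
    """The core target-decoy assumption: on tables with known labels the
    decoy estimate and the realized FDP of the accepted set agree to
    Monte-Carlo accuracy."""
    ests, fdps = [], []
    for rep in range(20):
        psms = _psm_table(
            two_group_design, small_db, 800, ScoreModelConfig(fraction_incorrect=0.5), 40 + rep
        )
        scored, _ = discriminant_scores(psms)
        res = fdr_filter(scored, alpha=0.05)
        ests.append(res.fdr_estimate)
        fdps.append(float((~res.accepted["is_correct"]).mean()))
    assert abs(np.mean(fdps) - np.mean(ests)) < 0.02
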