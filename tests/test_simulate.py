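"""The synthetic-data generators: construction invariants, determinism,
and agreement of the multinomial counting model with its closed form."""
import numpy as np
import pandas as pd
import pytest

from spcpipe.design import StudyDesign
from spcpipe.genesets import read_gmt, write_gmt
from spcpipe.identify import build_decoy_db
from spcpipe.simulate import (
    AMINO_ACIDS,
    ScoreModelConfig,
    generate_cohort_truth,
    generate_gene_sets,
    generate_protein_db,
    sample_spectral_counts,
    simulate_psm_table,
    write_fasta,
)


class TestProteinDb:
    def test_construction(self):
        db = generate_protein_db(100, mean_length=300, seed=1)
        assert len(db) == 100
        assert len({p.accession for p in db}) == 100
        assert all(p.length >= 7 for p in db)
        assert all(set(p.sequence) <= set(AMINO_ACIDS) for p in db)

    @pytest.mark.parametrize(
        "kwargs", [{"n_proteins": 0}, {"n_proteins": 10, "mean_length": -5}]
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_protein_db(**kwargs)

    def test_fasta_determinism(self, tmp_path):
        for name in ("a.fasta", "b.fasta"):
            write_fasta(generate_protein_db(30, seed=7), tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


class TestCohortTruth:
    def test_differential_count_and_split(self, design):
        db = generate_protein_db(200, seed=2)
        truth = generate_cohort_truth(db, design, frac_differential=0.2, fold_effect=4.0, seed=3)
        assert len(truth.differential) == 40  # floor(0.2 * 200)
        dirs = pd.Series([d for _, d in truth.differential.values()])
        assert (dirs == "up").sum() == 20 and (dirs == "down").sum() == 20

    def test_unit_fold_plants_nothing(self, design, small_db):
        truth = generate_cohort_truth(small_db, design, frac_differential=0.2, fold_effect=1.0, seed=3)
        assert truth.differential == {}

    def test_exclusives_are_zero_elsewhere(self, design):
        db = generate_protein_db(200, seed=2)
        truth = generate_cohort_truth(db, design, frac_exclusive=0.05, seed=4)
        assert len(truth.exclusive) == 10
        for acc, grp in truth.exclusive.items():
            others = [g for g in design.group_names if g != grp]
            assert truth.abundance.loc[acc, others].sum() == 0
            assert truth.abundance.loc[acc, grp] > 0

    def test_simplex_conservation(self, design, small_db):
        truth = generate_cohort_truth(
            small_db, design, frac_differential=0.3, fold_effect=8.0, frac_exclusive=0.1, seed=5
        )
        assert np.allclose(truth.abundance.sum(axis=0), 1.0, atol=1e-9)
        assert (truth.abundance.values >= 0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_differential": 1.2},
            {"frac_differential": 0.7, "frac_exclusive": 0.5},
            {"fold_effect": 0.5},
        ],
    )
    def test_invalid_fractions(self, design, small_db, kwargs):
        with pytest.raises(ValueError):
            generate_cohort_truth(small_db, design, **kwargs)


class TestSpectralCounts:
    def test_column_sums_equal_depth(self, design, small_db):
        truth = generate_cohort_truth(small_db, design, seed=1)
        counts = sample_spectral_counts(truth, depth_per_sample=10000, seed=2)
        assert (counts.sum(axis=0) == 10000).all()
        assert list(counts.columns) == list(design.all_samples)

    def test_zero_abundance_gives_zero_counts(self, design):
        db = generate_protein_db(100, seed=6)
        truth = generate_cohort_truth(db, design, frac_exclusive=0.1, seed=6)
        counts = sample_spectral_counts(truth, 5000, seed=7)
        for acc, grp in truth.exclusive.items():
            other_samples = [
                s for g in design.group_names if g != grp for s in design.samples_of(g)
            ]
            assert counts.loc[acc, other_samples].sum() == 0

    def test_multinomial_mean_matches_closed_form(self):
        """Monte-Carlo mean count per protein agrees with the closed-form
        multinomial expectation depth * a_i L_i / sum_j a_j L_j."""
        design = StudyDesign(samples={"G": ("s1",)})
        db = generate_protein_db(20, mean_length=100, seed=8)
        truth = generate_cohort_truth(db, design, frac_differential=0.0, seed=8)
        depth, reps = 2000, 500
        w = truth.abundance["G"].to_numpy() * truth.lengths.to_numpy()
        p = w / w.sum()
        acc = np.zeros(len(db))
        for r in range(reps):
            acc += sample_spectral_counts(truth, depth, seed=100 + r)["s1"].to_numpy()
        mean = acc / reps
        se = np.sqrt(depth * p * (1 - p) / reps)
        assert (np.abs(mean - depth * p) <= 3.5 * se + 1e-9).all()

    def test_invalid_depth(self, design, small_db):
        truth = generate_cohort_truth(small_db, design, seed=1)
        with pytest.raises(ValueError):
            sample_spectral_counts(truth, 0, seed=1)


def _tiny_counts(db, design, depth, seed):
    truth = generate_cohort_truth(db, design, seed=seed)
    return truth, sample_spectral_counts(truth, depth, seed=seed + 1)


class TestPsmTable:
    def test_correct_psm_conservation(self, two_group_design, small_db):
        _, counts = _tiny_counts(small_db, two_group_design, 500, 10)
        psms = simulate_psm_table(counts, build_decoy_db(small_db), seed=11)
        assert int(psms["is_correct"].sum()) == int(counts.to_numpy().sum())

    def test_fully_separated_laws_are_sortable(self, two_group_design, small_db):
        """With incorrect-match scores far below correct ones, ranking by
        zscore alone puts every correct PSM above every incorrect one."""
        cfg = ScoreModelConfig(incorrect_mean=(0.0, 0.0, -1000.0), fraction_incorrect=0.3)
        _, counts = _tiny_counts(small_db, two_group_design, 400, 12)
        psms = simulate_psm_table(counts, build_decoy_db(small_db), cfg, seed=13)
        assert psms.loc[psms["is_correct"], "zscore"].min() > psms.loc[~psms["is_correct"], "zscore"].max()

    def test_ppm_outlier_rate(self, two_group_design, small_db):
        rate = 0.05
        cfg = ScoreModelConfig(ppm_outlier_rate=rate, fraction_incorrect=0.0)
        _, counts = _tiny_counts(small_db, two_group_design, 3000, 14)
        psms = simulate_psm_table(counts, build_decoy_db(small_db), cfg, seed=15)
        n = len(psms)
        assert n >= 10_000
        frac = (psms["ppm_error"].abs() > 5).mean()
        tol = 4 * np.sqrt(rate * (1 - rate) / n) + 0.001  # MC error + normal-tail leak
        assert abs(frac - rate) < tol

    def test_record_ranges_and_labels(self, two_group_design, small_db):
        _, counts = _tiny_counts(small_db, two_group_design, 300, 16)
        psms = simulate_psm_table(counts, build_decoy_db(small_db), seed=17)
        assert psms["xcorr"].min() >= 0
        assert psms["delta_cn"].between(0, 1).all()
        assert set(psms["n_tryptic_termini"]) <= {1, 2}
        decoy_rows = psms["accessions"].str.startswith("rev_")
        assert (psms["label"] == "decoy").equals(decoy_rows)
        assert not psms.loc[psms["is_correct"], "label"].eq("decoy").any()

    def test_requires_decoys(self, two_group_design, small_db):
        _, counts = _tiny_counts(small_db, two_group_design, 100, 18)
        with pytest.raises(ValueError, match="decoy"):
            simulate_psm_table(counts, small_db, seed=19)

    def test_determinism(self, two_group_design, small_db):
        _, counts = _tiny_counts(small_db, two_group_design, 200, 20)
        a = simulate_psm_table(counts, build_decoy_db(small_db), seed=21)
        b = simulate_psm_table(counts, build_decoy_db(small_db), seed=21)
        pd.testing.assert_frame_equal(a, b)


class TestGeneSets:
    def _truth(self, design):
        db = generate_protein_db(300, seed=22)
        return generate_cohort_truth(db, design, frac_differential=0.2, seed=22)

    def test_planted_sets_contain_differential_members(self, design):
        truth = self._truth(design)
        sets, enriched = generate_gene_sets(
            truth, n_sets=20, set_size=30, n_enriched=3, enrichment_fraction=0.5, seed=23
        )
        assert len(sets) == 20 and len(enriched) == 3
        diff = set(truth.differential)
        by_name = {s.name: s for s in sets}
        for name in enriched:
            assert len(by_name[name].members & diff) >= 15
        assert truth.enriched_sets == set(enriched)

    def test_no_enrichment_mode(self, design):
        truth = self._truth(design)
        sets, enriched = generate_gene_sets(truth, n_sets=10, n_enriched=0, seed=24)
        assert enriched == [] and len(sets) == 10

    def test_gmt_round_trip(self, design, tmp_path):
        truth = self._truth(design)
        sets, _ = generate_gene_sets(truth, n_sets=8, n_enriched=2, seed=25)
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [s.name for s in back] == [s.name for s in sets]
        assert [s.members for s in back] == [s.members for s in sets]

    def test_impossible_enrichment_rejected(self, design):
        truth = self._truth(design)  # 60 differential proteins
        with pytest.raises(ValueError, match="differential"):
            generate_gene_sets(truth, n_sets=5, set_size=200, n_enriched=1, enrichment_fraction=0.5)
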