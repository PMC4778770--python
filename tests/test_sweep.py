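import numpy as np
import pytest

from commnull.generate import generate_traits
from commnull.matrix import TraitVector
from commnull.sweep import (GridSpec, binomial_interval, export_grid, null_breadth,
                            run_grid, run_type1_cell, run_type2_cell,
                            ses_correlation, summaries_frame, trait_abundance_chisq)

TINY = dict(replicates=6, n_randomizations=40, n_swaps=200,
            cscore_iterations=30, trait_iterations=40)


class TestGridSpec:
    def test_levels_below_three_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(species_levels=(2,), site_levels=(5,))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(models=("cooc", "phylo"))

    def test_full_study_grid_dimensions(self):
        spec = GridSpec.full_study("type1")
        assert len(spec.species_levels) == 22
        assert len(spec.site_levels) == 21
        assert spec.replicates == 10_000
        assert spec.n_randomizations == 5_000
        assert spec.n_swaps == 30_000


class TestType1Cell:
    def test_counts_reconcile(self):
        spec = GridSpec(species_levels=(5,), site_levels=(6,),
                        models=("cooc", "aits_nn"), **TINY)
        summaries, records = run_type1_cell(5, 6, spec, rng=np.random.default_rng(0))
        assert len(summaries) == 2 * 3  # models x criteria
        for s in summaries:
            assert 0.0 <= s.rejection_proportion <= 1.0
            assert s.rejections == round(s.rejection_proportion * s.replicates)
            assert s.replicates == spec.replicates
        assert len(records) == 2 * spec.replicates

    def test_alpha_one_rejects_everything_inclusive(self):
        spec = GridSpec(species_levels=(4,), site_levels=(5,), models=("cooc",),
                        alpha=1.0, **TINY)
        summaries, _ = run_type1_cell(4, 5, spec, rng=np.random.default_rng(1))
        inclusive = [s for s in summaries if s.criterion == "inclusive"][0]
        assert inclusive.rejection_proportion == 1.0

    def test_models_share_matrices_for_pairing(self):
        spec = GridSpec(species_levels=(5,), site_levels=(6,),
                        models=("cooc", "aits_nn", "aits_sdnn"), **TINY)
        _, records = run_type1_cell(5, 6, spec, rng=np.random.default_rng(2))
        # paired design: one record per model per replicate
        assert records.groupby("replicate").size().eq(3).all()


class TestType2Cell:
    def test_cooc_detection_fields(self):
        spec = GridSpec(species_levels=(5,), site_levels=(6,), models=("cooc",), **TINY)
        summaries, records = run_type2_cell(5, 6, spec, "cooc",
                                            rng=np.random.default_rng(3))
        assert {s.criterion for s in summaries} == {"inclusive", "exclusive", "ses"}
        assert (records["improvements"] >= 0).all()

    def test_trait_path_runs_screen_and_maximization(self):
        spec = GridSpec(species_levels=(5,), site_levels=(6,),
                        models=("aits_nn",), **TINY)
        summaries, records = run_type2_cell(5, 6, spec, "aits_nn",
                                            rng=np.random.default_rng(4))
        assert len(records) == spec.replicates
        assert all(0.0 <= s.rejection_proportion <= 1.0 for s in summaries)


class TestRunGrid:
    def test_row_count_and_byte_exact_reproducibility(self, tmp_path):
        spec = GridSpec(species_levels=(4, 5), site_levels=(5,), models=("cooc",),
                        **TINY)
        frames = []
        for run in range(2):
            summary, _ = run_grid(spec, kind="type1", seed=123)
            path = tmp_path / f"run{run}.tsv"
            export_grid(summary, path)
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]
        assert len(summary) == 2 * 1 * 1 * 3  # cells x models x criteria

    def test_type2_grid(self):
        spec = GridSpec(species_levels=(4,), site_levels=(5,), models=("cooc",),
                        **TINY)
        summary, records = run_grid(spec, kind="type2", seed=9)
        assert len(summary) == 3
        assert not records.empty

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_grid([], tmp_path / "x.tsv")


class TestDiagnostics:
    def test_chisq_identity_is_zero(self):
        traits = TraitVector(np.array([1.0, 2.0, 3.0]))
        chi2, df = trait_abundance_chisq(traits, traits, np.array([4, 2, 1]))
        assert chi2 == 0.0 and df == 2

    def test_chisq_hand_example(self):
        # occurrences (4,2,1); swapping the first two traits:
        # (2-4)^2/4 + (4-2)^2/2 + 0 = 3
        before = TraitVector(np.array([10.0, 20.0, 30.0]))
        after = TraitVector(np.array([20.0, 10.0, 30.0]))
        chi2, df = trait_abundance_chisq(before, after, np.array([4, 2, 1]))
        assert chi2 == pytest.approx(3.0)
        assert df == 2

    def test_chisq_demands_same_multiset(self):
        before = TraitVector(np.array([1.0, 2.0]))
        after = TraitVector(np.array([1.0, 3.0]))
        with pytest.raises(ValueError):
            trait_abundance_chisq(before, after, np.array([1, 1]))

    def test_awts_chisq_reflects_trait_abundance_structure(self, rng):
        """The abundance-weighted shuffle maintains trait abundance (chi-square
        below the df critical value) when the community's traits really are
        clustered by abundance, and degrades it when they are not - the
        mechanism behind its false positives on unstructured communities."""
        from scipy import stats as st

        from commnull.traits import awts_shuffle

        m = 20
        occurrences = rng.integers(1, 8, m)
        values = generate_traits(m, rng).values
        critical = st.chi2.ppf(0.95, m - 1)

        aligned = np.empty(m)
        aligned[np.argsort(-occurrences, kind="stable")] = np.sort(values)[::-1]

        medians = {}
        for label, traits in (("aligned", TraitVector(aligned)),
                              ("random", TraitVector(values))):
            chis = [trait_abundance_chisq(
                traits, awts_shuffle(traits, occurrences, rng), occurrences)[0]
                for _ in range(100)]
            medians[label] = float(np.median(chis))
        assert medians["aligned"] < critical
        assert medians["random"] > medians["aligned"]

    def test_pearson_hand_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, p = ses_correlation(x, y)
        # closed-form Pearson r computed by hand from sums
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert r == pytest.approx(expected)
        assert 0.0 <= p <= 1.0

    def test_identical_series_r_one(self):
        x = np.array([0.3, -1.2, 0.8, 2.0])
        r, _ = ses_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_outliers_removed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 25.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, -30.0])
        r, _ = ses_correlation(x, y)
        assert r == pytest.approx(1.0)  # the |SES| >= 20 pair is dropped

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ses_correlation([1.0, 2.0], [1.0, 2.0])

    def test_null_breadth_grouping(self):
        spec = GridSpec(species_levels=(4,), site_levels=(5,), models=("cooc",),
                        **TINY)
        _, records = run_type1_cell(4, 5, spec, rng=np.random.default_rng(5))
        breadth = null_breadth(records)
        assert set(breadth.columns) == {"species", "sites", "model", "mean_null_sd"}
        assert (breadth["mean_null_sd"] >= 0).all()


def test_binomial_interval_limits():
    lo, hi = binomial_interval(0, 100)
    assert lo == 0.0 and 0 < hi < 0.05
    lo, hi = binomial_interval(100, 100)
    assert hi == 1.0 and lo > 0.95
    lo, hi = binomial_interval(10, 100)
    assert lo < 0.1 < hi
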