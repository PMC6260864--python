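import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from reversig import de
from reversig.datatypes import ContrastSpec, CountMatrix, DdctTable, SampleDesign, ValidationError
from reversig.simulate import SimulationConfig, generate_factorial_counts


def _matrix(values, genes=None, samples=None, scale="raw"):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                    columns=samples), scale=scale)


def bh_oracle(pvalues):
    """Brute-force step-up: padj_i = min(1, min over ranks >= rank_i of p*m/rank)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        tail = [p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]]
        out[i] = min(1.0, min(tail))
    return out


# ---------------------------------------------------------------------------
# size factors & normalization
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = _matrix(np.tile([[10], [20], [30]], (1, 2)))
        np.testing.assert_allclose(de.estimate_size_factors(cm), [1.0, 1.0])

    def test_exact_doubling_gives_sqrt2_factors(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 500, size=100)
        cm = _matrix(np.column_stack([a, 2 * a]))
        sf = de.estimate_size_factors(cm)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_all_zero_gene_excluded_from_reference(self):
        rng = np.random.default_rng(1)
        a = rng.integers(5, 500, size=(50, 3))
        sf = de.estimate_size_factors(_matrix(a))
        with_zero = np.vstack([a, np.zeros((1, 3), dtype=int)])
        sf2 = de.estimate_size_factors(_matrix(with_zero))
        np.testing.assert_allclose(sf, sf2)

    def test_no_zero_free_gene_instructs_fallback(self):
        cm = _matrix([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="pseudo_reference"):
            de.estimate_size_factors(cm)
        sf = de.estimate_size_factors(cm, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestNormalize:
    def test_unit_factors_identity(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        norm = de.normalize(small_counts, sf)
        np.testing.assert_array_equal(norm.data.to_numpy(), small_counts.data.to_numpy())
        assert norm.scale == "normalized"

    def test_doubling_counts_and_factor_is_invariant(self, small_counts):
        sf = de.estimate_size_factors(small_counts)
        norm = de.normalize(small_counts, sf)
        scaled = small_counts.data.copy()
        first = scaled.columns[0]
        scaled[first] = scaled[first] * 2
        sf2 = sf.copy()
        sf2[first] = sf2[first] * 2
        norm2 = de.normalize(CountMatrix(scaled), sf2)
        np.testing.assert_allclose(norm2.data[first], norm.data[first])

    def test_normalized_column_means_agree_under_equal_expression(self):
        cfg = SimulationConfig(n_genes=5000, n_per_group=3, dispersion=0.05,
                               libsize_sd=0.3, seed=13)
        counts, _, _ = generate_factorial_counts(cfg)
        sf = de.estimate_size_factors(counts)
        norm = de.normalize(counts, sf)
        col_means = norm.data.mean(axis=0)
        assert (col_means / col_means.mean()).between(0.98, 1.02).all()


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

class TestDispersions:
    def _design(self, n_per_cell):
        rows = []
        for age in ("adult", "aged"):
            for tr in ("control", "repopulation"):
                for k in range(n_per_cell):
                    rows.append({"sample_id": f"{age}_{tr}_{k}", "age": age, "treatment": tr})
        return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))

    def test_poisson_counts_give_near_zero_estimates(self):
        design = self._design(3)
        rng = np.random.default_rng(2)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), size=2000))
        values = rng.poisson(mu[:, None], size=(2000, 12))
        cm = _matrix(values, samples=list(design.sample_ids))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = de.estimate_dispersions(cm, design, sf)
        assert disp.median() <= 0.01

    def test_nb_counts_recover_dispersion_scale(self):
        design = self._design(3)
        rng = np.random.default_rng(3)
        alpha = 0.2
        mu = np.exp(rng.uniform(np.log(50), np.log(500), size=2000))
        r = 1 / alpha
        values = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 12))
        cm = _matrix(values, samples=list(design.sample_ids))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = de.estimate_dispersions(cm, design, sf)
        assert 0.1 <= disp.median() <= 0.35

    def test_constant_counts_clamp_at_floor(self):
        design = self._design(3)
        values = np.full((20, 12), 7)
        cm = _matrix(values, samples=list(design.sample_ids))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = de.estimate_dispersions(cm, design, sf)
        assert (disp <= 1e-4).all()  # zero variance pulls to the lower clamp

    def test_single_replicate_everywhere_rejected(self):
        design = self._design(1)
        cm = _matrix(np.ones((5, 4), dtype=int), samples=list(design.sample_ids))
        sf = pd.Series(1.0, index=cm.sample_ids)
        with pytest.raises(ValidationError, match="replicate"):
            de.estimate_dispersions(cm, design, sf)


# ---------------------------------------------------------------------------
# contrast fitting
# ---------------------------------------------------------------------------

def two_group_design(n=6):
    rows = [{"sample_id": f"s{j}", "age": "adult" if j < n else "aged",
             "treatment": "control"} for j in range(2 * n)]
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


class TestFitContrast:
    spec = ContrastSpec(factor="age", numerator="aged", denominator="adult")

    def test_identical_counts_give_null_result(self):
        design = two_group_design(3)
        cm = _matrix(np.tile([5, 8, 13], (1, 2)).reshape(1, 6).repeat(2, axis=0),
                     samples=list(design.sample_ids))
        disp = pd.Series(0.1, index=cm.gene_ids)
        sf = pd.Series(1.0, index=cm.sample_ids)
        res = de.fit_contrast(cm, design, self.spec, disp, sf)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_poisson_limit_matches_independent_glm(self):
        # tiny dispersion: NB Wald must agree with a Poisson GLM to 1e-6
        design = two_group_design(4)
        values = np.array([[3, 7, 4, 6, 12, 9, 15, 11],
                           [20, 25, 18, 22, 19, 24, 21, 23],
                           [1, 0, 2, 1, 5, 4, 6, 3]])
        cm = _matrix(values, samples=list(design.sample_ids))
        disp = pd.Series(1e-12, index=cm.gene_ids)
        sf = pd.Series(1.0, index=cm.sample_ids)
        res = de.fit_contrast(cm, design, self.spec, disp, sf)
        X = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        for i, gene in enumerate(cm.gene_ids):
            fit = sm.GLM(values[i].astype(float), X, family=sm.families.Poisson()).fit(tol=1e-12)
            assert res.loc[gene, "log2fc"] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
            assert res.loc[gene, "lfc_se"] == pytest.approx(fit.bse[1] / np.log(2), abs=1e-6)
            assert res.loc[gene, "pvalue"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_nb_fit_matches_statsmodels_negative_binomial(self):
        design = two_group_design(4)
        rng = np.random.default_rng(5)
        values = rng.poisson(np.array([[50] * 4 + [120] * 4,
                                       [200] * 8,
                                       [30] * 4 + [15] * 4]))
        cm = _matrix(values, samples=list(design.sample_ids))
        alpha = 0.15
        disp = pd.Series(alpha, index=cm.gene_ids)
        sf = de.estimate_size_factors(cm)
        res = de.fit_contrast(cm, design, self.spec, disp, sf)
        X = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        for i, gene in enumerate(cm.gene_ids):
            fit = sm.GLM(values[i].astype(float), X,
                         family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=np.log(sf.to_numpy())).fit(tol=1e-12)
            assert res.loc[gene, "log2fc"] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
            assert res.loc[gene, "lfc_se"] == pytest.approx(fit.bse[1] / np.log(2), abs=1e-6)

    def test_planted_effect_is_detected(self):
        # lfc 2 at baseline 100, n=6/group: essentially always p < 1e-4
        detected = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            design = two_group_design(6)
            r = 1 / 0.05
            mu = np.array([100.0] * 6 + [400.0] * 6)
            values = rng.negative_binomial(r, r / (r + mu), size=(1, 12))
            cm = _matrix(values, samples=list(design.sample_ids))
            res = de.fit_contrast(cm, design, self.spec,
                                  pd.Series(0.05, index=cm.gene_ids),
                                  pd.Series(1.0, index=cm.sample_ids))
            if res["pvalue"].iloc[0] < 1e-4:
                detected += 1
        assert detected >= 0.9 * reps

    def test_wald_antisymmetry_under_level_swap(self):
        cfg = SimulationConfig(n_genes=200, n_per_group=5, seed=21)
        counts, design, _ = generate_factorial_counts(cfg)
        sf = de.estimate_size_factors(counts)
        disp = de.estimate_dispersions(counts, design, sf)
        fwd = de.fit_contrast(counts, design,
                              ContrastSpec("age", "aged", "adult", {"treatment": "control"}),
                              disp, sf)
        rev = de.fit_contrast(counts, design,
                              ContrastSpec("age", "adult", "aged", {"treatment": "control"}),
                              disp, sf)
        tested = fwd["tested"] & rev["tested"]
        np.testing.assert_allclose(fwd.loc[tested, "log2fc"], -rev.loc[tested, "log2fc"], atol=1e-10)
        np.testing.assert_allclose(fwd.loc[tested, "stat"], -rev.loc[tested, "stat"], atol=1e-10)
        np.testing.assert_allclose(fwd.loc[tested, "pvalue"], rev.loc[tested, "pvalue"], atol=1e-10)

    def test_scaling_one_sample_normalizes_away(self):
        """Tripling one sample's counts is absorbed by its size factor.

        Median-of-ratios rescales the whole factor vector (the scaled sample
        by 3^((n-1)/n), the rest by 3^(-1/n)) so every normalized column is
        multiplied by the same constant: relative normalized expression, and
        hence the contrast point estimates, are unaffected up to the small
        likelihood-level effect of the count magnitudes themselves.
        """
        cfg = SimulationConfig(n_genes=150, n_per_group=4, seed=22)
        counts, design, _ = generate_factorial_counts(cfg)
        spec = ContrastSpec("age", "aged", "adult", {"treatment": "control"})
        sf = de.estimate_size_factors(counts)
        disp = de.estimate_dispersions(counts, design, sf)
        base = de.fit_contrast(counts, design, spec, disp, sf)

        scaled = counts.data.copy()
        target = scaled.columns[0]
        scaled[target] = scaled[target] * 3
        cm2 = CountMatrix(scaled)
        sf2 = de.estimate_size_factors(cm2)
        n = counts.n_samples
        assert sf2[target] == pytest.approx(sf[target] * 3 ** ((n - 1) / n), rel=1e-12)
        others = sf.index.drop(target)
        np.testing.assert_allclose(sf2[others], sf[others] * 3 ** (-1 / n), rtol=1e-12)
        norm1 = de.normalize(counts, sf)
        norm2 = de.normalize(cm2, sf2)
        ratio = norm2.data / norm1.data
        np.testing.assert_allclose(ratio.to_numpy(), 3 ** (1 / n), rtol=1e-12)

        res2 = de.fit_contrast(cm2, design, spec, disp, sf2)
        tested = base["tested"] & res2["tested"]
        np.testing.assert_allclose(base.loc[tested, "log2fc"],
                                   res2.loc[tested, "log2fc"], atol=0.1)
        # mid-range p-values move with the information content of the scaled
        # sample; significance calls stay essentially identical
        calls1 = base.loc[tested, "pvalue"] < 0.05
        calls2 = res2.loc[tested, "pvalue"] < 0.05
        assert (calls1 == calls2).mean() >= 0.95

    def test_untested_genes_carry_missing_statistics(self):
        design = two_group_design(3)
        values = np.array([[0, 0, 0, 5, 6, 7],     # zero denominator side
                           [0, 0, 0, 0, 0, 0],     # all zero
                           [5, 6, 7, 8, 9, 10]])
        cm = _matrix(values, samples=list(design.sample_ids))
        res = de.fit_contrast(cm, design, self.spec,
                              pd.Series(0.1, index=cm.gene_ids),
                              pd.Series(1.0, index=cm.sample_ids))
        assert not res.loc["g0", "tested"] and np.isnan(res.loc["g0", "pvalue"])
        assert not res.loc["g1", "tested"] and np.isnan(res.loc["g1", "padj"])
        assert res.loc["g2", "tested"]
        # padj >= pvalue for every tested gene
        tested = res[res["tested"]]
        assert (tested["padj"] >= tested["pvalue"]).all()

    def test_base_mean_prefilter_excludes_low_expression(self):
        design = two_group_design(3)
        values = np.array([[2, 3, 2, 3, 2, 3], [50, 60, 55, 65, 50, 60]])
        cm = _matrix(values, samples=list(design.sample_ids))
        res = de.fit_contrast(cm, design, self.spec,
                              pd.Series(0.1, index=cm.gene_ids),
                              pd.Series(1.0, index=cm.sample_ids), base_mean_min=10.0)
        assert not res.loc["g0", "tested"]
        assert res.loc["g1", "tested"]

    def test_singular_design_names_collinear_columns(self):
        design = two_group_design(3)
        cov = pd.DataFrame({"ruv1": [0, 0, 0, 1, 1, 1]}, index=design.sample_ids, dtype=float)
        design = SampleDesign(design.table, cov)  # ruv1 duplicates the age indicator
        cm = _matrix(np.ones((3, 6), dtype=int) * 5, samples=list(design.sample_ids))
        spec = ContrastSpec("age", "aged", "adult", covariates=["ruv1"])
        with pytest.raises(ValidationError, match="collinear"):
            de.fit_contrast(cm, design, spec,
                            pd.Series(0.1, index=cm.gene_ids),
                            pd.Series(1.0, index=cm.sample_ids))

    def test_missing_contrast_level_rejected(self):
        design = two_group_design(3)
        cm = _matrix(np.ones((2, 6), dtype=int), samples=list(design.sample_ids))
        spec = ContrastSpec("treatment", "repopulation", "control")
        with pytest.raises(ValidationError, match="repopulation"):
            de.fit_contrast(cm, design, spec,
                            pd.Series(0.1, index=cm.gene_ids),
                            pd.Series(1.0, index=cm.sample_ids))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestAdjustBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(de.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(de.adjust_bh([0.37]), [0.37])

    def test_missing_entries_pass_through(self):
        out = de.adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_oracle([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            de.adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_exactly(self, pvals, _):
        ours = de.adjust_bh(pvals)
        np.testing.assert_array_equal(ours, bh_oracle(pvals))

    def test_matches_statsmodels_closely(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 100))
            ours = de.adjust_bh(p)
            ref = sm.stats.multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=200)
        adj = de.adjust_bh(p)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# comparative CT
# ---------------------------------------------------------------------------

class TestDdct:
    def _table(self, dct, groups):
        return DdctTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(dct))],
            "group": groups,
            "ct_target": [15.0 + d for d in dct],
            "ct_reference": 15.0,
        }))

    def test_equal_target_and_reference_gives_unit_fold_change(self):
        t = self._table([0, 0, 0], ["c", "c", "t"])
        np.testing.assert_allclose(de.ddct_fold_change(t, "c"), 1.0)

    def test_closed_form_fold_change(self):
        # control mean dCT 5, sample dCT 3 -> 2^-(3-5) = 4
        t = self._table([4, 6, 3], ["c", "c", "t"])
        fc = de.ddct_fold_change(t, "c")
        assert fc.iloc[2] == pytest.approx(4.0)

    def test_control_group_log2_centering(self):
        rng = np.random.default_rng(23)
        dct = rng.normal(5, 1, size=10)
        t = self._table(dct, ["c"] * 10)
        fc = de.ddct_fold_change(t, "c")
        assert np.log2(fc).mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_control_group_rejected(self):
        t = self._table([1, 2], ["t", "t"])
        with pytest.raises(ValidationError):
            de.ddct_fold_change(t, "c")
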