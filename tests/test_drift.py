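"""Heteroscedasticity screen and methylome entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methage import (EntropyResult, MethylationMatrix, SampleRecord,
                     breusch_pagan, detect_vmps, entropy_age_model,
                     entropy_per_sample, shannon_entropy)
from methage.drift import vmp_frame
from methage.errors import DataError, ValidationError


def bp_oracle(y, X):
    """Brute force: two explicit least-squares solves, LM = n * R2_aux."""
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u2 = (y - X @ beta) ** 2
    gamma = np.linalg.lstsq(X, u2, rcond=None)[0]
    fitted = X @ gamma
    r2 = 1 - ((u2 - fitted) ** 2).sum() / ((u2 - u2.mean()) ** 2).sum()
    lm = len(y) * r2
    return lm, stats.chi2.sf(lm, X.shape[1] - 1)


class TestBreuschPagan:
    def test_four_point_worked_example(self):
        # OLS slope 2.8, intercept -3; squared residuals
        # (1.44, 0.36, 5.76, 3.24); auxiliary R2 = 0.3488 -> LM = 4*R2
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        lm, df, p = breusch_pagan(y, np.column_stack([np.ones(4), x]))
        assert lm == pytest.approx(4 * 0.3488, abs=0.01)
        assert df == 1
        assert p == pytest.approx(0.24, abs=0.01)

    def test_exact_linear_fit_gives_zero(self):
        x = np.arange(10.0)
        lm, df, p = breusch_pagan(2 * x + 1, np.column_stack([np.ones(10), x]))
        assert lm == 0.0 and p == 1.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(DataError):
            breusch_pagan(np.arange(6.0),
                          np.column_stack([np.ones(6), np.ones(6)]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_matches_two_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 40)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.normal(size=n) * (1 + 0.3 * np.abs(X[:, 1]))
        lm, df, p = breusch_pagan(y, X)
        lm_o, p_o = bp_oracle(y, X)
        assert lm == pytest.approx(lm_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)
        assert df == 2


class TestHolm:
    def test_step_down_example(self):
        _, adj, _, _ = multipletests([0.001, 0.02, 0.04], method="holm")
        assert adj == pytest.approx([0.003, 0.04, 0.04])

    def test_dominated_by_bonferroni(self, pipeline_run):
        frame = vmp_frame(pipeline_run.vmps)
        m = len(frame)
        assert (frame["p_holm"] <= np.minimum(1.0, m * frame["p"]) + 1e-12).all()
        assert (frame["p_holm"] >= frame["p"] - 1e-12).all()


def drift_matrix(seed=0, n_null=60, n_het=60, reps=3):
    """Small two-class matrix: constant-variance vs phi-decaying sites."""
    rng = np.random.default_rng(seed)
    samples = [SampleRecord(f"{sex}{age}r{r}", sex, age, r)
               for sex in "FM" for age in (0, 8, 16) for r in range(1, reps + 1)]
    ages = np.array([s.age_days for s in samples], float)
    rows_meth, rows_cov, sites = [], [], []
    pos = 1
    for cls, n_sites in (("null", n_null), ("het", n_het)):
        for _ in range(n_sites):
            mu = rng.uniform(0.35, 0.65)
            phi = np.full(len(samples), 80.0)
            if cls == "het":
                phi = 80.0 + (10.0 - 80.0) * ages / 16.0
            p = rng.beta(mu * phi, (1 - mu) * phi)
            cov = np.full(len(samples), 30)
            rows_meth.append(rng.binomial(cov, p))
            rows_cov.append(cov)
            sites.append(("c", pos))
            pos += 1
    return (MethylationMatrix(sites, samples, np.array(rows_meth),
                              np.array(rows_cov)),
            {("c", i + 1) for i in range(n_null)})


class TestDetectVmps:
    def test_null_sites_rarely_flagged(self):
        matrix, null_keys = drift_matrix(seed=3)
        results = detect_vmps(matrix)
        false = [r.is_vmp for r in results if r.site in null_keys]
        assert np.mean(false) <= 0.05

    def test_raw_screen_enriched_for_heteroscedastic_sites(self):
        """Drift sites get systematically smaller screen p-values than
        constant-variance sites (the small-n screen ranks correctly even
        where family-wise significance is out of reach)."""
        matrix, null_keys = drift_matrix(seed=4, n_null=150, n_het=150)
        results = detect_vmps(matrix, fit_mean_model=False)
        p_null = [r.p for r in results if r.site in null_keys]
        p_het = [r.p for r in results if r.site not in null_keys]
        assert stats.mannwhitneyu(p_het, p_null,
                                  alternative="less").pvalue < 1e-4

    def test_too_few_samples_rejected(self):
        samples = [SampleRecord(f"s{i}", "F", 0, i + 1) for i in range(4)]
        m = MethylationMatrix([("c", 1)], samples,
                              np.ones((1, 4), int), np.full((1, 4), 10))
        with pytest.raises(DataError):
            detect_vmps(m)


class TestShannonEntropy:
    def test_maximal_at_half(self):
        assert shannon_entropy([0.5, 0.5, 0.5]) == pytest.approx(1.0, abs=1e-15)

    def test_degenerate_fractions_zero(self):
        assert shannon_entropy([0.0, 1.0, 0.0, 1.0]) == 0.0

    def test_quarter_case_direct_evaluation(self):
        expected = (0.25 * np.log(0.25) + 0.75 * np.log(0.75)) / np.log(0.5)
        assert shannon_entropy([0.25]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(DataError):
            shannon_entropy([])
        with pytest.raises(ValidationError):
            shannon_entropy([1.2])

    def test_as_printed_variant_differs_and_requires_positive(self):
        assert shannon_entropy([0.25], variant="as-printed") != pytest.approx(
            shannon_entropy([0.25]))
        with pytest.raises(ValidationError):
            shannon_entropy([0.0, 0.5], variant="as-printed")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_symmetry_and_range(self, mf):
        h = shannon_entropy(mf)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert h == pytest.approx(shannon_entropy([1 - x for x in mf]),
                                  abs=1e-12)

    def test_unique_maximum_at_half_by_grid_search(self):
        grid = np.linspace(0, 1, 201)
        values = [shannon_entropy([x]) for x in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5)
        assert max(values) == pytest.approx(1.0)
        assert all(v < 1.0 for x, v in zip(grid, values) if x != 0.5)


class TestEntropyPerSample:
    def matrix(self, meth, cov):
        samples = [SampleRecord(f"s{j}", "F", 0, j + 1)
                   for j in range(meth.shape[1])]
        sites = [("c", 10 * (i + 1)) for i in range(meth.shape[0])]
        return MethylationMatrix(sites, samples, meth, cov)

    def test_all_half_methylated_is_one(self):
        m = self.matrix(np.full((4, 2), 5), np.full((4, 2), 10))
        for r in entropy_per_sample(m):
            assert r.entropy == pytest.approx(1.0)
            assert r.n_sites == 4

    def test_identical_samples_identical_entropy(self):
        meth = np.array([[3, 3], [7, 7], [1, 1]])
        m = self.matrix(meth, np.full((3, 2), 10))
        a, b = entropy_per_sample(m)
        assert a.entropy == b.entropy

    def test_empty_site_set_rejected(self, pipeline_run):
        with pytest.raises(DataError):
            entropy_per_sample(pipeline_run.methylated, [])


class TestEntropyAgeModel:
    def simulated(self, f_slope, m_slope, seed=5, phi=300.0):
        rng = np.random.default_rng(seed)
        samples, ents = [], []
        for sex, slope in (("F", f_slope), ("M", m_slope)):
            for age in (0, 8, 16):
                for rep in range(1, 4):
                    sid = f"{sex}{age}r{rep}"
                    samples.append(SampleRecord(sid, sex, age, rep))
                    mu = min(0.5 + slope * age, 0.95)
                    ents.append(EntropyResult(
                        sid, float(rng.beta(mu * phi, (1 - mu) * phi)), 100))
        return ents, samples

    def test_sex_specific_drift_detected(self):
        ents, samples = self.simulated(f_slope=0.02, m_slope=0.0)
        model = entropy_age_model(ents, samples)
        assert model.interaction_p < 0.05
        f_slope, _, _, f_p = model.per_sex["F"]
        _, _, _, m_p = model.per_sex["M"]
        assert f_p < 0.05 and f_slope > 0
        assert m_p > 0.05

    def test_identical_relation_usually_non_significant(self):
        hits = 0
        for seed in range(20):
            ents, samples = self.simulated(0.01, 0.01, seed=seed)
            hits += entropy_age_model(ents, samples).interaction_p < 0.05
        assert hits <= 4  # ~alpha-level rate, generous band at 20 draws

    def test_constant_entropy_has_zero_slope(self):
        ents, samples = self.simulated(0.0, 0.0)
        ents = [EntropyResult(e.sample_id, 0.7, e.n_sites) for e in ents]
        model = entropy_age_model(ents, samples)
        assert model.full_fit.params[1] == pytest.approx(0.0, abs=1e-6)

    def test_two_age_design_skips_slope_with_warning(self):
        ents, samples = self.simulated(0.02, 0.0)
        keep = [i for i, s in enumerate(samples)
                if not (s.sex == "M" and s.age_days == 16)]
        ents = [ents[i] for i in keep]
        samples = [samples[i] for i in keep]
        with pytest.warns(UserWarning, match="skipped"):
            model = entropy_age_model(ents, samples)
        assert model.per_sex["M"] is None


class TestDriftOnSyntheticRun:
    def test_entropy_rises_with_age_over_dm_sites(self, pipeline_run):
        by_id = {s.sample_id: s for s in pipeline_run.samples}
        by_age = {}
        for e in pipeline_run.entropies:
            by_age.setdefault(by_id[e.sample_id].age_days, []).append(e.entropy)
        assert np.mean(by_age[16]) > np.mean(by_age[0])
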