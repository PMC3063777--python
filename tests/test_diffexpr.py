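"""Normalization, dispersion, the NB exact test, q-values, and bias summaries."""

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import strainseq.diffexpr as de
from strainseq.gene_models import ExonRecord, build_union_exons
from strainseq.synthetic import CountConfig, SimulationConfig, default_samples, simulate_count_matrix

from _oracles import enumerate_exact_p
from conftest import make_count_matrix


class TestTotalCountScale:
    def test_definition(self, small_samples):
        cm = make_count_matrix(np.array([[30, 30, 30, 30]]), small_samples,
                               lib_sizes=[15_000_000] * 4)
        assert de.total_count_scale(cm).iloc[0, 0] == pytest.approx(2.0)

    def test_matches_direct_recomputation_on_random_matrix(self, small_samples, rng):
        y = rng.integers(0, 500, size=(50, 4))
        n = rng.integers(10**5, 10**7, size=4)
        cm = make_count_matrix(y, small_samples, lib_sizes=n)
        got = de.total_count_scale(cm).to_numpy()
        assert np.allclose(got, y * 1e6 / n[None, :])

    def test_zero_library_raises(self, small_samples):
        cm = make_count_matrix(np.ones((2, 4), int), small_samples, lib_sizes=[0, 1, 1, 1])
        with pytest.raises(ValueError):
            de.total_count_scale(cm)


class TestUpperQuartileFactors:
    def test_identical_samples_give_unit_factors(self, small_samples, rng):
        col = rng.integers(0, 200, size=100)
        cm = make_count_matrix(np.tile(col[:, None], 4), small_samples)
        f = de.upper_quartile_factors(cm)
        assert np.allclose(f.factors, 1.0)

    def test_doubled_sample_doubles_factor_at_equal_n(self, small_samples, rng):
        col = rng.integers(1, 200, size=200)
        y = np.stack([col, col, col, 2 * col], axis=1)
        cm = make_count_matrix(y, small_samples, lib_sizes=[10_000] * 4)
        f = de.upper_quartile_factors(cm)
        assert f.factors["d2"] / f.factors["b1"] == pytest.approx(2.0)

    def test_geometric_mean_of_factors_is_one(self, small_samples, rng):
        y = rng.integers(0, 300, size=(150, 4))
        y[:, 0] += 1  # no all-zero sample
        cm = make_count_matrix(y, small_samples)
        f = de.upper_quartile_factors(cm)
        assert np.exp(np.log(f.factors.to_numpy()).mean()) == pytest.approx(1.0)
        assert np.allclose(f.effective_sizes, f.factors * f.lib_sizes)

    def test_planted_multipliers_recovered_within_5pct(self, small_samples, rng):
        m_g = rng.lognormal(np.log(100), 1.0, size=2000)
        cj = np.array([0.5, 1.0, 2.0, 4.0])
        r = 1 / 0.1
        y = rng.negative_binomial(r, r / (r + m_g[:, None] * cj[None, :]))
        cm = make_count_matrix(y, small_samples, lib_sizes=[1_000_000] * 4)
        f = de.upper_quartile_factors(cm)
        target = cj / np.exp(np.log(cj).mean())
        assert np.all(np.abs(f.factors.to_numpy() / target - 1) < 0.05)

    def test_all_zero_sample_raises(self, small_samples):
        y = np.array([[1, 1, 1, 0], [2, 2, 2, 0]])
        cm = make_count_matrix(y, small_samples, lib_sizes=[10, 10, 10, 10])
        with pytest.raises(ValueError):
            de.upper_quartile_factors(cm)


class TestQuantileAdjust:
    def _factors(self, lib, samples):
        lib = pd.Series(lib, index=samples.index, dtype=float)
        f = lib / np.exp(np.log(lib).mean())
        return de.NormalizationFactors(
            lib_sizes=pd.Series(1.0, index=samples.index),
            upper_quartiles=pd.Series(1.0, index=samples.index),
            factors=f,
            effective_sizes=lib,
        )

    def test_equal_library_sizes_identity(self, small_samples, rng):
        y = pd.DataFrame(rng.integers(0, 100, size=(30, 4)),
                         columns=small_samples.index)
        factors = self._factors([5000.0] * 4, small_samples)
        groups = (["b1", "b2"], ["d1", "d2"])
        pseudo, m_star = de.quantile_adjust(y, factors, groups, phi=0.2)
        assert np.allclose(pseudo.to_numpy(), y.to_numpy())
        assert m_star == pytest.approx(5000.0)

    def test_poisson_limit_matches_closed_form_interpolation(self, small_samples):
        # one gene, unequal sizes; oracle recomputes the interpolated
        # Poisson quantile match directly
        y = pd.DataFrame([[10.0, 20.0, 12.0, 24.0]], columns=small_samples.index)
        lib = np.array([1000.0, 2000.0, 1000.0, 2000.0])
        factors = self._factors(lib, small_samples)
        groups = (["b1", "b2"], ["d1", "d2"])
        pseudo, m_star = de.quantile_adjust(y, factors, groups, phi=0.0)
        lam = {0: 30 / 3000, 1: 30 / 3000, 2: 36 / 3000, 3: 36 / 3000}
        for j, s in enumerate(small_samples.index):
            u = stats.poisson.cdf(y.iloc[0, j], lam[j] * lib[j])
            mu_out = lam[j] * m_star
            k = 0
            while stats.poisson.cdf(k, mu_out) < u:
                k += 1
            f_k = stats.poisson.cdf(k, mu_out)
            f_km1 = stats.poisson.cdf(k - 1, mu_out) if k >= 1 else 0.0
            want = k - 1 + (u - f_km1) / (f_k - f_km1)
            assert pseudo.iloc[0, j] == pytest.approx(want, abs=1e-9)

    def test_flat_gene_mean_pseudocount_scales_with_library_size(self, rng):
        # doubling a sample's effective size halves its expected contribution:
        # after adjustment all samples should contribute comparably
        samples = pd.DataFrame(
            {"strain": ["B6"] * 6 + ["D2"] * 6, "lane": "", "flowcell": ""},
            index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
        )
        lib = np.array([1000.0, 2000.0] * 6)
        mu = 50 * lib / 1000.0
        r = 1 / 0.1
        y = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[None, :]), size=(4000, 12)).astype(float),
            columns=samples.index,
        )
        factors = self._factors(lib, samples)
        groups = (list(samples.index[:6]), list(samples.index[6:]))
        pseudo, m_star = de.quantile_adjust(y, factors, groups, phi=0.1)
        means = pseudo.mean(axis=0).to_numpy()
        assert np.all(np.abs(means / means.mean() - 1) < 0.05)


class TestCommonDispersion:
    def test_conditional_loglik_matches_high_precision_formula(self):
        samples = ["a", "b", "c"]
        z = pd.DataFrame([[3.0, 5.0, 2.0]], columns=samples)
        phi = 0.25
        got = de.conditional_loglik(z, ([*samples], []), phi)  # empty group ignored
        r = sympy.Rational(4)  # 1/phi
        zs = [3, 5, 2]
        zdot = sum(zs)
        n = 3
        expr = (
            sympy.loggamma(zdot + 1)
            - sum(sympy.loggamma(v + 1) for v in zs)
            + sum(sympy.loggamma(v + r) for v in zs)
            - n * sympy.loggamma(r)
            + sympy.loggamma(n * r)
            - sympy.loggamma(zdot + n * r)
        )
        assert got == pytest.approx(float(expr.evalf(30)), rel=1e-12)

    def test_recovery_and_poisson_boundary(self):
        samples = default_samples()
        cfg = SimulationConfig(
            seed=101,
            counts=CountConfig(n_genes=800, dispersion=0.1, de_fraction=0.0,
                               library_factors=[1.0] * 21),
        )
        cm, _ = simulate_count_matrix(cfg, samples)
        est = de.estimate_common_dispersion(
            cm.counts, de.upper_quartile_factors(cm), de.strain_groups(samples)
        )
        assert 0.07 < est.phi < 0.13
        cfg0 = SimulationConfig(
            seed=102,
            counts=CountConfig(n_genes=800, dispersion=0.0, de_fraction=0.0,
                               library_factors=[1.0] * 21),
        )
        cm0, _ = simulate_count_matrix(cfg0, samples)
        est0 = de.estimate_common_dispersion(
            cm0.counts, de.upper_quartile_factors(cm0), de.strain_groups(samples)
        )
        assert est0.phi <= 0.01

    def test_tiny_design_does_not_crash(self, small_samples, rng):
        y = pd.DataFrame(rng.integers(0, 60, size=(100, 4)).astype(float),
                         columns=small_samples.index)
        factors = de.upper_quartile_factors(
            make_count_matrix(y.to_numpy(), small_samples)
        )
        est = de.estimate_common_dispersion(y, factors, (["b1", "b2"], ["d1", "d2"]))
        assert np.isfinite(est.phi)

    def test_single_group_sample_raises(self, small_samples):
        y = pd.DataFrame(np.ones((5, 4)), columns=small_samples.index)
        factors = de.upper_quartile_factors(make_count_matrix(np.ones((5, 4), int), small_samples))
        with pytest.raises(ValueError):
            de.estimate_common_dispersion(y, factors, (["b1"], ["d1", "d2"]))


class TestExactTest:
    def test_symmetric_observation_gives_p_one(self):
        assert de.nb_exact_test(40, 40, 10, 10, 0.1) == pytest.approx(1.0)

    def test_zero_total_is_p_one(self):
        assert de.nb_exact_test(0, 0, 10, 11, 0.1) == 1.0

    def test_poisson_limit_equals_conditional_binomial(self):
        for s_a, s_b in [(3, 20), (15, 5), (0, 12), (8, 8)]:
            want = stats.binomtest(s_a, s_a + s_b, 10 / 21).pvalue
            assert de.nb_exact_test(s_a, s_b, 10, 11, 0.0) == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 1.0])
    def test_matches_enumeration_oracle_small_totals(self, phi):
        for S in range(0, 61, 5):
            for s_a in range(0, S + 1, 3):
                got = de.nb_exact_test(s_a, S - s_a, 10, 11, phi)
                want = enumerate_exact_p(s_a, S - s_a, 10, 11, phi)
                assert abs(got - want) < 1e-10

    def test_matches_arbitrary_precision_weights(self):
        # sympy anchor: exact negative-hypergeometric weights at S=18
        n_a, n_b, phi, S = 10, 11, sympy.Rational(1, 5), 18
        ra, rb = n_a / phi, n_b / phi
        weights = []
        for s in range(S + 1):
            w = (
                sympy.gamma(s + ra) / (sympy.gamma(s + 1) * sympy.gamma(ra))
                * sympy.gamma(S - s + rb) / (sympy.gamma(S - s + 1) * sympy.gamma(rb))
            )
            weights.append(w)
        total = sum(weights)
        for s_a in (0, 4, 9, 13, 18):
            obs = weights[s_a] / total
            p = sum(w / total for w in weights if w / total <= obs * (1 + sympy.Rational(1, 10**7)))
            want = float(sympy.N(p, 30))
            got = de.nb_exact_test(s_a, S - s_a, n_a, n_b, 0.2)
            assert got == pytest.approx(want, abs=1e-9)

    @given(
        s_a=st.integers(0, 60),
        s_b=st.integers(0, 60),
        phi=st.sampled_from([0.0, 0.1, 0.5]),
    )
    @settings(max_examples=40, deadline=None)
    def test_p_in_unit_interval_and_label_symmetric(self, s_a, s_b, phi):
        p = de.nb_exact_test(s_a, s_b, 10, 10, phi)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(de.nb_exact_test(s_b, s_a, 10, 10, phi), abs=1e-12)


class TestPoissonLRT:
    def test_identical_group_rates_give_p_one(self, small_samples):
        cm = make_count_matrix(np.array([[7, 7, 7, 7]]), small_samples, lib_sizes=[100] * 4)
        factors = de.upper_quartile_factors(cm)
        p = de.poisson_lrt(cm.counts.iloc[0], (["b1", "b2"], ["d1", "d2"]), factors)
        assert p == pytest.approx(1.0)

    def test_all_zero_gene_p_one(self, small_samples):
        cm = make_count_matrix(np.array([[0, 0, 0, 0], [1, 2, 3, 4]]), small_samples,
                               lib_sizes=[100] * 4)
        factors = de.upper_quartile_factors(cm)
        p = de.poisson_lrt_pvalues(cm.counts, (["b1", "b2"], ["d1", "d2"]), factors)
        assert p.iloc[0] == 1.0

    def test_matches_generic_optimizer(self, small_samples, rng):
        groups = (["b1", "b2"], ["d1", "d2"])
        for _ in range(10):
            y = rng.integers(1, 50, size=(1, 4)).astype(float)
            cm = make_count_matrix(y.astype(int), small_samples,
                                   lib_sizes=rng.integers(80, 300, size=4))
            factors = de.upper_quartile_factors(cm)
            m = factors.effective_sizes.to_numpy(float)
            yv = y[0]

            def nll_null(loglam):
                mu = np.exp(loglam) * m
                return -(yv * np.log(mu) - mu)[yv + mu > 0].sum()

            def nll_alt(loglams):
                mu = np.where([True, True, False, False], np.exp(loglams[0]), np.exp(loglams[1])) * m
                return -(yv * np.log(mu) - mu).sum()

            if yv.sum() == 0 or yv[:2].sum() == 0 or yv[2:].sum() == 0:
                continue
            r0 = optimize.minimize_scalar(nll_null, bounds=(-20, 5), method="bounded",
                                          options={"xatol": 1e-12})
            r1 = optimize.minimize(nll_alt, x0=[r0.x, r0.x], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
            stat = max(2 * (r0.fun - r1.fun), 0.0)
            got_stat = de.poisson_lrt_statistics(cm.counts, groups, factors).iloc[0]
            assert got_stat == pytest.approx(stat, abs=1e-8)
            got_p = de.poisson_lrt(cm.counts.iloc[0], groups, factors)
            assert got_p == pytest.approx(stats.chi2.sf(got_stat, 1), abs=1e-12)


class TestStoreyQvalues:
    def test_null_pi0_near_one_and_q_equals_pi0_times_bh(self, rng):
        import statsmodels.stats.multitest as mt

        p = rng.random(4000)
        pi0 = de.estimate_pi0(p)
        assert 0.9 <= pi0 <= 1.0
        q = de.storey_qvalues(p)
        bh = mt.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, np.minimum(pi0 * bh, 1.0), rtol=1e-10)

    def test_single_pvalue(self):
        q = de.storey_qvalues(np.array([0.04]))
        assert 0 < q[0] <= 0.04

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p_and_ties_share_q(self, ps):
        p = np.array(ps)
        q = de.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        for v in np.unique(p):
            assert np.allclose(q[p == v], q[p == v][0])

    def test_empty_input(self):
        assert de.storey_qvalues(np.array([])).size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            de.storey_qvalues(np.array([0.5, 1.2]))


class TestCallDEAndFlags:
    def test_equal_means_give_zero_fc_and_no_direction(self, small_samples):
        cm = make_count_matrix(np.array([[50, 50, 50, 50]]), small_samples,
                               lib_sizes=[1000] * 4)
        factors = de.upper_quartile_factors(cm)
        res = de.call_de(cm.counts, factors, (["b1", "b2"], ["d1", "d2"]),
                         pd.Series([1.0], index=cm.counts.index))
        assert res["log2_fc"].iloc[0] == pytest.approx(0.0)
        assert res["direction"].iloc[0] == "none"

    def test_direction_threshold_rule(self, small_samples, rng):
        # background genes keep the upper-quartile factors flat so the
        # planted 4-fold gene keeps its fold change after normalization
        bg = np.tile(rng.integers(10, 100, size=50)[:, None], 4)
        y = np.vstack([[80, 80, 20, 20], [80, 80, 20, 20], bg])
        cm = make_count_matrix(y, small_samples, lib_sizes=[1000] * 4)
        factors = de.upper_quartile_factors(cm)
        pvals = pd.Series(0.9, index=cm.counts.index)
        pvals.iloc[0] = 0.0001
        res = de.call_de(cm.counts, factors, (["b1", "b2"], ["d1", "d2"]), pvals)
        # q for the first gene is small, for the second large
        assert res["direction"].iloc[0] == "B6>D2"
        assert res["direction"].iloc[1] == "none"
        assert (res["direction"] == "none").equals(res["q_value"] >= 0.01)

    def test_planted_twofold_recovered(self):
        samples = default_samples()
        cfg = SimulationConfig(
            seed=55,
            counts=CountConfig(n_genes=400, mean_log=np.log(500), mean_sdlog=0.0,
                               dispersion=0.05, de_fraction=0.5,
                               effect_size=(1.0, 1.0)),
        )
        cm, truth = simulate_count_matrix(cfg, samples)
        res, _, _ = de.run_exact_de(cm)
        planted = truth.genes["is_de"]
        err = (res.loc[planted, "log2_fc"].abs() - 1.0).abs()
        assert err.median() < 0.1

    def test_low_count_flag_threshold(self):
        res = pd.DataFrame(
            {"avg_log_abundance": [-21.0, -10.0], "q_value": [0.5, 0.5]},
            index=["a", "b"],
        )
        out = de.flag_low_count(res)
        assert out["low_count_flag"].tolist() == [True, False]

    def test_flag_count_matches_direct_recomputation(self, small_samples, rng):
        y = rng.integers(0, 5, size=(300, 4))
        y[0] = [200, 220, 210, 190]  # keep the upper quartile sane
        cm = make_count_matrix(y, small_samples, lib_sizes=[10**8] * 4)
        factors = de.upper_quartile_factors(cm)
        res = de.call_de(cm.counts, factors, (["b1", "b2"], ["d1", "d2"]),
                         pd.Series(0.5, index=cm.counts.index))
        prop = cm.counts / factors.effective_sizes
        with np.errstate(divide="ignore"):
            direct = np.log2(prop.mean(axis=1)) < -20
        assert (res["low_count_flag"] == direct).all()


class TestLengthBias:
    def _results(self, qvals):
        return pd.DataFrame(
            {"q_value": qvals}, index=[f"G{i:04d}" for i in range(len(qvals))]
        )

    def _models(self, lengths):
        recs = [
            ExonRecord(f"G{i:04d}", "T1", "chr1", 10_000 * i + 1, 10_000 * i + int(L))
            for i, L in enumerate(lengths)
        ]
        return build_union_exons(recs)

    def test_quartile_boundaries_match_percentiles(self, rng):
        lengths = rng.integers(100, 10_000, size=80)
        models = self._models(lengths)
        res = self._results(rng.random(80))
        table, _ = de.length_bias_summary(res, models)
        assert table["n_genes"].sum() == 80
        assert (table["n_genes"] == 20).all()

    def test_null_labels_rarely_rejected(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            lengths = rng.integers(100, 10_000, size=200)
            q = np.where(rng.random(200) < 0.1, 0.001, 0.5)  # DE independent of length
            table, p = de.length_bias_summary(self._results(q), self._models(lengths))
            hits += p >= 0.01
        assert hits >= int(0.8 * n_sim)

    def test_planted_length_bias_detected_as_monotone_counts(self, rng):
        lengths = np.sort(rng.integers(100, 10_000, size=400))
        prob = np.linspace(0.0, 0.6, 400)
        q = np.where(rng.random(400) < prob, 0.001, 0.5)
        table, p = de.length_bias_summary(self._results(q), self._models(lengths))
        counts = table["n_de"].to_numpy()
        assert np.all(np.diff(counts) > 0)
        assert p < 0.01

    def test_too_few_genes_raise(self):
        with pytest.raises(ValueError):
            de.length_bias_summary(self._results([0.5, 0.5]), self._models([100, 200]))
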