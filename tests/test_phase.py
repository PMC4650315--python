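import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import i0e, i1e

from clockminer import (
    CircularPhaseGLM,
    HitMatrix,
    PhaseModelParams,
    PhaseRecord,
    SimulationConfig,
    circular_median_ct,
    filter_and_pool_phases,
    predict_phase,
    rayleigh_test,
    simulate_hit_matrix,
    simulate_phase_table,
    tf_combo_summary,
    tf_group_scores,
)
from clockminer.phase import (
    circular_mean_ct,
    ct_to_radians,
    vonmises_kappa_from_rbar,
    wrap_ct,
)

MU_CT, C_E, C_D, C_RRE, KAPPA = 17.97, -2.25, 0.67, 0.41, 0.58


class TestTFGroupScores:
    def test_group_maxima_and_examples(self, registry):
        ids = registry.dataset_ids
        values = np.zeros((3, len(registry)), dtype=np.int8)
        # gene 0: all four E-box datasets
        for rid in ("koike_bmal1", "koike_clock", "koike_npas", "rey_bmal1"):
            values[0, ids.index(rid)] = 1
        # gene 1: only the weight-3 BMAL1 set
        values[1, ids.index("rey_bmal1")] = 1
        hm = HitMatrix(("g0", "g1", "g2"), ids, values)
        scores = tf_group_scores(hm, registry)
        assert scores.loc["g0", "s_e"] == pytest.approx(1.0)
        assert scores.loc["g1", "s_e"] == pytest.approx(0.5)  # 3 / group max 6
        assert scores.loc["g2", "s_rre"] == 0.0
        assert ((scores >= 0) & (scores <= 1)).all().all()

    def test_per_cry_columns_feed_no_group(self, registry):
        ids = registry.dataset_ids
        values = np.zeros((1, len(registry)), dtype=np.int8)
        for rid in ("koike_per1", "koike_per2", "koike_cry1", "koike_cry2"):
            values[0, ids.index(rid)] = 1
        hm = HitMatrix(("g",), ids, values)
        scores = tf_group_scores(hm, registry)
        assert (scores.loc["g"] == 0).all()


class TestFilterAndPool:
    def test_cutoff_and_wrapping(self):
        records = [
            PhaseRecord("a", "liver", 5.0, 0.04),
            PhaseRecord("a", "lung", 24.5, 0.01),
            PhaseRecord("b", "liver", 10.0, 0.06),
            PhaseRecord("b", "lung", 11.0, 0.2),
            PhaseRecord("c", "scn", -1.0, 0.001),
            PhaseRecord("c", "liver", 3.0, 0.5),
        ]
        pooled = filter_and_pool_phases(records, fdr_cutoff=0.05)
        assert len(pooled) == 3
        assert pooled.loc[pooled["gene_id"] == "a", "phase_ct"].tolist() == [5.0, 0.5]
        assert pooled.loc[pooled["gene_id"] == "c", "phase_ct"].tolist() == [23.0]

    def test_empty_output_allowed(self):
        pooled = filter_and_pool_phases([PhaseRecord("a", "liver", 1.0, 0.9)])
        assert pooled.empty


def _planted_dataset(n_obs, seed, params=None):
    """Phases drawn from the generative model over a realistic score mix."""
    params = params or PhaseModelParams()
    cfg = SimulationConfig(
        seed=seed,
        phase_params=params,
        circadian_fraction=min(1.0, n_obs / (1000 * 14)),
    )
    rng = np.random.default_rng(seed)
    hits, _ = simulate_hit_matrix(cfg, rng=rng)
    scores = tf_group_scores(hits, cfg.registry)
    table = simulate_phase_table(cfg, scores, rng=rng)
    pooled = filter_and_pool_phases(table)
    return pooled, scores


class TestCircularPhaseGLMFit:
    def test_intercept_only_reduction(self):
        rng = np.random.default_rng(0)
        phases = wrap_ct(rng.vonmises(ct_to_radians(8.0), 2.0, size=400) * 12 / np.pi)
        exog = np.zeros((400, 3))
        model = CircularPhaseGLM(phases, exog, exog_names=["s_e", "s_d", "s_rre"])
        fit = model.fit()
        assert fit.unidentifiable == ("s_e", "s_d", "s_rre")
        assert fit.coefs.tolist() == [0.0, 0.0, 0.0]
        cm = circular_mean_ct(phases)
        assert abs((fit.mu_ct - cm + 12) % 24 - 12) < 1e-6
        rbar = float(np.abs(np.exp(1j * ct_to_radians(phases)).mean()))
        assert fit.kappa == pytest.approx(vonmises_kappa_from_rbar(rbar), rel=1e-8)

    def test_matches_direct_search_oracle(self):
        """An independent Nelder-Mead maximization of the same von Mises
        likelihood reaches the same optimum on a 50-observation toy set."""
        pooled, scores = _planted_dataset(50, seed=42)
        pooled = pooled.iloc[:50]
        model = CircularPhaseGLM.from_dataframe(pooled, scores)
        fit = model.fit()

        theta = model.theta
        x = model.exog

        def negll(p):
            mu, ce, cd, cr, logk = p
            kappa = np.exp(logk)
            resid = theta - mu - 2 * np.arctan(x @ np.array([ce, cd, cr]))
            log_i0 = np.log(i0e(kappa)) + kappa
            return -(-len(theta) * (np.log(2 * np.pi) + log_i0) + kappa * np.sum(np.cos(resid)))

        best = np.inf
        for mu0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            res = minimize(
                negll, [mu0, 0, 0, 0, 0.0], method="Nelder-Mead",
                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
            )
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-6)

    def test_parameter_recovery_single_replicate(self):
        pooled, scores = _planted_dataset(3000, seed=7)
        fit = CircularPhaseGLM.from_dataframe(pooled, scores).fit()
        assert fit.converged
        assert abs((fit.mu_ct - MU_CT + 12) % 24 - 12) < 3 * fit.bse["mu_ct"]
        for name, truth in [("s_e", C_E), ("s_d", C_D), ("s_rre", C_RRE), ("kappa", KAPPA)]:
            est = fit.params[name]
            assert abs(est - truth) < 3 * fit.bse[name], name

    def test_bias_shrinks_with_n(self):
        errs = {}
        for n in (500, 3000):
            errors = []
            for rep in range(4):
                pooled, scores = _planted_dataset(n, seed=100 * n + rep)
                fit = CircularPhaseGLM.from_dataframe(pooled, scores).fit()
                errors.append(abs(fit.params["s_e"] - C_E))
            errs[n] = np.mean(errors)
        assert errs[3000] < errs[500]

    def test_likelihood_ascent_history(self):
        pooled, scores = _planted_dataset(800, seed=5)
        fit = CircularPhaseGLM.from_dataframe(pooled, scores).fit()
        hist = np.array(fit.criterion_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_rotation_equivariance(self):
        pooled, scores = _planted_dataset(800, seed=9)
        model = CircularPhaseGLM.from_dataframe(pooled, scores)
        fit = model.fit()
        delta = 5.0
        shifted = CircularPhaseGLM(
            wrap_ct(model.endog_ct + delta), model.exog, exog_names=model.exog_names
        )
        fit2 = shifted.fit()
        assert abs((fit2.mu_ct - fit.mu_ct - delta + 12) % 24 - 12) < 1e-4
        np.testing.assert_allclose(fit2.coefs, fit.coefs, atol=1e-4)
        assert fit2.kappa == pytest.approx(fit.kappa, abs=1e-6)

    def test_kappa_consistent_with_residual_resultant(self):
        pooled, scores = _planted_dataset(1000, seed=13)
        model = CircularPhaseGLM.from_dataframe(pooled, scores)
        fit = model.fit()
        resid = model.theta - (fit.mu_rad + 2 * np.arctan(model.exog @ fit.coefs))
        rbar = float(np.cos(resid).mean())
        assert i1e(fit.kappa) / i0e(fit.kappa) == pytest.approx(rbar, abs=1e-8)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 5"):
            CircularPhaseGLM(np.array([1.0, 2.0]), np.zeros((2, 3)))

    def test_summary_mentions_parameters(self):
        pooled, scores = _planted_dataset(300, seed=17)
        fit = CircularPhaseGLM.from_dataframe(pooled, scores).fit()
        text = fit.summary()
        for token in ("mu_ct", "s_e", "kappa", "log-likelihood"):
            assert token in text


class TestPredictPhase:
    def _fixed_fit(self):
        pooled, scores = _planted_dataset(300, seed=23)
        model = CircularPhaseGLM.from_dataframe(pooled, scores)
        fit = model.fit()
        object.__setattr__(fit, "mu_rad", float(ct_to_radians(MU_CT)))
        object.__setattr__(fit, "coefs", np.array([C_E, C_D, C_RRE]))
        return fit

    def test_zero_scores_give_mu(self):
        fit = self._fixed_fit()
        assert predict_phase(fit, 0, 0, 0) == pytest.approx(MU_CT)

    def test_ebox_only_peaks_before_dusk(self):
        # published coefficients place a pure E-box gene near CT 9.2
        fit = self._fixed_fit()
        expected = (MU_CT + 12 / np.pi * 2 * np.arctan(C_E)) % 24
        got = predict_phase(fit, 1, 0, 0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(9.2, abs=0.1)

    def test_dbox_rre_peaks_at_dawn(self):
        fit = self._fixed_fit()
        expected = (MU_CT + 12 / np.pi * 2 * np.arctan(C_D + C_RRE)) % 24
        got = predict_phase(fit, 0, 1, 1)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.2, abs=0.1)

    def test_prediction_bounded_within_half_cycle(self):
        fit = self._fixed_fit()
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = rng.random(3)
            pred = predict_phase(fit, *s)
            diff = abs((pred - MU_CT + 12) % 24 - 12)
            assert diff < 12.0


class TestRayleigh:
    def test_identical_phases(self):
        direction, rbar, p = rayleigh_test([6.0] * 10)
        assert rbar == pytest.approx(1.0)
        assert direction == pytest.approx(6.0)
        assert p < 1e-3

    def test_quadrant_symmetry(self):
        _, rbar, p = rayleigh_test([0.0, 6.0, 12.0, 18.0])
        assert rbar == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_needs_two_phases(self):
        with pytest.raises(ValueError):
            rayleigh_test([1.0])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(99)
        n, reps = 100, 1000
        rejections = 0
        for _ in range(reps):
            phases = rng.uniform(0, 24, size=n)
            _, _, p = rayleigh_test(phases)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        phases = wrap_ct(rng.vonmises(1.0, 0.8, size=60) * 12 / np.pi)
        _, _, p = rayleigh_test(phases)
        # pingouin applies Zar's variant of the correction; the two
        # approximations agree closely but not identically
        z, p_ref = pingouin.circ_rayleigh(ct_to_radians(phases))
        assert p == pytest.approx(p_ref, rel=0.02)


class TestCircularMedianAndCombos:
    def test_median_simple(self):
        assert circular_median_ct([1.0, 2.0, 3.0]) == 2.0

    def test_median_wraps(self):
        # cluster straddling midnight: 23, 0, 1 -> median 0
        assert circular_median_ct([23.0, 0.0, 1.0]) == 0.0

    def test_combo_labels(self, registry):
        ids = registry.dataset_ids
        values = np.zeros((3, len(registry)), dtype=np.int8)
        values[0, ids.index("cho_reverba")] = 1
        values[1, ids.index("koike_clock")] = 1
        values[1, ids.index("fang_e4bp4")] = 1
        hm = HitMatrix(("rre_only", "ebox_dbox", "nothing"), ids, values)
        obs = pd.DataFrame(
            {
                "gene_id": ["rre_only", "ebox_dbox", "nothing"],
                "tissue": ["liver"] * 3,
                "phase_ct": [0.0, 12.0, 5.0],
            }
        )
        summary = tf_combo_summary(hm, registry, obs)
        combos = dict(zip(summary["combo"], summary["n"]))
        assert combos == {"rre": 1, "ebox+dbox": 1, "none": 1}

    def test_simulated_group_medians(self, registry):
        """E-box-only genes planted around CT12 and RRE-only around CT0 are
        summarized within +/- 1 h of their planted medians."""
        ids = registry.dataset_ids
        rng = np.random.default_rng(8)
        n_each = 40
        values = np.zeros((2 * n_each, len(registry)), dtype=np.int8)
        values[:n_each, ids.index("koike_bmal1")] = 1
        values[n_each:, ids.index("cho_reverba")] = 1
        genes = tuple(f"e{i}" for i in range(n_each)) + tuple(f"r{i}" for i in range(n_each))
        hm = HitMatrix(genes, ids, values)
        kappa = 3.0
        phases = np.concatenate(
            [
                (rng.vonmises(ct_to_radians(12.0), kappa, n_each) * 12 / np.pi) % 24,
                (rng.vonmises(0.0, kappa, n_each) * 12 / np.pi) % 24,
            ]
        )
        obs = pd.DataFrame({"gene_id": genes, "tissue": "liver", "phase_ct": phases})
        summary = tf_combo_summary(hm, registry, obs).set_index("combo")
        med_e = summary.loc["ebox", "median_phase_ct"]
        med_r = summary.loc["rre", "median_phase_ct"]
        assert abs((med_e - 12 + 12) % 24 - 12) < 1.0
        assert abs((med_r - 0 + 12) % 24 - 12) < 1.0
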