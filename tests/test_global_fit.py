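import numpy as np
import pytest
from dataclasses import replace

from exokin.forward_sim import TitrationProtocol, PulseChaseProtocol, make_band_table, simulate_timecourse, simulate_pulse_chase
from exokin.global_fit import (
    ConstraintSpec,
    Dataset,
    PerLengthParameterization,
    compute_chi2,
    compute_r2,
    global_fit,
    profile_bounds,
    propagate_khalf_sigma,
    propagate_p_sigma,
)
from exokin.kinetic_scheme import RateSet, StepRates, build_scheme
from conftest import random_scheme


def _random_tables(rng, n=30):
    keys = [("d", 50.0, float(t), int(n_)) for t in range(1, 6) for n_ in (8, 7, 6)]
    obs = make_band_table([k + (rng.uniform(0, 1),) for k in keys])
    pred = make_band_table([k + (rng.uniform(0, 1),) for k in keys])
    return obs, pred


class TestChi2:
    def test_identical_tables_give_zero(self):
        rng = np.random.default_rng(0)
        obs, _ = _random_tables(rng)
        assert compute_chi2(obs, obs) == 0.0

    def test_single_band_squared_residual(self):
        obs = make_band_table([("d", 50.0, 10.0, 7, 0.6)])
        pred = make_band_table([("d", 50.0, 10.0, 7, 0.5)])
        assert compute_chi2(obs, pred) == pytest.approx(0.01, abs=1e-15)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            obs, pred = _random_tables(rng)
            naive = 0.0
            for _, row in obs.iterrows():
                match = pred[
                    (pred["dataset_id"] == row["dataset_id"])
                    & (pred["enzyme_conc_nM"] == row["enzyme_conc_nM"])
                    & (pred["time_s"] == row["time_s"])
                    & (pred["species_length_nt"] == row["species_length_nt"])
                ]
                naive += (row["fraction"] - float(match["fraction"].iloc[0])) ** 2
            assert compute_chi2(obs, pred) == pytest.approx(naive, rel=1e-12)

    def test_mismatched_keys_error(self):
        rng = np.random.default_rng(1)
        obs, pred = _random_tables(rng)
        with pytest.raises(ValueError, match="mismatched"):
            compute_chi2(obs, pred.iloc[:-1])


class TestR2:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(2)
        obs, _ = _random_tables(rng)
        assert compute_r2(obs, obs) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self):
        rng = np.random.default_rng(3)
        obs, _ = _random_tables(rng)
        pred = obs.copy()
        pred["fraction"] = obs["fraction"].mean()
        assert compute_r2(obs, pred) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        obs, pred = _random_tables(rng)
        y = obs["fraction"].to_numpy()
        yhat = pred["fraction"].to_numpy()
        expected = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert compute_r2(obs, pred) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_is_nan(self):
        obs = make_band_table([("d", 1.0, float(t), 7, 0.5) for t in range(1, 5)])
        assert np.isnan(compute_r2(obs, obs))


class TestErrorPropagation:
    def test_khalf_formula_values(self):
        assert propagate_khalf_sigma(100.0, 1.0, 0.03, 0.01, 0.0004) == pytest.approx(5.0)
        assert propagate_khalf_sigma(50.0, 0.5, 0.0, 0.01, 0.0) == 0.0

    def test_khalf_homogeneity(self):
        a = propagate_khalf_sigma(100.0, 1.0, 0.03, 0.01, 0.0004)
        b = propagate_khalf_sigma(100.0, 1.0, 0.06, 0.01, 0.0008)
        assert b == pytest.approx(2 * a)

    def test_p_formula_values(self):
        assert propagate_p_sigma(0.5, 1.0, 0.1, 1.0, 0.1) == pytest.approx(0.25 * np.sqrt(0.02))
        assert propagate_p_sigma(0.5, 1.0, 0.0, 1.0, 0.0) == 0.0

    def test_p_vanishes_at_certainty(self):
        for p in (0.0, 1.0):
            assert propagate_p_sigma(p, 1.0, 0.5, 1.0, 0.5) == 0.0

    @pytest.mark.parametrize("rel_koff,rel_kon", [(0.03, 0.04), (0.1, 0.05)])
    def test_khalf_against_monte_carlo(self, rel_koff, rel_kon):
        rng = np.random.default_rng(17)
        koff, kon = 0.5, 0.001
        n = 1_000_000
        draws = (koff + rng.normal(0, rel_koff * koff, n)) / (kon + rng.normal(0, rel_kon * kon, n))
        mc = draws.std()
        formula = propagate_khalf_sigma(koff / kon, koff, rel_koff * koff, kon, rel_kon * kon)
        assert formula == pytest.approx(mc, rel=0.01)

    @pytest.mark.parametrize("p_true,rel", [(0.23, 0.05), (0.5, 0.1), (0.8, 0.03)])
    def test_p_against_monte_carlo(self, p_true, rel):
        rng = np.random.default_rng(23)
        kf = 1.0
        koff = kf * (1 - p_true) / p_true
        n = 1_000_000
        kf_d = kf + rng.normal(0, rel * kf, n)
        koff_d = koff + rng.normal(0, rel * koff, n)
        mc = (kf_d / (kf_d + koff_d)).std()
        formula = propagate_p_sigma(p_true, kf, rel * kf, koff, rel * koff)
        assert formula == pytest.approx(mc, rel=0.01)


def _noise_free_datasets(scheme, concs=(5.0, 25.0, 100.0, 500.0)):
    prot = TitrationProtocol(enzyme_concs=concs, times=(5.0, 15.0, 40.0, 100.0, 250.0, 600.0, 1500.0))
    return [Dataset(simulate_timecourse(scheme, prot), prot)], prot


class TestGlobalFit:
    def test_noise_free_recovery_random_small_schemes(self):
        """All identifiable per-length rates recovered within 1% without noise."""
        rng = np.random.default_rng(31)
        n_ok = 0
        for trial in range(3):
            scheme = random_scheme(rng, n_cleavable=int(rng.integers(2, 4)), nonproductive=False)
            datasets, _ = _noise_free_datasets(scheme)
            # start from a perturbed template
            steps = {
                int(n): StepRates(
                    kon_p=scheme.rates[int(n)].kon_p * 2.5,
                    koff_p=scheme.rates[int(n)].koff_p * 0.4,
                    kf=scheme.rates[int(n)].kf * 3.0,
                )
                for n in scheme.ladder.cleavable_lengths
            }
            template = build_scheme(scheme.ladder.full_length, scheme.ladder.product_length, RateSet(steps))
            fit = global_fit(datasets, template, seed=trial, n_starts=4, jitter=0.5)
            assert fit.converged
            for name, true_val in _true_values(scheme).items():
                assert fit.params[name] == pytest.approx(true_val, rel=0.01), name
            n_ok += 1
        assert n_ok == 3

    def test_null_nonproductive_pathway_is_gauge_redundant(self):
        """Data generated without NP binding need no distinct NP kinetics.

        Band-level observation of a single length cannot distinguish one
        bound state from a split into two: the fit reaches chi2 ~ 0 and the
        gauge-invariant combinations (total association rate, effective
        cleavage flux) reproduce the generating productive-only values,
        confirming the extra pathway adds nothing.
        """
        truth = build_scheme(7, 6, RateSet({7: StepRates(kon_p=2e-3, koff_p=0.05, kf=0.02)}))
        datasets, _ = _noise_free_datasets(truth)
        template = build_scheme(
            7, 6, RateSet({7: StepRates(kon_p=1e-3, koff_p=0.02, kf=0.05, kon_np=1e-3, koff_np=0.02)})
        )
        fit = global_fit(datasets, template, seed=0)
        assert fit.chi2 < 1e-12
        kon_tot = fit.params["kon_p[7]"] + fit.params["kon_np[7]"]
        kf_eff = fit.params["kf[7]"] * fit.params["kon_p[7]"] / kon_tot
        assert kon_tot == pytest.approx(2e-3, rel=1e-3)
        assert kf_eff == pytest.approx(0.02, rel=1e-3)

    def test_chi2_trace_non_increasing_with_blocks(self, three_length_scheme):
        datasets, _ = _noise_free_datasets(three_length_scheme, concs=(25.0, 250.0))
        steps = {
            int(n): replace(three_length_scheme.rates[int(n)],
                            kf=three_length_scheme.rates[int(n)].kf * 2.0)
            for n in three_length_scheme.ladder.cleavable_lengths
        }
        template = build_scheme(8, 6, RateSet(steps))
        par = PerLengthParameterization(template)
        blocks = [[nm for nm in par.names if nm.startswith("kf")],
                  [nm for nm in par.names if not nm.startswith("kf")]]
        fit = global_fit(datasets, template, ConstraintSpec(blocks=blocks), seed=0,
                         parameterization=par)
        trace = np.asarray(fit.chi2_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert fit.chi2 < 1e-10

    def test_khalf_link_is_honored(self, one_step_scheme):
        datasets, _ = _noise_free_datasets(one_step_scheme)
        khalf = one_step_scheme.rates[7].koff_p / one_step_scheme.rates[7].kon_p
        template = build_scheme(7, 6, RateSet({7: StepRates(kon_p=5e-4, koff_p=khalf * 5e-4, kf=0.1)}))
        constraints = ConstraintSpec(khalf_links={7: khalf})
        fit = global_fit(datasets, template, constraints, seed=0)
        assert "koff_p[7]" not in fit.params
        s = fit.scheme.rates[7]
        assert s.koff_p / s.kon_p == pytest.approx(khalf, rel=1e-9)
        assert s.kf == pytest.approx(one_step_scheme.rates[7].kf, rel=0.01)

    def test_kf_bounds_enforced(self, one_step_scheme):
        datasets, _ = _noise_free_datasets(one_step_scheme)
        template = build_scheme(7, 6, RateSet({7: StepRates(kon_p=1e-3, koff_p=0.03, kf=0.009)}))
        constraints = ConstraintSpec(kf_bounds={7: (0.001, 0.01)})  # true kf = 0.02 outside
        fit = global_fit(datasets, template, constraints, seed=0)
        assert fit.params["kf[7]"] <= 0.01 + 1e-9

    def test_requires_a_titration_dataset(self, one_step_scheme):
        prot = PulseChaseProtocol(enzyme_conc=50.0, prechase_times=(180.0,),
                                  postchase_times=(240.0,))
        tab = simulate_pulse_chase(one_step_scheme, prot)
        with pytest.raises(ValueError, match="titration"):
            global_fit([Dataset(tab, prot)], one_step_scheme, seed=0)


def _true_values(scheme):
    out = {}
    for n in scheme.ladder.cleavable_lengths:
        s = scheme.rates[int(n)]
        out[f"kon_p[{int(n)}]"] = s.kon_p
        out[f"koff_p[{int(n)}]"] = s.koff_p
        out[f"kf[{int(n)}]"] = s.kf
    return out


@pytest.fixture(scope="module")
def converged_fit():
    truth = build_scheme(7, 6, RateSet({7: StepRates(kon_p=2e-3, koff_p=0.05, kf=0.02)}))
    prot = TitrationProtocol(enzyme_concs=(10.0, 100.0), times=(5.0, 20.0, 60.0, 200.0, 600.0))
    rng = np.random.default_rng(9)
    tab = simulate_timecourse(truth, prot)
    tab = tab.assign(fraction=np.clip(tab["fraction"] + rng.normal(0, 0.01, len(tab)), 0, 1))
    template = build_scheme(7, 6, RateSet({7: StepRates(kon_p=1e-3, koff_p=0.02, kf=0.05)}))
    return global_fit([Dataset(tab, prot)], template, seed=1)


class TestProfileBounds:
    def test_interval_contains_point_estimate(self, converged_fit):
        for name in converged_fit.params:
            lo, hi = profile_bounds(converged_fit, name, n_grid=12, max_decades=2.0)
            assert lo <= converged_fit.params[name] <= hi, name

    def test_width_shrinks_with_noise(self):
        truth = build_scheme(7, 6, RateSet({7: StepRates(kon_p=2e-3, koff_p=0.05, kf=0.02)}))
        prot = TitrationProtocol(enzyme_concs=(10.0, 100.0), times=(5.0, 20.0, 60.0, 200.0, 600.0))
        widths = []
        for sigma in (0.02, 0.002):
            rng = np.random.default_rng(33)
            tab = simulate_timecourse(truth, prot)
            tab = tab.assign(fraction=np.clip(tab["fraction"] + rng.normal(0, sigma, len(tab)), 0, 1))
            fit = global_fit([Dataset(tab, prot)], truth, seed=2)
            lo, hi = profile_bounds(fit, "kf[7]", n_grid=15, max_decades=2.0)
            widths.append(np.log(hi) - np.log(lo))
        assert widths[1] < widths[0]

    def test_uninformative_parameter_unbounded(self):
        """A rate with no influence on the observed window is unbounded."""
        truth = build_scheme(
            8, 6,
            RateSet({8: StepRates(kon_p=2e-3, koff_p=0.05, kf=0.02),
                     7: StepRates(kon_p=1e-3, koff_p=1e-8, kf=10.0)}),
        )
        # dissociation at length 7 loses to cleavage by 10^9: koff_p[7] has
        # no measurable leverage anywhere in the scanned range
        prot = TitrationProtocol(enzyme_concs=(25.0,), times=(10.0, 50.0, 200.0, 800.0))
        tab = simulate_timecourse(truth, prot)
        par = PerLengthParameterization(truth, float_names=["kf[8]", "koff_p[7]"])
        fit = global_fit([Dataset(tab, prot)], truth, seed=0, parameterization=par)
        lo, hi = profile_bounds(fit, "koff_p[7]", n_grid=10, max_decades=2.0)
        assert np.isinf(hi)
        assert lo == 0.0
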