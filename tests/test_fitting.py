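"""Objective construction, global fitting, determinism and identifiability."""

import numpy as np
import pytest

from cx36mg import (
    FitDataset,
    FitEntry,
    GatingModelFitter,
    fit_global,
    get_scheme,
    objective,
    simulate_pair,
    sse,
    symmetric_protocol,
    trace_summary,
)
from cx36mg.synthetic import _recovery_bounds, generate_recovery_suite


class TestSse:
    def test_perfect_fit_is_zero(self):
        assert sse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        assert sse([1.0, 2.0], [0.0, 0.0]) == 5.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            sse([1.0, 2.0], [1.0])

    def test_expected_value_under_iid_noise(self, rng):
        """SSE of a noisy series against its noiseless counterpart
        concentrates around n * sigma^2."""
        n, sigma = 300, 0.02
        curve = np.linspace(1.0, 0.3, n)
        values = [
            sse(curve + rng.normal(0.0, sigma, n), curve) for _ in range(100)
        ]
        assert np.mean(values) == pytest.approx(n * sigma**2, rel=0.05)


@pytest.fixture(scope="module")
def noiseless_dataset(wt):
    dataset, _ = generate_recovery_suite(wt, sigma=0.0, n_replicates=1, seed=3)
    return dataset


class TestObjective:
    def test_self_consistency_at_generating_parameters(self, wt, noiseless_dataset):
        assert objective(wt, "Model 5, Hill", noiseless_dataset) < 1e-8

    def test_invariant_to_trace_ordering(self, wt, noiseless_dataset):
        reversed_ds = FitDataset(
            entries=list(reversed(noiseless_dataset.entries)),
            variant=noiseless_dataset.variant,
        )
        a = objective(wt, "Model 5, Hill", noiseless_dataset)
        b = objective(wt, "Model 5, Hill", reversed_ds)
        assert a == pytest.approx(b, abs=1e-15)

    def test_suppressing_binding_worsens_fit_of_responsive_data(
        self, wt, noiseless_dataset
    ):
        no_binding = wt.replace(k3=1e-6)
        assert objective(no_binding, "Model 5, Hill", noiseless_dataset) > 10 * (
            objective(wt, "Model 5, Hill", noiseless_dataset) + 1e-12
        )


class TestDatasetValidation:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            FitDataset(entries=[])

    def test_invalid_channel_rejected(self, wt, model5_hill):
        trace = simulate_pair(model5_hill, wt, symmetric_protocol(5.0))
        with pytest.raises(ValueError):
            FitEntry(trace=trace, protocol=symmetric_protocol(5.0), channels=("volts",))

    def test_fi_channel_dropped_when_trace_has_no_fluorescence(
        self, wt, model5_hill
    ):
        protocol = symmetric_protocol(5.0)
        trace = simulate_pair(model5_hill, wt, protocol)
        trace.fi_norm = None
        entry = FitEntry(trace=trace, protocol=protocol, channels=("gj", "fi"))
        assert entry.channels == ("gj",)


class TestGlobalFit:
    def test_noiseless_recovery_of_identifiable_quantities(self, wt, model5_hill,
                                                           noiseless_dataset):
        """On noise-free data the fit drives SSE to numerical zero and pins
        the identifiable quantities: Hill coefficient, unbinding rate,
        permeability, and the effective binding rate k3*k1/(k1+k2)."""
        fitter = GatingModelFitter(
            scheme=model5_hill,
            bounds=_recovery_bounds(wt, model5_hill),
            n_restarts=3,
            random_state=3,
        )
        fitter.fit(noiseless_dataset)
        assert fitter.sse_ < 1e-6
        p = fitter.params_
        assert p.n == pytest.approx(wt.n, rel=0.01)
        assert p.k4 == pytest.approx(wt.k4, rel=0.01)
        assert p.p == pytest.approx(wt.p, rel=0.01)
        combo = p.k3 * p.k1 / (p.k1 + p.k2)
        assert combo == pytest.approx(wt.k3 * wt.k1 / (wt.k1 + wt.k2), rel=0.01)

    def test_same_seed_reproduces_fit_exactly(self, wt, model5_hill,
                                              noiseless_dataset):
        kwargs = dict(
            scheme=model5_hill,
            bounds=_recovery_bounds(wt, model5_hill),
            n_restarts=2,
            random_state=11,
            max_nfev=40,
        )
        first = GatingModelFitter(**kwargs).fit(noiseless_dataset)
        second = GatingModelFitter(**kwargs).fit(noiseless_dataset)
        assert first.params_ == second.params_
        assert first.sse_ == second.sse_
        assert np.array_equal(first.restart_sse_, second.restart_sse_)

    def test_reported_sse_is_best_of_restarts(self, wt, model5_hill,
                                              noiseless_dataset):
        fitter = GatingModelFitter(
            scheme=model5_hill,
            bounds=_recovery_bounds(wt, model5_hill),
            n_restarts=3,
            random_state=3,
        ).fit(noiseless_dataset)
        finite = fitter.restart_sse_[np.isfinite(fitter.restart_sse_)]
        assert fitter.sse_ == finite.min()

    def test_fit_global_wrapper_matches_estimator(self, wt, model5_hill,
                                                  noiseless_dataset):
        result = fit_global(
            model5_hill, noiseless_dataset,
            bounds=_recovery_bounds(wt, model5_hill),
            seed=11, n_restarts=2, max_nfev=40,
        )
        est = GatingModelFitter(
            scheme=model5_hill, bounds=_recovery_bounds(wt, model5_hill),
            n_restarts=2, random_state=11, max_nfev=40,
        ).fit(noiseless_dataset)
        assert result.params == est.params_
        assert result.k_params == 6
        assert result.n_points == noiseless_dataset.n_points()

    def test_hill_fit_never_worse_than_nested_mass_action(self, wt):
        """On data generated with genuine cooperativity (n = 1.5), the Hill
        scheme contains the mass-action scheme, so its best SSE cannot be
        higher at a matched restart budget."""
        truth = wt.replace(n=1.5)
        dataset, _ = generate_recovery_suite(truth, sigma=0.0, n_replicates=1, seed=4)
        hill = GatingModelFitter(
            "Model 5, Hill",
            bounds=_recovery_bounds(truth, get_scheme("Model 5, Hill")),
            n_restarts=3, random_state=4,
        ).fit(dataset)
        mass = GatingModelFitter(
            "Model 5",
            bounds=_recovery_bounds(truth, get_scheme("Model 5")),
            n_restarts=3, random_state=4,
        ).fit(dataset)
        assert hill.sse_ <= mass.sse_ + 1e-10

    def test_flat_binding_profile_reports_near_zero_k3(self, wt):
        """For data with no Mg2+ response the fitter must land on a
        negligible binding rate, not an arbitrary interior value: the
        fitted k3/k4 stays >100-fold below the responsive (wild-type)
        ratio, and the implied Mg2+-response index is ~1."""
        scheme = get_scheme("Model 5")
        truth = wt.replace(k3=0.0, n=1.0)
        dataset, _ = generate_recovery_suite(
            truth, scheme=scheme, sigma=0.02, n_replicates=2, seed=5
        )
        bounds = {
            "k1": (wt.k1 * 0.99, wt.k1 * 1.01),
            "k2": (wt.k2 * 0.99, wt.k2 * 1.01),
            "k3": (1e-8, 10.0),
            "k4": (wt.k4 * 0.1, wt.k4 * 10),
            "p": (wt.p * 0.1, wt.p * 10),
        }
        fitter = GatingModelFitter(
            scheme, bounds=bounds, n_restarts=3, random_state=5
        ).fit(dataset)
        assert fitter.params_.k3 / fitter.params_.k4 < (wt.k3 / wt.k4) / 100.0
        refit_trace = simulate_pair(scheme, fitter.params_, symmetric_protocol(5.0))
        assert trace_summary(refit_trace)["gj_ss_over_init"] == pytest.approx(1.0, abs=0.01)

    def test_predict_simulates_fitted_model(self, wt, model5_hill,
                                            noiseless_dataset):
        fitter = GatingModelFitter(
            scheme=model5_hill,
            bounds=_recovery_bounds(wt, model5_hill),
            n_restarts=2, random_state=3, max_nfev=60,
        ).fit(noiseless_dataset)
        protocol = symmetric_protocol(5.0)
        predicted = fitter.predict(protocol)
        truth_trace = simulate_pair(model5_hill, wt, protocol)
        assert np.max(np.abs(predicted.gj_norm - truth_trace.gj_norm)) < 0.01

    def test_sklearn_param_round_trip(self):
        fitter = GatingModelFitter(n_restarts=7, random_state=3)
        clone_params = fitter.get_params()
        assert clone_params["n_restarts"] == 7
        fitter.set_params(n_restarts=9)
        assert fitter.n_restarts == 9
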