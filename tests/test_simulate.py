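"""Synthetic-cohort generator: distributional targets, noise, determinism."""

import numpy as np
import pytest

from hdlturnover import (CohortSpec, ValidationError, fcr_closed_form,
                         fcr_from_biexponential, fit_biexponential,
                         mann_whitney_exact, sample_cohort, simulate_decay,
                         solve_model, subclass_fractions, synth_densitogram)
from hdlturnover.simulate import (gel_calibration,
                                  lognormal_sigma, truth_record)


def _point_mass_spec(seed, n=1):
    """Spec whose every target has q1 = q3 = median (no between-animal
    spread), for the degenerate-sigma path."""
    fcr = {g: (m, m, m) for g, (m, _, _) in CohortSpec(seed=0)
           .fcr_targets.items()}
    lipids = {g: {k: (m, m, m) for k, (m, _, _) in targets.items()}
              for g, targets in CohortSpec(seed=0).lipid_targets.items()}
    return CohortSpec(seed=seed, n_per_group=n, noise_cv=0.0,
                      fcr_targets=fcr, lipid_targets=lipids,
                      densitogram_resolution=60)


class TestSampleCohort:
    def test_median_converges_to_target(self):
        # Log-normal draws matched to median/IQR: at n = 10,000 per group
        # the sample medians of the true FCR land within 2% of the group
        # targets and the quartiles near the target IQRs.
        spec = CohortSpec(seed=3, n_per_group=10_000,
                          densitogram_resolution=50)
        cohort = sample_cohort(spec)
        sham = np.array([a.true_fcr_per_hour for a in cohort
                         if a.group == "sham"])
        ntx = np.array([a.true_fcr_per_hour for a in cohort
                        if a.group == "ntx"])
        assert np.median(sham) == pytest.approx(0.24, rel=0.02)
        assert np.median(ntx) == pytest.approx(0.14, rel=0.02)
        q1, q3 = np.percentile(sham, [25, 75])
        assert q1 == pytest.approx(0.17, rel=0.05)
        assert q3 == pytest.approx(0.36, rel=0.05)

    def test_point_mass_targets_reproduce_medians(self):
        cohort = sample_cohort(_point_mass_spec(seed=1))
        sham = next(a for a in cohort if a.group == "sham")
        assert sham.true_fcr_per_hour == pytest.approx(0.24, rel=1e-12)
        assert sham.hdl_panel.ce == pytest.approx(0.59, rel=1e-12)
        assert sham.hdl_panel.ph == pytest.approx(0.84, rel=1e-12)

    def test_same_seed_identical_cohort(self):
        spec = CohortSpec(seed=11, n_per_group=2, densitogram_resolution=60)
        a = [truth_record(x) for x in sample_cohort(spec)]
        b = [truth_record(x) for x in sample_cohort(spec)]
        assert a == b

    def test_different_seeds_differ(self):
        a = sample_cohort(CohortSpec(seed=1, n_per_group=2,
                                     densitogram_resolution=60))
        b = sample_cohort(CohortSpec(seed=2, n_per_group=2,
                                     densitogram_resolution=60))
        assert a[0].true_fcr_per_hour != b[0].true_fcr_per_hour

    def test_body_weights_in_protocol_range(self):
        cohort = sample_cohort(CohortSpec(seed=5, n_per_group=4,
                                          densitogram_resolution=60))
        for animal in cohort:
            assert 3.0 <= animal.body_weight_kg <= 3.5

    def test_inverted_quartiles_rejected(self):
        with pytest.raises(ValidationError):
            lognormal_sigma(0.36, 0.17)

    def test_curves_satisfy_normalization_contract(self):
        cohort = sample_cohort(CohortSpec(seed=8, n_per_group=3,
                                          densitogram_resolution=60))
        for animal in cohort:
            assert animal.curve.hdl_activity[0] == 100.0
            assert animal.curve.vldl_activity[0] == 0.0
            assert np.all(animal.curve.vldl_activity >= 0)


class TestSimulateDecay:
    def test_noiseless_equals_model_solution(self, sham_rates, study_times):
        curve = simulate_decay(sham_rates, cv=0.0)
        truth = solve_model(sham_rates, study_times)
        np.testing.assert_array_equal(curve.times, truth.times)
        np.testing.assert_allclose(curve.hdl_activity, truth.hdl_activity,
                                   rtol=1e-12)
        np.testing.assert_allclose(curve.vldl_activity, truth.vldl_activity,
                                   rtol=1e-12)

    def test_activities_never_negative_even_at_high_noise(self, sham_rates):
        rng = np.random.default_rng(17)
        for _ in range(50):
            curve = simulate_decay(sham_rates, cv=0.5, rng=rng)
            assert np.all(curve.hdl_activity >= 0)
            assert np.all(curve.vldl_activity >= 0)

    def test_poisson_mode(self, sham_rates):
        curve = simulate_decay(sham_rates, noise_model="poisson",
                               rng=np.random.default_rng(23))
        assert curve.hdl_activity[0] == 100.0
        # counting noise at 1e6 cpm dose is sub-percent
        truth = solve_model(sham_rates, curve.times)
        np.testing.assert_allclose(curve.hdl_activity[1:],
                                   truth.hdl_activity[1:], rtol=0.02)

    def test_median_fcr_recovery_end_to_end(self, sham_rates):
        # 200 seeded noisy studies at the default 3% CV.  The slow decay
        # phase sits at the edge of identifiability within the 5-hour
        # sampling window, which biases the biexponential route's median
        # FCR upward by about +11% at these conditions (measured; see the
        # methods note) — the two-pool route, tested separately, is
        # unbiased.  Asserted at the documented 15% envelope, and upward:
        # the route must not collapse toward zero.
        truth = fcr_closed_form(sham_rates)
        rng = np.random.default_rng(123)
        estimates = []
        for i in range(200):
            curve = simulate_decay(sham_rates, cv=0.03, rng=rng)
            params, _ = fit_biexponential(curve, seed=i)
            estimates.append(fcr_from_biexponential(params))
        median = np.median(estimates)
        assert truth * 0.95 < median < truth * 1.15


class TestSynthDensitogram:
    def test_equal_fractions_roundtrip(self):
        d = synth_densitogram([0.2] * 5, "total cholesterol")
        recovered = subclass_fractions(d, gel_calibration()).fractions
        np.testing.assert_allclose(recovered, 0.2, atol=0.01)

    def test_single_component(self):
        d = synth_densitogram([0, 0, 0, 0, 1], "triglycerides")
        recovered = subclass_fractions(d, gel_calibration()).fractions
        assert recovered[-1] > 0.98  # all mass in HDL 3c

    def test_deterministic(self):
        a = synth_densitogram([0.3, 0.2, 0.2, 0.2, 0.1], "phospholipids")
        b = synth_densitogram([0.3, 0.2, 0.2, 0.2, 0.1], "phospholipids")
        np.testing.assert_array_equal(a.signal, b.signal)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_resolution_floor(self):
        with pytest.raises(ValidationError):
            synth_densitogram([0.2] * 5, "protein", resolution=49)


class TestCohortContrast:
    def test_group_contrast_detection_rate(self):
        # Power check documented with its exact seeds: cohorts 0..39 at the
        # default study conditions (n = 6/6, 3% CV, published median/IQR
        # targets).  The published IQRs overlap substantially, which caps
        # the attainable Mann-Whitney power near 0.3 at this sample size;
        # the assertion is that the FCR contrast is detected well above
        # the 5% false-positive rate, with the measured rate recorded in
        # the methods note.
        hits = 0
        n_cohorts = 40
        for seed in range(n_cohorts):
            cohort = sample_cohort(CohortSpec(
                seed=seed, densitogram_resolution=60))
            fcr = {"sham": [], "ntx": []}
            for a in cohort:
                params, _ = fit_biexponential(a.curve, seed=seed)
                fcr[a.group].append(fcr_from_biexponential(params))
            res = mann_whitney_exact(fcr["sham"], fcr["ntx"])
            hits += res.p_two_sided < 0.05
        assert hits / n_cohorts >= 0.15
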