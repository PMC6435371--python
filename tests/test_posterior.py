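"""Posterior analyses: retrieval, equivalence, prior correction, zones."""

import numpy as np
import pytest

from sanod import (
    Chronograms,
    ComponentSet,
    Dataset,
    MockConfig,
    SANODConfig,
    SpectralAxis,
    TimeAxis,
    artifact_components_from_negative_delays,
    assemble_components,
    chronogram_equivalence_check,
    correct_prior_from_residual,
    detect_stationary_zones,
    generate_sequential_with_heating,
    generate_xfel_scenario,
    lcf_fit,
    retrieve_physical_spectrum,
    run_sanod,
    zone_spectra,
)
from sanod.benchmarks import _grid_search_beta
from sanod.metrics import cosine_similarity, pearson_r2


@pytest.fixture(scope="module")
def xfel():
    ds, truth = generate_xfel_scenario(MockConfig.xfel(seed=3))
    artifacts = artifact_components_from_negative_delays(ds, -2e-12, n=2)
    with pytest.warns(UserWarning, match="discarded"):
        result = run_sanod(ds, artifacts, SANODConfig(n_svd_components=3))
    target = [l for l in result.retained_labels() if l not in artifacts.labels][0]
    return ds, truth, artifacts, result, target


class TestRetrievePhysicalSpectrum:
    def test_orthogonal_chronograms_give_zero_mixing(self, rng):
        n = 20
        axis = SpectralAxis(np.arange(n, dtype=float))
        C = rng.normal(size=(n, 2))
        alpha = np.vstack([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, 1.0, 1.0]])  # orthogonal rows
        ds = Dataset(axis, TimeAxis(np.arange(4.0)), C @ alpha)
        comps = ComponentSet(axis, C, ("art", "target"), ("prior", "svd_global"))
        fit = lcf_fit(ds, comps)
        spectrum, betas = retrieve_physical_spectrum(fit, "target", ["art"])
        assert betas["art"] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(spectrum, C[:, 1], atol=1e-10)

    def test_recovers_true_heating_spectrum(self, xfel):
        _, truth, artifacts, result, target = xfel
        spectrum, _ = retrieve_physical_spectrum(result, target, artifacts.labels)
        cos = cosine_similarity(spectrum, truth.components.column("heating"), signless=True)
        assert cos > 0.99

    def test_mixing_matches_grid_search(self, xfel):
        _, _, artifacts, result, target = xfel
        _, betas = retrieve_physical_spectrum(result, target, artifacts.labels)
        alpha_t = result.chronograms.row(target)
        for label, beta in betas.items():
            oracle = _grid_search_beta(result.chronograms.row(label), alpha_t)
            assert abs(beta - oracle) < 1e-6

    def test_fixed_point_under_refit(self, xfel):
        ds, _, artifacts, result, target = xfel
        spectrum, _ = retrieve_physical_spectrum(result, target, artifacts.labels)
        comps = ComponentSet(
            ds.axis,
            np.column_stack([artifacts.matrix, spectrum]),
            artifacts.labels + ("physical",),
            artifacts.provenance + ("derived",),
        )
        refit = lcf_fit(ds, comps)
        _, betas2 = retrieve_physical_spectrum(refit, "physical", artifacts.labels)
        assert all(abs(b) < 1e-9 for b in betas2.values())

    def test_zero_target_chronogram_rejected(self, rng):
        n = 10
        axis = SpectralAxis(np.arange(n, dtype=float))
        C = rng.normal(size=(n, 2))
        ds = Dataset(axis, TimeAxis(np.arange(4.0)),
                     np.outer(C[:, 0], np.ones(4)))
        comps = ComponentSet(axis, C, ("art", "target"), ("prior", "svd_global"))
        fit = lcf_fit(ds, comps)
        fit.chronograms.weights[1, :] = 0.0
        with pytest.raises(ValueError, match="zero"):
            retrieve_physical_spectrum(fit, "target", ["art"])


class TestChronogramEquivalence:
    def test_in_span_candidate_is_identical(self, xfel):
        ds, _, artifacts, result, target = xfel
        u1 = result.components.column(target)
        candidate = u1 + 0.3 * artifacts.matrix[:, 0] - 0.2 * artifacts.matrix[:, 1]
        assert chronogram_equivalence_check(ds, artifacts, candidate, u1) < 1e-6

    def test_out_of_span_perturbation_grows_monotonically(self, xfel):
        ds, truth, artifacts, result, target = xfel
        u1 = result.components.column(target)
        basis = np.column_stack([artifacts.matrix, u1])
        q, _ = np.linalg.qr(basis)
        rng = np.random.default_rng(0)
        probe = rng.normal(size=len(u1))
        probe -= q @ (q.T @ probe)
        probe /= np.linalg.norm(probe)
        diffs = [
            chronogram_equivalence_check(ds, artifacts, u1 + eps * probe, u1)
            for eps in (0.0, 0.05, 0.1, 0.2)
        ]
        assert all(a < b for a, b in zip(diffs, diffs[1:]))

    def test_zero_data_gives_zero_chronograms(self, rng):
        n = 15
        axis = SpectralAxis(np.arange(n, dtype=float))
        artifacts = ComponentSet(axis, rng.normal(size=(n, 2)), ("a1", "a2"), ("prior",) * 2)
        ds = Dataset(axis, TimeAxis(np.arange(5.0)), np.zeros((n, 5)))
        u = rng.normal(size=n)
        assert chronogram_equivalence_check(ds, artifacts, u, u) == 0.0


class TestCorrectPrior:
    def distorted_case(self, seed, amount):
        ds, truth = generate_xfel_scenario(MockConfig.xfel(seed=seed))
        q = ds.axis.values
        bump = np.exp(-((q - 5.0) ** 2) / (2 * 0.4**2))
        bump /= np.linalg.norm(bump)
        heating = truth.components.column("heating")
        distorted = heating + amount * bump
        comps = ComponentSet(
            ds.axis,
            np.column_stack([truth.components.matrix[:, :2], distorted]),
            ("artifact1", "artifact2", "heating_prior"),
            ("prior", "prior", "prior"),
        )
        fit = lcf_fit(ds, comps)
        return ds, truth, comps, fit, heating

    def test_distorted_prior_corrected(self):
        _, truth, _, fit, heating = self.distorted_case(seed=0, amount=0.2)
        before = cosine_similarity(fit.components.column("heating_prior"), heating,
                                   signless=True)
        corrected = correct_prior_from_residual(fit, "heating_prior")
        after = cosine_similarity(corrected.spectrum, heating, signless=True)
        assert corrected.applied
        assert before < 0.99
        assert after > 0.99

    def test_correction_does_not_increase_misfit(self):
        ds, _, comps, fit, _ = self.distorted_case(seed=1, amount=0.2)
        corrected = correct_prior_from_residual(fit, "heating_prior")
        refit_comps = ComponentSet(
            ds.axis,
            np.column_stack([comps.matrix[:, :2], corrected.spectrum]),
            comps.labels,
            comps.provenance,
        )
        refit = lcf_fit(ds, refit_comps)
        assert refit.total_misfit <= fit.total_misfit

    def test_undistorted_prior_returned_unchanged(self):
        _, _, _, fit, _ = self.distorted_case(seed=2, amount=0.0)
        corrected = correct_prior_from_residual(fit, "heating_prior")
        assert not corrected.applied
        assert corrected.gamma == 0.0
        assert np.array_equal(corrected.spectrum, fit.components.column("heating_prior"))

    def test_gamma_grows_with_distortion(self):
        gammas = []
        for amount in (0.0, 0.1, 0.2, 0.3):
            _, _, _, fit, _ = self.distorted_case(seed=3, amount=amount)
            gammas.append(abs(correct_prior_from_residual(fit, "heating_prior").gamma))
        assert gammas[0] == 0.0
        assert all(a < b for a, b in zip(gammas, gammas[1:]))


class TestStationaryZones:
    def make_chronograms(self, rows, times=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        t = times if times is not None else np.arange(rows.shape[1], dtype=float)
        return Chronograms(TimeAxis(t), rows, tuple(f"c{i}" for i in range(rows.shape[0])))

    def test_two_plateaus_detected(self):
        ramp = np.concatenate([np.zeros(10), np.linspace(0, 1, 10), np.ones(10)])
        zones = detect_stationary_zones(self.make_chronograms(ramp))
        assert len(zones) == 2
        assert zones[0].start_index == 0
        assert zones[1].end_index == 29
        assert all(z.flatness < 0.05 for z in zones)

    def test_monotone_ramp_has_no_zone(self):
        zones = detect_stationary_zones(self.make_chronograms(np.linspace(0, 1, 30)))
        assert zones == []

    def test_window_larger_than_axis_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_stationary_zones(self.make_chronograms(np.arange(4.0)), window=5)

    def test_zero_dynamic_range_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            detect_stationary_zones(self.make_chronograms(np.ones(10)))

    def test_affine_rescaling_invariance(self, rng):
        rows = np.vstack([
            np.concatenate([np.zeros(10), np.linspace(0, 1, 10), np.ones(10)]),
            np.concatenate([np.ones(10), np.linspace(1, 0, 10), np.zeros(10)]),
        ])
        a = detect_stationary_zones(self.make_chronograms(rows))
        b = detect_stationary_zones(self.make_chronograms(rows * 37.0 - 5.0))
        assert [(z.start_index, z.end_index) for z in a] == [
            (z.start_index, z.end_index) for z in b
        ]

    def test_excluded_monotone_background_unmasks_zones(self):
        plateau = np.concatenate([np.zeros(10), np.linspace(0, 1, 10), np.ones(10)])
        drift = np.linspace(0, 1, 30)
        chron = Chronograms(TimeAxis(np.arange(30.0)), np.vstack([plateau, drift]),
                            ("species", "heating"))
        assert detect_stationary_zones(chron) == []
        zones = detect_stationary_zones(chron, exclude_labels=["heating"])
        assert len(zones) == 2

    def test_kinetics_scenario_has_two_zones(self):
        ds, truth = generate_sequential_with_heating(MockConfig.sequential(seed=0))
        result = run_sanod(ds, truth.component_set(["heating"]),
                           SANODConfig(n_svd_components=2))
        zones = detect_stationary_zones(result.chronograms, exclude_labels=["heating"])
        assert len(zones) == 2
        # one plateau between the kinetic steps, one after completion
        assert 1e-11 < zones[0].start_time < 1e-9
        assert zones[1].end_time == pytest.approx(ds.times.delays[-1])


@pytest.fixture(scope="module")
def fitted():
    ds, truth = generate_sequential_with_heating(MockConfig.sequential(seed=0))
    result = run_sanod(ds, truth.component_set(["heating"]),
                       SANODConfig(n_svd_components=2))
    zones = detect_stationary_zones(result.chronograms, exclude_labels=["heating"])
    return ds, truth, result, zones


class TestZoneSpectra:
    def test_plateau_spectrum_matches_species(self, fitted):
        # with the heating contribution removed exactly (true-component fit)
        # a plateau's averaged curve is the spectrum of the species present
        ds, truth, result, zones = fitted
        exact = lcf_fit(ds, truth.components)
        spectra = zone_spectra(ds, exact, zones, solvent_labels=["heating"])
        cos = cosine_similarity(
            spectra.column("zone1"), truth.components.column("intermediate2"), signless=True
        )
        assert cos > 0.99

    def test_width_one_zone_is_single_cleaned_column(self, fitted):
        ds, truth, result, zones = fitted
        one = [z for z in zones][:1]
        from sanod.posterior import StationaryZone

        z = StationaryZone(one[0].start_index, one[0].start_index,
                           one[0].start_time, one[0].start_time, 0.0)
        spectra = zone_spectra(ds, result, [z], solvent_labels=["heating"])
        j = z.start_index
        expected = ds.signal[:, j] - result.components.column("heating") * \
            result.chronograms.row("heating")[j]
        assert np.allclose(spectra.matrix[:, 0], expected, atol=1e-12)

    def test_refit_round_trip_recovers_chronograms(self, fitted):
        ds, truth, result, zones = fitted
        spectra = zone_spectra(ds, result, zones[-2:], solvent_labels=["heating"])
        comps = assemble_components(truth.component_set(["heating"]), spectra)
        refit = lcf_fit(ds, comps)
        assert pearson_r2(refit.chronograms.row("zone1"),
                          truth.chronograms.row("intermediate2")) >= 0.98
        assert pearson_r2(refit.chronograms.row("zone2"),
                          truth.chronograms.row("product")) >= 0.98

    def test_empty_zone_list_rejected(self, fitted):
        ds, _, result, _ = fitted
        with pytest.raises(ValueError, match="empty"):
            zone_spectra(ds, result, [], solvent_labels=["heating"])
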