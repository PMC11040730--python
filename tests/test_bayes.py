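"""Joint model, posterior sampling, pruning, and the deconvolution loop."""

import numpy as np
import pytest

import nmrdeconv.bayes as bayes_mod
from nmrdeconv import (
    CompoundSpectrum,
    FitResult,
    NoSurvivorsError,
    PriorConfig,
    Resonance,
    SamplerConfig,
    Spectrum,
    build_joint_model,
    deconvolute,
    make_grid,
    prune_candidates,
    render_mixture,
    render_spectrum,
    sample_posterior,
)
from nmrdeconv.bayes import prepare_observed

FAST = dict(warmup=250, samples=400, fit_grid_points=1024, max_depth=6)


def _fit(library, observed, seed=1, **kw):
    cfg = SamplerConfig(seed=seed, **{**FAST, **kw})
    processed = prepare_observed(observed, cfg.broaden_fwhm_hz, cfg.fit_grid_points)
    model = build_joint_model(library, processed)
    return sample_posterior(model, cfg)


class TestSelfFit:
    def test_single_compound_recovers_own_shifts(self):
        comp = CompoundSpectrum(
            "solo", [Resonance(2.5, 1.0), Resonance(6.5, 2.0)], shift_sigma=0.05
        )
        obs = render_spectrum(comp, make_grid())
        fit = _fit([comp], obs)
        np.testing.assert_allclose(
            fit.shift_posterior_mean, [2.5, 6.5], atol=0.01
        )

    def test_two_compound_mixture_center(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.7, 0.3], make_grid())
        fit = _fit(two_compound_library, obs)
        np.testing.assert_allclose(fit.center, [0.7, 0.3], atol=0.02)

    def test_absent_candidate_gets_negligible_weight(self, two_compound_library):
        ghost = CompoundSpectrum("ghost", [Resonance(5.0, 2.0)], shift_sigma=0.05)
        obs = render_mixture(two_compound_library, [0.6, 0.4], make_grid())
        fit = _fit(two_compound_library + [ghost], obs)
        assert fit.center[2] < 0.05

    def test_posterior_contraction_of_shifts(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.5, 0.5], make_grid())
        fit = _fit(two_compound_library, obs)
        assert np.all(fit.shift_posterior_sd <= fit.res_prior_sd)


class TestDeterminismAndInvariance:
    def test_same_seed_identical_draws(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.7, 0.3], make_grid())
        f1 = _fit(two_compound_library, obs, seed=42)
        f2 = _fit(two_compound_library, obs, seed=42)
        np.testing.assert_array_equal(f1.weight_samples, f2.weight_samples)
        np.testing.assert_array_equal(f1.shift_samples, f2.shift_samples)

    def test_intensity_scale_invariance(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.7, 0.3], make_grid())
        scaled = Spectrum(obs.grid, 7.0 * obs.intensity, obs.spectrometer_mhz)
        f1 = _fit(two_compound_library, obs, seed=3)
        f2 = _fit(two_compound_library, scaled, seed=3)
        # both sides are normalised to densities; agreement is limited only by
        # rounding of the rescaled intensities amplified through the chaotic
        # Hamiltonian trajectories, i.e. Monte-Carlo precision
        np.testing.assert_allclose(f1.center, f2.center, atol=0.01)

    def test_library_permutation_permutes_center(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.7, 0.3], make_grid())
        fwd = _fit(two_compound_library, obs, seed=5)
        rev = _fit(list(reversed(two_compound_library)), obs, seed=5)
        np.testing.assert_allclose(fwd.center, rev.center[::-1], atol=0.03)


class TestPrune:
    def _result(self, names, center):
        lib = [
            CompoundSpectrum(n, [Resonance(1.0 + i)], 0.1)
            for i, n in enumerate(names)
        ]
        z = np.zeros((1, len(names)))
        return FitResult(
            names=list(names), library=lib, weight_samples=z + 1, shift_samples=z,
            center=np.asarray(center), shift_posterior_mean=np.zeros(len(names)),
            shift_posterior_sd=np.zeros(len(names)),
            res_compound=np.arange(len(names)), res_prior_mean=np.zeros(len(names)),
            res_prior_sd=np.full(len(names), 0.1),
        )

    def test_below_cutoff_removed(self):
        fit = self._result(["a", "b", "c"], [0.6, 0.38, 0.02])
        assert [c.name for c in prune_candidates(fit, 0.05)] == ["a", "b"]

    def test_all_above_cutoff_kept(self):
        fit = self._result(["a", "b"], [0.5, 0.5])
        assert [c.name for c in prune_candidates(fit, 0.05)] == ["a", "b"]

    def test_no_survivors_raises(self):
        fit = self._result(["a", "b"], [0.01, 0.02])
        with pytest.raises(NoSurvivorsError):
            prune_candidates(fit, 0.05)


class TestDeconvolute:
    def test_all_present_converges_in_one_iteration(self, two_compound_library):
        obs = render_mixture(two_compound_library, [0.6, 0.4], make_grid())
        cfg = SamplerConfig(seed=2, **FAST)
        fit = deconvolute(two_compound_library, obs, cutoff=0.05, cfg=cfg)
        assert fit.converged
        assert list(fit.present) == [True, True]
        assert len([h for h in fit.history if h["stage"] == "global"]) == 1
        np.testing.assert_allclose(fit.center_full, [0.6, 0.4], atol=0.03)

    def test_absent_candidates_pruned_and_zeroed(self, two_compound_library):
        ghost = CompoundSpectrum("ghost", [Resonance(5.0, 2.0)], shift_sigma=0.05)
        lib = two_compound_library + [ghost]
        obs = render_mixture(two_compound_library, [0.6, 0.4], make_grid())
        cfg = SamplerConfig(seed=2, **FAST)
        fit = deconvolute(lib, obs, cutoff=0.05, cfg=cfg)
        assert list(fit.present) == [True, True, False]
        assert fit.center_full[2] == 0.0
        np.testing.assert_allclose(fit.center_full[:2], [0.6, 0.4], atol=0.03)

    def test_three_equal_components(self):
        lib = [
            CompoundSpectrum(f"c{i}", [Resonance(1.5 + 3 * i, 1.0)], 0.05)
            for i in range(3)
        ]
        obs = render_mixture(lib, np.full(3, 1 / 3), make_grid())
        cfg = SamplerConfig(seed=7, **FAST)
        fit = deconvolute(lib, obs, cutoff=0.05, cfg=cfg)
        np.testing.assert_allclose(fit.center_full, 1 / 3, atol=0.03)

    def test_zero_spectrum_is_rejected(self, two_compound_library):
        grid = make_grid(0, 10, 4096)
        empty = Spectrum(grid, np.zeros_like(grid))
        with pytest.raises(ValueError, match="empty spectrum"):
            deconvolute(two_compound_library, empty, cfg=SamplerConfig(seed=0, **FAST))

    def test_nonuniform_grid_rejected(self, two_compound_library):
        grid = np.concatenate([np.linspace(0, 5, 100), np.linspace(5.5, 10, 50)])
        spec = Spectrum(grid, np.ones_like(grid))
        with pytest.raises(ValueError, match="uniform"):
            build_joint_model(two_compound_library, spec)


class TestWideningHeuristic:
    def _fake_results(self, library, sds):
        """Sequence of canned fits with controlled shift-posterior spreads."""
        nres = sum(len(c.resonances) for c in library)

        def make(sd_value, scale):
            n = len(library)
            z = np.full((4, n), 1.0 / n)
            return FitResult(
                names=[c.name for c in library], library=list(library),
                weight_samples=z, shift_samples=np.zeros((4, nres)),
                center=np.full(n, 1.0 / n),
                shift_posterior_mean=np.zeros(nres),
                shift_posterior_sd=np.full(nres, sd_value),
                res_compound=np.zeros(nres, dtype=int),
                res_prior_mean=np.zeros(nres),
                res_prior_sd=np.full(nres, 0.1 * scale),
                diagnostics={"divergences": 0},
            )

        return make

    def test_poor_shift_fit_triggers_one_widened_iteration(
        self, two_compound_library, monkeypatch
    ):
        make = self._fake_results(two_compound_library, None)
        calls = []

        def fake_sample(model, cfg):
            scale = model.priors.shift_sigma_scale
            calls.append(scale)
            # first fit: spreads at 3x the prior sd -> trigger; later fits tight
            sd = 0.3 if len(calls) == 1 else 0.01
            return make(sd, scale)

        monkeypatch.setattr(bayes_mod, "sample_posterior", fake_sample)
        obs = render_mixture(two_compound_library, [0.5, 0.5], make_grid(0, 10, 4096))
        fit = deconvolute(
            two_compound_library, obs, cfg=SamplerConfig(seed=0, warmup=1, samples=1)
        )
        # base fit, then exactly one widened (3x priors) fit, then convergence
        assert calls == [1.0, 3.0]
        assert fit.converged
        scales = [h["shift_sigma_scale"] for h in fit.history]
        assert scales == [1.0, 3.0]


class TestIntervalMode:
    def test_highfield_interval_eliminates_absent_candidates(self):
        # two candidates resonate only above 8 ppm but are absent from the
        # mixture; the entropy-ranked high-field interval removes them first
        absent = [
            CompoundSpectrum("ald", [Resonance(9.3, 1.0), Resonance(2.2, 2.0)], 0.05),
            CompoundSpectrum("acid", [Resonance(9.7, 1.0), Resonance(2.6, 2.0)], 0.05),
        ]
        present = [
            CompoundSpectrum("keto", [Resonance(1.2, 2.0), Resonance(4.6, 1.0)], 0.05),
            CompoundSpectrum("alc", [Resonance(0.9, 2.0), Resonance(3.6, 1.0)], 0.05),
        ]
        obs = render_mixture(present, [0.6, 0.4], make_grid())
        cfg = SamplerConfig(seed=4, **FAST)
        fit = deconvolute(absent + present, obs, cutoff=0.05, cfg=cfg, interval_mode=True)
        assert list(fit.present) == [False, False, True, True]
        stages = [h for h in fit.history if h["stage"] == "interval"]
        assert stages, "interval fits should be recorded"
        pruned_in_intervals = {n for h in stages for n in h["pruned"]}
        assert {"ald", "acid"} <= pruned_in_intervals
        np.testing.assert_allclose(fit.center_full, [0, 0, 0.6, 0.4], atol=0.05)
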