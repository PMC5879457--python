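"""Model fitting: recovery, degeneracies, equivariances, bootstrap."""

import numpy as np
import pytest

from fotmech.impedance import ImpedanceSpectrum, RESpectra
from fotmech.mechfit import (
    bootstrap_ci,
    fit_animal,
    fit_elastance,
    fit_group_mean,
    fit_resistance,
    predict_spectra,
)
from fotmech.synthetic_data import (
    DEFAULT_FREQUENCIES,
    MechParams,
    impedance_of,
    synthesize_waveform,
)
from fotmech.impedance import estimate_impedance

FREQS = np.asarray(DEFAULT_FREQUENCIES)


def spectrum_for(params: MechParams, freqs=FREQS) -> RESpectra:
    return predict_spectra(params, freqs)


class TestPredictSpectra:
    def test_resistance_limits(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        s = predict_spectra(p, [0.0, 5.0, 1e9])
        assert s.rl[0] == pytest.approx(0.4)        # a/c
        assert s.rl[1] == pytest.approx(0.3)        # (2+1)/10
        assert s.rl[2] == pytest.approx(0.2, rel=1e-6)  # -> b

    def test_elastance_values(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        s = predict_spectra(p, [0.0, 2.0])
        assert s.el[0] == pytest.approx(20.0)
        assert s.el[1] == pytest.approx(20 + 10 * (1 - np.exp(-1.0)))
        assert s.el[1] == pytest.approx(26.3212, abs=1e-4)

    def test_zero_de_gives_flat_elastance(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=0.0, beta=0.5)
        s = predict_spectra(p, FREQS)
        assert np.allclose(s.el, 20.0)


class TestFitResistance:
    def test_noiseless_exact_recovery(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        fit = fit_resistance(spectrum_for(p))
        assert fit.converged and fit.rss < 1e-12
        for name, truth in (("a", 2.0), ("b", 0.2), ("c", 5.0)):
            assert abs(fit[name] / truth - 1) < 1e-4

    def test_constant_spectrum_hits_degenerate_ridge(self):
        s = RESpectra(freqs=FREQS, rl=np.full(FREQS.size, 0.35), el=np.zeros(FREQS.size))
        fit = fit_resistance(s)
        assert fit.rss == pytest.approx(0.0, abs=1e-15)
        assert fit["a"] / fit["c"] == pytest.approx(0.35, rel=1e-6)
        assert fit["b"] == pytest.approx(0.35, rel=1e-6)
        assert any("degenerate" in w or "ill-conditioned" in w for w in fit.warnings)

    def test_median_bias_of_low_freq_resistance_small_under_noise(self):
        # Monte-Carlo recovery: 2% absolute noise on RL, many replicates
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        rl_true = spectrum_for(p).rl
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(300):
            s = RESpectra(freqs=FREQS, rl=rl_true + rng.normal(0, 0.02, FREQS.size),
                          el=np.zeros(FREQS.size))
            fit = fit_resistance(s)
            ratios.append((fit["a"] / fit["c"]) / p.a_over_c)
        assert abs(np.median(ratios) - 1) < 0.02

    def test_requires_four_distinct_frequencies(self):
        s = RESpectra(freqs=np.array([1.0, 2.0, 3.0]), rl=np.ones(3), el=np.zeros(3))
        with pytest.raises(ValueError):
            fit_resistance(s)

    def test_scale_equivariance(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        s = spectrum_for(p)
        k = 3.0
        scaled = RESpectra(freqs=s.freqs, rl=k * s.rl, el=s.el)
        fit = fit_resistance(scaled)
        assert fit["a"] == pytest.approx(k * 2.0, rel=1e-5)
        assert fit["b"] == pytest.approx(k * 0.2, rel=1e-5)
        assert fit["c"] == pytest.approx(5.0, rel=1e-5)


class TestFitElastance:
    def test_noiseless_exact_recovery(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        fit = fit_elastance(spectrum_for(p))
        assert fit.converged and fit.rss < 1e-12
        for name, truth in (("e0", 20.0), ("de", 10.0), ("beta", 0.5)):
            assert abs(fit[name] / truth - 1) < 1e-4

    def test_flat_elastance_reports_degenerate_de(self):
        s = RESpectra(freqs=FREQS, rl=np.ones(FREQS.size), el=np.full(FREQS.size, 18.0))
        fit = fit_elastance(s)
        assert fit["e0"] == pytest.approx(18.0, rel=1e-6)
        assert abs(fit["de"]) < 1e-5 * fit["e0"] or any("degenerate" in w for w in fit.warnings)

    def test_huge_beta_flags_weak_identification(self):
        # beta >> 1/f_min: the exponential has decayed below the first
        # frequency, so only the plateau E0 + dE is identified and the fit
        # must say so rather than return a confident beta
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=25.0)
        fit = fit_elastance(spectrum_for(p))
        assert fit["e0"] + fit["de"] == pytest.approx(30.0, rel=1e-3)
        assert any("ill-conditioned" in w for w in fit.warnings)

    def test_scale_equivariance(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        s = spectrum_for(p)
        k = 2.5
        scaled = RESpectra(freqs=s.freqs, rl=s.rl, el=k * s.el)
        fit = fit_elastance(scaled)
        assert fit["e0"] == pytest.approx(k * 20.0, rel=1e-5)
        assert fit["de"] == pytest.approx(k * 10.0, rel=1e-5)
        assert fit["beta"] == pytest.approx(0.5, rel=1e-5)


class TestModelShapeInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_rl_monotonicity_matches_sign_of_bc_minus_a(self, seed):
        rng = np.random.default_rng(seed)
        p = MechParams(
            a=rng.uniform(0.5, 4), b=rng.uniform(0.01, 1), c=rng.uniform(1, 10),
            e0=rng.uniform(10, 40), de=rng.uniform(1, 20), beta=rng.uniform(0.1, 2),
        )
        f = np.linspace(0, 30, 500)
        rl = predict_spectra(p, f).rl
        drl = np.diff(rl)
        if p.b * p.c < p.a:
            assert np.all(drl < 0)
        elif p.b * p.c > p.a:
            assert np.all(drl > 0)

    def test_el_monotone_and_bounded_for_positive_de(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        f = np.linspace(0, 100, 1000)
        el = predict_spectra(p, f).el
        assert np.all(np.diff(el) >= 0)
        assert el[-1] <= 30.0 + 1e-9
        assert predict_spectra(p, [1e9]).el[0] == pytest.approx(30.0)


class TestGridSearchOracle:
    def test_nls_dominates_dense_grid_under_noise(self):
        """The NLS optimum must beat-or-match every point of a dense log grid."""
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        rng = np.random.default_rng(8)
        s = RESpectra(
            freqs=FREQS,
            rl=predict_spectra(p, FREQS).rl + rng.normal(0, 0.02, FREQS.size),
            el=np.zeros(FREQS.size),
        )
        rfit = fit_resistance(s)
        grid = np.exp(np.linspace(np.log(0.25), np.log(4.0), 25))
        best_grid = min(
            float(np.sum(((ga + gb * FREQS) / (gc + FREQS) - s.rl) ** 2))
            for ga in 2.0 * grid for gb in 0.2 * grid for gc in 5.0 * grid
        )
        assert rfit.rss <= best_grid + 1e-12

    def test_nls_lands_within_grid_resolution_on_noiseless_instance(self):
        p = MechParams(a=2, b=0.2, c=5, e0=20, de=10, beta=0.5)
        s = spectrum_for(p)
        rfit = fit_resistance(s)
        efit = fit_elastance(s)
        grid = np.exp(np.linspace(np.log(0.25), np.log(4.0), 25))
        step = np.log(grid[1] / grid[0])
        # resistance: grid over (a, b, c)
        best = min(
            ((float(np.sum(((ga + gb * FREQS) / (gc + FREQS) - s.rl) ** 2))), (ga, gb, gc))
            for ga in 2.0 * grid for gb in 0.2 * grid for gc in 5.0 * grid
        )
        for got, gbest in zip(rfit.values, best[1]):
            assert abs(np.log(got / gbest)) <= step + 1e-9
        # elastance: grid over (e0, de, log beta)
        best_e = min(
            ((float(np.sum((ge + gd * (1 - np.exp(-gb * FREQS)) - s.el) ** 2))), (ge, gd, gb))
            for ge in 20.0 * grid for gd in 10.0 * grid for gb in 0.5 * grid
        )
        for got, gbest in zip(efit.values, best_e[1]):
            assert abs(np.log(got / gbest)) <= step + 1e-9


class TestFitAnimal:
    def test_end_to_end_noiseless_pipeline_recovery(self, base_params):
        rec = synthesize_waveform(
            base_params, peep=3.0, noise_sd=0.0, rng=np.random.default_rng(5)
        )
        spec = estimate_impedance(rec, DEFAULT_FREQUENCIES)
        fit = fit_animal(spec)
        for name, truth in base_params.as_dict().items():
            assert abs(fit.params.as_dict()[name] / truth - 1) < 1e-3
        assert fit.derived["low_freq_resistance"] == fit.params.a / fit.params.c

    def test_survives_one_dropped_frequency(self, base_params):
        z = impedance_of(base_params, FREQS)
        coh = np.ones(FREQS.size)
        coh[4] = 0.2
        spec = ImpedanceSpectrum(
            animal_id="x", peep=3.0, freqs=FREQS, z_re=z.real, z_im=z.imag, coherence=coh
        )
        fit = fit_animal(spec, coherence_threshold=0.9)
        assert fit.n_freqs == 12
        assert fit.converged

    def test_identical_spectra_give_identical_fits(self, base_params):
        z = impedance_of(base_params, FREQS)
        mk = lambda: ImpedanceSpectrum(
            animal_id="x", peep=3.0, freqs=FREQS, z_re=z.real, z_im=z.imag,
            coherence=np.ones(FREQS.size),
        )
        f1, f2 = fit_animal(mk()), fit_animal(mk())
        assert f1.params.as_dict() == f2.params.as_dict()

    def test_group_mean_fit_recovers_shared_truth(self, base_params):
        rng = np.random.default_rng(3)
        specs = []
        for _ in range(4):
            s = predict_spectra(base_params, FREQS)
            specs.append(RESpectra(freqs=FREQS, rl=s.rl + rng.normal(0, 0.01, FREQS.size),
                                   el=s.el + rng.normal(0, 0.2, FREQS.size)))
        fit = fit_group_mean(specs)
        assert abs(fit.params.e0 / 20.0 - 1) < 0.02
        assert abs(fit.params.a_over_c / 0.4 - 1) < 0.05


class TestBootstrap:
    def test_noiseless_intervals_have_zero_width(self, base_params):
        ci = bootstrap_ci(spectrum_for(base_params), n_boot=100, rng=np.random.default_rng(0))
        for lo, hi in ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_small_n_boot_rejected(self, base_params):
        with pytest.raises(ValueError):
            bootstrap_ci(spectrum_for(base_params), n_boot=99)

    def test_interval_covers_truth_on_a_noisy_instance(self, base_params):
        rng = np.random.default_rng(12)
        s = predict_spectra(base_params, FREQS)
        noisy = RESpectra(freqs=FREQS, rl=s.rl + rng.normal(0, 0.01, FREQS.size),
                          el=s.el + rng.normal(0, 0.3, FREQS.size))
        ci = bootstrap_ci(noisy, n_boot=200, rng=rng)
        lo, hi = ci["a_over_c"]
        assert lo < base_params.a_over_c < hi
        assert 0 < hi - lo < 0.2
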