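"""Trace normalization and exponential-decay fitting."""

import math

import numpy as np
import pytest

from scramblekit import assay, fitting, synthetic
from scramblekit.errors import InputError
from scramblekit.types import AssayParams, FluorescenceTrace, ModelSolution

LN2 = math.log(2)


def biexp_trace(plateau, a_fast, t_half_fast, a_slow, t_half_slow,
                t_max=2500.0, dt=1.0, noise_sd=0.0, seed=0):
    sol = ModelSolution(
        plateau=plateau,
        amplitudes=(a_fast, a_slow),
        rates=(LN2 / t_half_fast, LN2 / t_half_slow),
    )
    t = np.arange(0.0, t_max + dt / 2, dt)
    y = sol(t)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.shape)
    return FluorescenceTrace(times_s=t, intensity=y, normalized=True)


class TestNormalize:
    def test_pre_addition_mean_becomes_one(self):
        t = np.arange(-30.0, 300.0, 1.0)
        raw = FluorescenceTrace(
            times_s=t, intensity=np.where(t < 0, 2.0, 2.0 * np.exp(-0.05 * t)),
            probe_addition_time_s=0.0,
        )
        norm = fitting.normalize_trace(raw)
        assert norm.intensity[norm.pre_addition].mean() == pytest.approx(1.0)
        assert norm.probe_addition_time_s == 0.0

    def test_idempotent(self):
        t = np.arange(-30.0, 300.0, 1.0)
        raw = FluorescenceTrace(
            times_s=t, intensity=np.where(t < 0, 1.0, np.exp(-0.05 * t)),
        )
        once = fitting.normalize_trace(raw)
        twice = fitting.normalize_trace(once)
        np.testing.assert_allclose(twice.intensity, once.intensity)

    def test_amplitude_rescaling_invariance(self):
        # fitting after normalization must not depend on raw signal amplitude
        t = np.arange(-50.0, 1500.0, 1.0)
        p = AssayParams(probe="dithionite", k_probe=LN2 / 12)
        fits = []
        for baseline in (1.0, 7.3):
            raw = synthetic.generate_assay_trace(
                p, t, probe_addition_time_s=0.0, baseline=baseline
            )
            fit = fitting.fit_decay(fitting.normalize_trace(raw), "mono")
            fits.append(fit)
        assert fits[0].rates[0] == pytest.approx(fits[1].rates[0], rel=1e-9)
        assert fits[0].plateau == pytest.approx(fits[1].plateau, abs=1e-9)

    def test_known_noisy_baseline_recovers_model_plateau(self):
        p = AssayParams(probe="dithionite", k_probe=LN2 / 12,
                        fraction_active=0.6, k_scramble=0.02)
        t = np.arange(-60.0, 1200.0, 1.0)
        noise = 0.01
        raw = synthetic.generate_assay_trace(
            p, t, noise_sd=noise, seed=7, baseline=3.0
        )
        fit = fitting.fit_decay(fitting.normalize_trace(raw), "bi")
        assert fit.converged
        assert abs(fit.plateau - assay.plateau(p)) < 2 * noise

    def test_no_pre_addition_samples_is_an_error(self):
        tr = FluorescenceTrace(times_s=np.arange(5.0), intensity=np.ones(5))
        with pytest.raises(InputError):
            fitting.normalize_trace(tr)


class TestFitDecay:
    def test_noiseless_mono_recovers_12s_half_time(self):
        t = np.arange(0.0, 400.0, 0.5)
        tr = FluorescenceTrace(
            times_s=t, intensity=0.5 + 0.5 * np.exp(-(LN2 / 12) * t),
            normalized=True,
        )
        fit = fitting.fit_decay(tr, "mono")
        assert fit.converged
        assert fit.half_times_s[0] == pytest.approx(12.0, rel=1e-6)
        assert fit.plateau == pytest.approx(0.5, abs=1e-6)

    def test_noiseless_biexponential_recovers_both_half_times(self):
        tr = biexp_trace(0.1, 0.55, 12.0, 0.35, 400.0)
        fit = fitting.fit_decay(tr, "bi")
        assert fit.converged
        assert fit.half_times_s[0] == pytest.approx(12.0, rel=1e-6)
        assert fit.half_times_s[1] == pytest.approx(400.0, rel=1e-6)
        assert fit.plateau == pytest.approx(0.1, abs=1e-6)

    def test_amplitudes_sum_with_plateau_to_f0(self):
        tr = biexp_trace(0.2, 0.5, 20.0, 0.3, 300.0)
        fit = fitting.fit_decay(tr, "bi")
        assert fit.plateau + sum(fit.amplitudes) == pytest.approx(1.0, abs=1e-6)

    def test_half_time_labels_are_ordered_fast_slow(self):
        tr = biexp_trace(0.15, 0.4, 30.0, 0.45, 90.0, noise_sd=0.01)
        fit = fitting.fit_decay(tr, "bi")
        assert fit.half_times_s[0] <= fit.half_times_s[1]
        assert fit.rates[0] >= fit.rates[1]

    def test_mono_fit_of_degenerate_biexponential(self):
        # a "biexponential" with zero second amplitude is the same trace
        t = np.arange(0.0, 600.0, 1.0)
        y = 0.5 + 0.5 * np.exp(-(LN2 / 40) * t)
        tr1 = FluorescenceTrace(times_s=t, intensity=y, normalized=True)
        sol = ModelSolution(plateau=0.5, amplitudes=(0.5, 0.0),
                            rates=(LN2 / 40, LN2 / 400))
        tr2 = FluorescenceTrace(times_s=t, intensity=sol(t), normalized=True)
        f1 = fitting.fit_decay(tr1, "mono")
        f2 = fitting.fit_decay(tr2, "mono")
        assert f1.rates[0] == pytest.approx(f2.rates[0], rel=1e-9)

    def test_too_short_trace_flags_not_raises(self):
        tr = FluorescenceTrace(times_s=np.arange(3.0), intensity=np.ones(3),
                               normalized=True)
        fit = fitting.fit_decay(tr, "bi")
        assert not fit.converged

    def test_eigenrate_back_mapping(self):
        kp, ks = LN2 / 12, 0.0018
        fast, slow = assay.eigenrates(kp, ks)
        tr = biexp_trace(0.0, 0.6, LN2 / fast, 0.4, LN2 / slow)
        kp_hat, ks_hat = fitting.scramble_rate_from_fit(fitting.fit_decay(tr, "bi"))
        assert kp_hat == pytest.approx(kp, rel=1e-6)
        assert ks_hat == pytest.approx(ks, rel=1e-6)


class TestClassify:
    def _fit_for(self, fa, seed=0, noise=0.005):
        p = AssayParams(probe="dithionite", k_probe=LN2 / 12,
                        fraction_active=fa, k_scramble=0.01)
        t = np.arange(0.0, 1500.0, 1.0)
        tr = synthetic.generate_assay_trace(p, t, noise_sd=noise, seed=seed)
        return fitting.fit_decay(tr, "bi" if fa > 0 else "mono")

    def test_identical_fits_are_negative(self):
        ref = self._fit_for(0.0)
        v = fitting.classify_scrambling(ref, ref)
        assert v["verdict"] == "scrambling-negative"
        assert v["loss_difference"] == pytest.approx(0.0)

    def test_printed_proteoliposome_vs_liposome_losses(self):
        # plateau losses 0.73 vs 0.53: 20-point difference, clearly positive
        mk = lambda plat, model: fitting.FitResult(
            model=model, plateau=plat, amplitudes=(1 - plat,),
            rates=(0.05,), half_times_s=(LN2 / 0.05,),
            residual_rms=0.0, converged=True,
        )
        v = fitting.classify_scrambling(mk(0.27, "bi"), mk(0.47, "mono"))
        assert v["verdict"] == "scrambling-positive"
        assert v["loss_difference"] == pytest.approx(0.20)

    def test_verdict_flips_exactly_at_margin(self):
        ref = self._fit_for(0.0, noise=0.0)
        test = self._fit_for(0.30, noise=0.0)
        diff = (1 - test.plateau) - (1 - ref.plateau)
        below = fitting.classify_scrambling(test, ref, margin=diff + 1e-6)
        above = fitting.classify_scrambling(test, ref, margin=diff - 1e-6)
        assert below["verdict"] == "scrambling-negative"
        assert above["verdict"] == "scrambling-positive"

    def test_fraction_active_estimate_round_trips(self):
        ref = self._fit_for(0.0, noise=0.0)
        test = self._fit_for(0.5, noise=0.0)
        v = fitting.classify_scrambling(test, ref)
        assert v["fraction_active"] == pytest.approx(0.5, abs=0.02)

    def test_unconverged_input_rejected(self):
        ok = self._fit_for(0.0)
        bad = fitting.FitResult(model="bi", plateau=float("nan"), amplitudes=(),
                                rates=(), half_times_s=(), residual_rms=float("nan"),
                                converged=False)
        with pytest.raises(InputError):
            fitting.classify_scrambling(bad, ok)
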