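"""Kinetic model evaluation, fitting, and variant selection."""

import numpy as np
import pytest

from ktr.kinetics import (
    FitConfig,
    KineticParams,
    eval_monotone,
    eval_recovery,
    fit_arrays,
    fit_trace,
    select_variant,
)


MONO = KineticParams("monotone", k_on=0.02, t_on=100.0, R_eq=3.0)
RECOV = KineticParams(
    "recovery", k_on=0.02, t_on=100.0, R_eq=3.0, k_off=0.01, t_off=500.0
)


class TestEvaluators:
    def test_value_at_onset_is_one(self):
        assert float(eval_monotone(MONO, MONO.t_on)) == 1.0
        assert float(eval_recovery(RECOV, RECOV.t_on)) == 1.0

    def test_half_rise_identity(self):
        t = 100.0 + np.log(2) / 0.02
        assert float(eval_monotone(MONO, t)) == pytest.approx(2.0, abs=1e-12)

    def test_monotone_asymptote(self):
        t = MONO.t_on + 20.0 / MONO.k_on
        assert abs(float(eval_monotone(MONO, t)) - MONO.R_eq) < 1e-8 * abs(
            1 - MONO.R_eq
        )

    def test_recovery_continuous_at_t_off(self):
        lo = np.nextafter(RECOV.t_off, -np.inf)
        hi = np.nextafter(RECOV.t_off, np.inf)
        assert abs(
            float(eval_recovery(RECOV, lo)) - float(eval_recovery(RECOV, hi))
        ) <= 1e-12

    def test_half_return_identity(self):
        # r(t_off)=2 by construction at these parameters
        p = KineticParams(
            "recovery",
            k_on=0.02,
            t_on=100.0,
            R_eq=3.0,
            k_off=0.01,
            t_off=100.0 + np.log(2) / 0.02,
        )
        r_off = float(eval_recovery(p, p.t_off))
        assert r_off == pytest.approx(2.0, abs=1e-12)
        t = p.t_off + 100.0 * np.log(2)
        assert float(eval_recovery(p, t)) == pytest.approx(1.5, abs=1e-12)

    def test_full_recovery_asymptote(self):
        assert float(eval_recovery(RECOV, RECOV.t_off + 1e5)) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_monotone_strictly_monotone_after_onset(self):
        t = np.linspace(MONO.t_on + 1, 1800, 200)
        r = eval_monotone(MONO, t)
        assert np.all(np.diff(r) > 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(variant="monotone", k_on=-0.01, t_on=10.0, R_eq=2.0),
            dict(variant="monotone", k_on=0.01, t_on=10.0, R_eq=0.0),
            dict(variant="recovery", k_on=0.01, t_on=100.0, R_eq=2.0,
                 k_off=0.01, t_off=50.0),
            dict(variant="recovery", k_on=0.01, t_on=100.0, R_eq=2.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)


def _schedule():
    # 4 pre-stimulation frames then every 15 s for 30 min
    return np.arange(-4, 121) * 15.0


class TestFitting:
    def test_noiseless_monotone_roundtrip(self):
        truth = KineticParams("monotone", k_on=0.01, t_on=60.0, R_eq=2.5)
        t = _schedule()
        fit = fit_arrays(t, eval_monotone(truth, t), "monotone")
        assert fit.converged
        assert fit.params.k_on == pytest.approx(truth.k_on, rel=1e-3)
        assert fit.params.t_on == pytest.approx(truth.t_on, rel=1e-3)
        assert fit.params.R_eq == pytest.approx(truth.R_eq, rel=1e-3)

    def test_noiseless_recovery_roundtrip(self):
        truth = KineticParams(
            "recovery", k_on=0.008, t_on=90.0, R_eq=2.8, k_off=0.004, t_off=500.0
        )
        t = _schedule()
        fit = fit_arrays(t, eval_recovery(truth, t), "recovery")
        assert fit.converged
        for name in ("k_on", "t_on", "R_eq", "k_off", "t_off"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-2
            )

    def test_constant_trace_unidentifiable(self):
        t = _schedule()
        fit = fit_arrays(t, np.ones_like(t), "monotone")
        assert not fit.converged
        assert fit.params is None
        assert "R_eq_unidentifiable" in fit.flags

    def test_too_few_points_excluded(self):
        t = np.array([-15.0, 0.0, 15.0, 30.0])
        fit = fit_arrays(t, np.array([1.0, 1.0, 1.5, 2.0]), "monotone")
        assert fit.exclusion_reason == "too_few_points"

    def test_time_unit_equivariance(self):
        """Fitting in minutes scales k_on by 60 and t_on by 1/60."""
        truth = KineticParams("monotone", k_on=0.01, t_on=60.0, R_eq=2.5)
        t = _schedule()
        y = eval_monotone(truth, t)
        fit_s = fit_arrays(t, y, "monotone")
        cfg_min = FitConfig(
            k_bounds=(60e-5, 60.0),
            k_on_starts=(60e-3, 60e-2, 60e-1),
        )
        fit_min = fit_arrays(t / 60.0, y, "monotone", cfg_min)
        assert fit_min.params.k_on == pytest.approx(60.0 * fit_s.params.k_on, rel=1e-4)
        assert fit_min.params.t_on == pytest.approx(fit_s.params.t_on / 60.0, rel=1e-4)

    def test_bias_vanishes_as_noise_shrinks(self):
        truth = KineticParams("monotone", k_on=0.01, t_on=60.0, R_eq=2.5)
        t = _schedule()
        clean = eval_monotone(truth, t)
        errs = []
        for noise_sd in (0.10, 0.02, 0.004):
            rng = np.random.default_rng(5)
            reps = []
            for _ in range(12):
                fit = fit_arrays(t, clean + rng.normal(0, noise_sd, t.shape), "monotone")
                reps.append(fit.params.k_on)
            errs.append(abs(np.mean(reps) - truth.k_on))
        assert errs[2] < errs[0]
        assert errs[2] / truth.k_on < 0.01

    def test_noisy_recovery_accuracy(self):
        """Median parameter errors stay small at trace noise SD 0.05."""
        truth = KineticParams("monotone", k_on=0.01, t_on=60.0, R_eq=2.5)
        t = _schedule()
        clean = eval_monotone(truth, t)
        rng = np.random.default_rng(17)
        k_errs, r_errs = [], []
        for _ in range(30):
            fit = fit_arrays(t, clean + rng.normal(0, 0.05, t.shape), "monotone")
            assert fit.converged
            k_errs.append(abs(fit.params.k_on - truth.k_on) / truth.k_on)
            r_errs.append(abs(fit.params.R_eq - truth.R_eq) / truth.R_eq)
        assert np.median(k_errs) <= 0.15
        assert np.median(r_errs) <= 0.05


class TestVariantSelection:
    def test_recovery_archetype_selected(self):
        truth = KineticParams(
            "recovery", k_on=0.01, t_on=60.0, R_eq=2.0, k_off=0.004, t_off=450.0
        )
        t = _schedule()
        rng = np.random.default_rng(3)
        y = eval_recovery(truth, t) + rng.normal(0, 0.05, t.shape)
        chosen, fit, _, _ = fit_trace((t, y), "auto")
        assert chosen == "recovery"
        assert fit.converged

    def test_monotone_archetype_selected(self):
        truth = KineticParams("monotone", k_on=0.012, t_on=45.0, R_eq=2.8)
        t = _schedule()
        rng = np.random.default_rng(4)
        y = eval_monotone(truth, t) + rng.normal(0, 0.05, t.shape)
        chosen, fit, _, _ = fit_trace((t, y), "auto")
        assert chosen == "monotone"
        assert fit.converged

    def test_flat_noise_trace_is_monotone_unidentifiable(self):
        t = _schedule()
        rng = np.random.default_rng(6)
        y = 1.0 + rng.normal(0, 0.03, t.shape)
        chosen, fit, _, _ = fit_trace((t, y), "auto")
        assert chosen == "monotone"
        assert not fit.converged
        assert "R_eq_unidentifiable" in fit.flags

    def test_selection_respects_sse_improvement_gate(self):
        truth = KineticParams("monotone", k_on=0.012, t_on=45.0, R_eq=2.8)
        t = _schedule()
        y = eval_monotone(truth, t)
        fit_mono = fit_arrays(t, y, "monotone")
        fit_recov = fit_arrays(t, y, "recovery")
        assert select_variant((t, y), fit_mono, fit_recov) == "monotone"
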