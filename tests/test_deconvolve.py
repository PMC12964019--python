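import numpy as np
import pytest

from mhqpeldor import deconvolve as dc
from mhqpeldor.exceptions import ConditioningError, MhqError, TraceError


def make_trace(values, dt_ns=8):
    n = len(values)
    return dc.CorrectedTrace(t_ns=np.arange(n) * dt_ns, values=np.asarray(values))


@pytest.fixture(scope="module")
def form_factors(reference_pair):
    apo_t, holo_t, _ = reference_pair
    t_ns = np.round(apo_t.t_us * 1e3)
    apo = dc.CorrectedTrace(t_ns=t_ns, values=apo_t.real)
    holo = dc.CorrectedTrace(t_ns=t_ns, values=holo_t.real)
    return apo, holo


class TestDownsamplingFactors:
    @pytest.mark.parametrize("dts,expected", [
        ((8, 12), (2, 3)),
        ((8, 8), (1, 1)),
        ((16, 8), (2, 1)),
    ])
    def test_coprime_pairs(self, dts, expected):
        assert dc.downsampling_factors(*dts) == expected

    def test_non_integer_rejected(self):
        with pytest.raises(TraceError, match="integer"):
            dc.downsampling_factors(8.5, 8)


class TestModulationScale:
    def test_identity(self, form_factors):
        apo, _ = form_factors
        res = dc.modulation_scale(apo, apo)
        assert res.f_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.branch_used is dc.ScalingBranch.EQUAL

    def test_elementwise_square_gives_half(self, form_factors):
        apo, _ = form_factors
        squared = make_trace(apo.values**2, dt_ns=apo.dt_ns)
        res = dc.modulation_scale(apo, squared)
        assert res.f_lambda == pytest.approx(0.5, abs=1e-12)
        rescaled = dc.apply_scaling(squared, res.f_lambda)
        assert np.abs(rescaled.values - apo.values).max() < 1e-12

    def test_idempotent_after_scaling(self, form_factors):
        apo, holo = form_factors
        first = dc.modulation_scale(apo, holo)
        scaled = dc.apply_scaling(holo, first.f_lambda)
        again = dc.modulation_scale(apo, scaled)
        assert again.f_lambda == pytest.approx(1.0, abs=1e-10)

    def test_equal_dt_reduces_to_classic_two_trace_scaling(self, form_factors):
        # oracle: the direct log-domain formula without any downsampling
        apo, holo = form_factors
        lv1 = np.log(apo.values[1:])
        lv2 = np.log(holo.values[1:])
        classic = np.sum(lv1**2) / np.sum(lv1 * lv2)
        res = dc.modulation_scale(apo, holo)
        assert res.f_lambda == pytest.approx(classic, rel=1e-12)
        assert res.alpha_pair == (1, 1)

    def test_mixed_dt_matches_decimation_oracle(self, form_factors):
        # (8, 16) ns pair: scaling on the aligned coarse grid must equal
        # the same-dt result after decimating the fine trace by 2
        apo, _ = form_factors
        coarse = make_trace(apo.values[::2]**1.7, dt_ns=16)
        mixed = dc.modulation_scale(apo, coarse)
        apo_decimated = make_trace(apo.values[::2], dt_ns=16)
        oracle = dc.modulation_scale(apo_decimated, coarse)
        assert mixed.f_lambda == pytest.approx(oracle.f_lambda, rel=1e-12)
        assert mixed.branch_used is dc.ScalingBranch.V2_COARSER
        assert mixed.alpha_pair == (1, 2)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(TraceError, match="> 0"):
            make_trace([1.0, 0.5, -0.1, 0.4])


class TestLinearCombination:
    def test_pure_apo(self, form_factors):
        apo, holo = form_factors
        res = dc.linear_combination_fit(apo, apo, holo)
        assert res.a_apo == pytest.approx(1.0, abs=1e-10)
        assert res.b_holo == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("force_sum", [True, False])
    def test_noiseless_mixture_exact(self, form_factors, force_sum):
        apo, holo = form_factors
        mix = make_trace(0.3 * apo.values + 0.7 * holo.values, apo.dt_ns)
        res = dc.linear_combination_fit(apo=apo, holo=holo, mhq=mix,
                                        force_sum=force_sum)
        assert abs(res.a_apo - 0.3) < 1e-8
        assert abs(res.b_holo - 0.7) < 1e-8

    def test_forced_sum_is_exact_complement(self, form_factors):
        apo, holo = form_factors
        rng = np.random.default_rng(3)
        mix = make_trace(
            0.4 * apo.values + 0.6 * holo.values + rng.normal(0, 0.01, apo.values.size),
            apo.dt_ns)
        res = dc.linear_combination_fit(mix, apo, holo, force_sum=True)
        assert res.a_apo + res.b_holo == 1.0

    def test_monte_carlo_recovery_at_snr60(self, form_factors):
        # noise sd 0.005 at depth 0.3 is SNR ~ 60; coefficients recovered
        # to ~0.05 mean absolute error, and essentially unbiased
        apo, holo = form_factors
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(200):
            noisy = 0.5 * apo.values + 0.5 * holo.values + \
                rng.normal(0, 0.005, apo.values.size)
            res = dc.linear_combination_fit(make_trace(noisy, apo.dt_ns),
                                            apo, holo, force_sum=True)
            errs.append(res.a_apo - 0.5)
        errs = np.asarray(errs)
        assert np.mean(np.abs(errs)) <= 0.05
        assert abs(errs.mean()) < 0.01

    def test_recovery_degrades_with_snr(self, form_factors):
        apo, holo = form_factors
        mean_err = []
        for snr in (100, 50, 20, 10):
            sd = 0.3 / snr
            rng = np.random.default_rng(5)
            errs = []
            for _ in range(100):
                noisy = 0.5 * apo.values + 0.5 * holo.values + \
                    rng.normal(0, sd, apo.values.size)
                res = dc.linear_combination_fit(make_trace(noisy, apo.dt_ns),
                                                apo, holo, force_sum=True)
                errs.append(abs(res.a_apo - 0.5))
            mean_err.append(np.mean(errs))
        assert np.all(np.diff(mean_err) > 0)

    def test_collinear_components_rejected(self):
        v = np.exp(-np.linspace(0, 1, 100))
        a = make_trace(v)
        b = make_trace(v * (1 + 1e-12))
        with pytest.raises(ConditioningError):
            dc.linear_combination_fit(a, a, b)

    def test_nonneg_constraint(self, form_factors):
        apo, holo = form_factors
        # a mixture slightly outside the simplex pulls the unconstrained
        # solution negative; nnls clips it at the boundary
        mix = make_trace(np.clip(1.05 * apo.values - 0.05 * holo.values,
                                 1e-6, None), apo.dt_ns)
        res = dc.linear_combination_fit(mix, apo, holo, force_sum=False,
                                        nonneg=True)
        assert res.a_apo >= 0 and res.b_holo >= 0

    def test_unforced_fit_flags_normalisation(self, form_factors):
        apo, holo = form_factors
        mix = make_trace(0.3 * apo.values + 0.7 * holo.values, apo.dt_ns)
        res = dc.linear_combination_fit(mix, apo, holo, force_sum=False)
        assert res.meta.get("normalize_before_interpretation") is True


class TestResidualDiagnostics:
    def _result_with_residual(self, resid):
        n = resid.size
        return dc.DeconvolutionResult(
            a_apo=0.5, b_holo=0.5, a_2sigma=0.0, b_2sigma=0.0,
            forced_sum=True, residual=resid, fitted=np.ones(n),
            t_ns=np.arange(n) * 8)

    def test_zero_residual_passes(self):
        slope, intercept, ok = dc.residual_diagnostics(
            self._result_with_residual(np.zeros(200)))
        assert slope == 0 and intercept == 0 and ok

    def test_white_noise_passes_usually(self):
        # each coefficient clears its own 2-SE gate ~95% of the time (the
        # normal two-sided rate); the joint verdict is necessarily a bit
        # lower because both must pass at once
        rng = np.random.default_rng(17)
        joint = slope_ok = 0
        results = [self._result_with_residual(rng.normal(0, 0.01, 300))
                   for _ in range(1000)]
        for r in results:
            slope, _, ok = dc.residual_diagnostics(r)
            joint += ok
            slope_ok += abs(slope) <= 2 * r.residual_slope_se
        assert slope_ok / 1000 >= 0.94
        assert joint / 1000 >= 0.90

    def test_linear_drift_fails(self):
        n = 300
        t_us = np.arange(n) * 8e-3
        drift = 0.05 * t_us
        rng = np.random.default_rng(2)
        _, _, ok = dc.residual_diagnostics(
            self._result_with_residual(drift + rng.normal(0, 0.002, n)))
        assert not ok


class TestPipelineAndReport:
    def test_deconvolute_handles_depth_mismatch(self, form_factors):
        # the mixture was recorded at a lower modulation depth; log-domain
        # scaling must absorb it before the linear combination
        apo, holo = form_factors
        mix_deep = 0.4 * apo.values + 0.6 * holo.values
        mix = make_trace(mix_deep**0.8, apo.dt_ns)
        res = dc.deconvolute(mix, apo, holo)
        assert res.a_apo == pytest.approx(0.4, abs=0.02)

    def test_report_toggles(self, form_factors, tmp_path):
        apo, holo = form_factors
        mix = make_trace(0.3 * apo.values + 0.7 * holo.values, apo.dt_ns)
        res = dc.linear_combination_fit(mix, apo, holo)
        inputs = {"apo": apo, "holo": holo, "mhq": mix}
        assert dc.deconvolution_report(res, inputs, tmp_path) == []
        written = dc.deconvolution_report(res, inputs, tmp_path,
                                          save_ascii=True)
        assert len(written) == 4  # apo, holo, in-silico mix, residual
        assert {p.name for p in written} >= {"mix_insilico.dat", "residual.dat"}
        written = dc.deconvolution_report(res, inputs, tmp_path, report=True)
        text = written[0].read_text()
        for token in ("a (apo)", "b (holo)", "slope", "intercept"):
            assert token in text
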