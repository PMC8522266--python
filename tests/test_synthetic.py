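"""Synthetic-study generator: determinism, injected effects, raw-optics loop."""

import numpy as np
import pytest

from hemoptics.fitting import fit_dtof, fit_g2
from hemoptics.forward_models import (
    Geometry,
    OpticalProperties,
    ValidationError,
    wavenumber_in_medium,
)
from hemoptics.pipeline import EpochDesign, analyze_study
from hemoptics.synthetic import (
    DCS_WAVELENGTH,
    DEFAULT_MUSP,
    DEFAULT_RHO_DCS,
    DEFAULT_RHO_NIRS,
    EffectSpec,
    NoiseSpec,
    _sigmoid_onset,
    null_effects,
    paper_effects,
    simulate_raw_optics,
    simulate_study,
)


class TestSimulateStudy:
    def test_same_seed_is_bit_identical(self):
        a = simulate_study(n_subjects=2, seed=9)
        b = simulate_study(n_subjects=2, seed=9)
        assert len(a) == len(b) == 2 * 2 * 2
        for sa, sb in zip(a, b):
            assert (sa.subject_id, sa.mask_type, sa.hemisphere) == (
                sb.subject_id,
                sb.mask_type,
                sb.hemisphere,
            )
            for name in sa.channels:
                np.testing.assert_array_equal(sa.channels[name], sb.channels[name])

    def test_different_seed_differs(self):
        a = simulate_study(n_subjects=1, seed=1)
        b = simulate_study(n_subjects=1, seed=2)
        assert not np.allclose(a[0].channels["CBF"], b[0].channels["CBF"])

    def test_onset_is_zero_before_mask_and_saturates(self):
        t = np.arange(-600.0, 601.0)
        s = _sigmoid_onset(t)
        assert np.all(s[t <= 0] == 0.0)
        assert s[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(s[t >= 0]) >= 0)

    def test_injected_effect_recovered_population_level(self):
        """Pooling many subjects, the pipeline's estimate hits the injected mean."""
        series = simulate_study(n_subjects=40, seed=123)
        res, _ = analyze_study(series, compute_timecourses=False)
        d = {(r.parameter, r.mask_type): r for r in res}
        # MC error at n=40: sd/sqrt(40); assert within ~3 standard errors
        assert d[("CBF", "FFP2")].point_estimate == pytest.approx(6.5, abs=3 * 6.5 / np.sqrt(40))
        assert d[("RR", "FFP2")].point_estimate == pytest.approx(-3.2, abs=3 * 3.6 / np.sqrt(40))

    def test_null_preset_is_centered_on_null(self):
        series = simulate_study(n_subjects=40, effects=null_effects(), seed=77)
        res, _ = analyze_study(series, compute_timecourses=False)
        for r in res:
            if r.mask_type == "between-mask":
                continue
            null = 0.0
            scale = {"CBF": 6.5, "CMRO2": 6.0}.get(r.parameter, 3.0)
            assert abs(r.point_estimate - null) < scale  # loose: centered, not exact

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            EffectSpec("CBF", "FFP2", "r", -1.0, 0.1)
        with pytest.raises(ValidationError):
            NoiseSpec(ar1_coeff={"CBF": 1.2})
        with pytest.raises(ValidationError):
            simulate_study(n_subjects=1, effects=[EffectSpec("XX", "FFP2", "delta", 1.0, 0.1)])


class TestRawOptics:
    def _short_series(self, n_t=40):
        series = simulate_study(n_subjects=1, seed=3)[0]
        # trim to a short window for speed
        sl = slice(0, n_t)
        series.time = series.time[sl]
        series.channels = {k: v[sl] for k, v in series.channels.items()}
        series.valid = {k: v[sl] for k, v in series.valid.items()}
        return series

    def test_noiseless_round_trip_recovers_trajectories(self):
        """forward -> fit inverts: BFi, StO2, tHb recovered to <1% without noise."""
        s = self._short_series(5)
        times, g2s, dtofs = simulate_raw_optics(s, noiseless=True, cadence_s=10.0)
        geom_nirs = Geometry(rho=DEFAULT_RHO_NIRS)
        geom_dcs = Geometry(rho=DEFAULT_RHO_DCS)
        k0 = wavenumber_in_medium(DCS_WAVELENGTH)
        from hemoptics.hemodynamics import chromophores_from_mua, sto2_from_concentrations

        for j, i in enumerate(range(0, s.time.size, 10)):
            mua = {}
            for wl, d in dtofs[j].items():
                mua[wl] = fit_dtof(d, geom_nirs).mua
            hbo, hbr = chromophores_from_mua(mua)
            sto2, thb = sto2_from_concentrations(hbo, hbr)
            assert sto2 == pytest.approx(s.channels["StO2"][i], rel=0.01)
            assert thb == pytest.approx(s.channels["tHb"][i], rel=0.01)
            op = OpticalProperties(mua=mua[DCS_WAVELENGTH], musp=DEFAULT_MUSP[DCS_WAVELENGTH])
            res = fit_g2(g2s[j], op, geom_dcs, k0)
            bfi_true = s.meta["bfi_per_cbf"] * s.channels["CBF"][i]
            assert res.bfi == pytest.approx(bfi_true, rel=0.01)

    def test_noisy_stream_respects_physics_invariants(self):
        s = self._short_series(20)
        _, g2s, dtofs = simulate_raw_optics(s, cadence_s=5.0, rng=np.random.default_rng(8))
        for c in g2s:
            # Siegert bounds up to the additive noise floor
            assert np.all(c.g2 > 1.0 - 0.1) and np.all(c.g2 < 1.0 + c.beta + 0.1)
        for dset in dtofs:
            for d in dset.values():
                assert np.all(d.counts >= 0)
                assert np.all(d.counts == np.round(d.counts))  # Poisson integers

    def test_zero_count_acquisition_rejected(self):
        s = self._short_series(5)
        with pytest.raises(ValidationError):
            simulate_raw_optics(s, noise=NoiseSpec(dtof_total_counts=0.5))

    def test_missing_underlying_channels_rejected(self):
        s = self._short_series(5)
        del s.channels["tHb"]
        del s.valid["tHb"]
        with pytest.raises(ValidationError, match="tHb"):
            simulate_raw_optics(s)

    def test_end_to_end_effect_sign_recovered(self):
        """Raw-level chain preserves the injected CBF increase (sign and rough size)."""
        eff = [EffectSpec("CBF", "FFP2", "r", 1.30, 0.0, transition_time_constant=0.0)]
        series = simulate_study(
            n_subjects=1, effects=eff, seed=21,
            noise=NoiseSpec(sd={k: 0.0 for k in NoiseSpec().sd}),
        )
        s = next(x for x in series if x.mask_type == "FFP2")
        times, g2s, dtofs = simulate_raw_optics(s, cadence_s=200.0, rng=np.random.default_rng(4))
        geom_dcs = Geometry(rho=DEFAULT_RHO_DCS)
        k0 = wavenumber_in_medium(DCS_WAVELENGTH)
        mua_fit = fit_dtof(dtofs[0][DCS_WAVELENGTH], Geometry(rho=DEFAULT_RHO_NIRS)).mua
        op = OpticalProperties(mua=mua_fit, musp=DEFAULT_MUSP[DCS_WAVELENGTH])
        bfis = np.array([fit_g2(c, op, geom_dcs, k0).bfi for c in g2s])
        pre = bfis[times < 0].mean()
        post = bfis[times > 180].mean()
        assert post / pre == pytest.approx(1.30, rel=0.1)
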