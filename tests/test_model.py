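import numpy as np
import pytest
from scipy.linalg import expm

from ppmopkpd import (
    DoseRegimen,
    PlasmaPKParams,
    TissuePKParams,
    half_life,
    hybrid_rate_constants,
    plasma_terminal_halflife_hours,
    reference_estimates,
    simulate_full,
    simulate_plasma,
)
from ppmopkpd.model import _stimulation


def full_sim(ref, regimen, times, **kw):
    return simulate_full(ref.plasma, ref.tissue, ref.transcript, ref.dystrophin,
                         regimen, times, **kw)


class TestPlasma:
    def test_zero_dose_gives_zero_concentration(self, ref):
        traj = simulate_plasma(ref.plasma, DoseRegimen.single(0.0),
                               np.linspace(0, 1, 20))
        assert np.all(traj.cp == 0)

    def test_initial_condition_is_dose_over_vc(self, ref):
        traj = simulate_plasma(ref.plasma, DoseRegimen.single(80.0), [0.0, 0.01])
        assert traj.cp[0] == pytest.approx(2.0e6 / ref.plasma.vc)

    def test_mass_conserved_without_elimination(self):
        p = PlasmaPKParams(vc=5.0, kel=1e-12, k12=20.0, k21=30.0)
        traj = simulate_plasma(p, DoseRegimen.single(40.0), np.linspace(0, 5, 50))
        np.testing.assert_allclose(traj.ac + traj.aper, 1.0e6, rtol=1e-9)

    def test_closed_form_matches_ode_at_1e6(self, ref):
        times = np.linspace(0.0, 1.0, 100)
        reg = DoseRegimen.single(40.0)
        analytic = simulate_plasma(ref.plasma, reg, times)
        numeric = simulate_plasma(ref.plasma, reg, times, method="ode",
                                  rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(analytic.cp[1:], numeric.cp[1:], rtol=1e-6)

    def test_terminal_half_life_against_eigenvalue_oracle(self, ref):
        p = ref.plasma
        matrix = np.array([[-(p.kel + p.k12), p.k21], [p.k12, -p.k21]])
        lam = np.sort(np.linalg.eigvals(matrix))  # independent spectral oracle
        lam_z = -lam[-1]
        _, slow = hybrid_rate_constants(p)
        assert slow == pytest.approx(lam_z, rel=1e-12)
        assert plasma_terminal_halflife_hours(p) == pytest.approx(0.70, abs=5e-3)

    def test_terminal_slope_against_expm_decay(self, ref):
        # brute-force oracle: propagate with matrix exponentials and regress
        # the late-time log-concentration slope
        p = ref.plasma
        matrix = np.array([[-(p.kel + p.k12), p.k21], [p.k12, -p.k21]])
        ts = np.linspace(0.5, 1.0, 40)
        cp = np.array([(expm(matrix * t) @ [1e6, 0.0])[0] / p.vc for t in ts])
        slope = np.polyfit(ts, np.log(cp), 1)[0]
        assert half_life(-slope) * 24 == pytest.approx(
            plasma_terminal_halflife_hours(p), rel=1e-3)


class TestCascade:
    def test_superposition_dose_doubling(self, ref):
        times = np.linspace(0.0, 60.0, 40)
        lo = full_sim(ref, DoseRegimen.repeated(40.0, 28.0, 2), times)
        hi = full_sim(ref, DoseRegimen.repeated(80.0, 28.0, 2), times)
        for name in ("cp", "ct", "c1"):
            np.testing.assert_allclose(getattr(hi, name),
                                       2.0 * getattr(lo, name), rtol=1e-9)

    def test_tissue_mass_balance_with_zero_elimination(self, ref):
        # k = 0: muscle gains exactly kpt * integral(Ac) (quadrature oracle)
        tissue = TissuePKParams(kpt=ref.tissue.kpt, kt1=ref.tissue.kt1,
                                kt2=ref.tissue.kt2, k=1e-12, vt=ref.tissue.vt)
        # geometric spacing resolves the fast (~0.008 day) plasma decay that
        # dominates the influx integral
        times = np.concatenate([[0.0], np.geomspace(1e-4, 10.0, 3000)])
        traj = simulate_full(ref.plasma, tissue, ref.transcript, ref.dystrophin,
                             DoseRegimen.single(40.0), times)
        gained = traj.at + traj.a1
        influx = tissue.kpt * np.concatenate(
            [[0.0], np.cumsum((traj.ac[1:] + traj.ac[:-1]) / 2
                              * np.diff(times))])
        np.testing.assert_allclose(gained[1:], influx[1:], rtol=2e-3)
        assert np.all(np.diff(gained) >= -1e-9)

    def test_baseline_stationarity_without_dosing(self, ref):
        times = np.linspace(0.0, 168.0, 200)
        traj = full_sim(ref, DoseRegimen.single(0.0), times)
        np.testing.assert_allclose(traj.skmrna, 1.3, rtol=1e-8)
        np.testing.assert_allclose(traj.dys, 0.10, rtol=1e-8)

    def test_half_maximal_stimulation_at_sc50(self, ref):
        for gamma in (0.3, 1.0, 1.16, 4.0):
            s = _stimulation(np.array([795.28]), 1.41e4, 795.28, gamma)
            assert s[0] == pytest.approx(1.41e4 / 2)

    def test_fast_integrator_matches_lsoda(self, ref):
        times = np.array([0.5, 1, 2, 5, 7, 10, 14, 28, 56, 84.0])
        reg = DoseRegimen.repeated(40.0, 28.0, 3)
        fast = full_sim(ref, reg, times)
        ode = full_sim(ref, reg, times, method="ode")
        for name in ("ct", "c1", "skmrna", "dys"):
            np.testing.assert_allclose(getattr(fast, name), getattr(ode, name),
                                       rtol=1e-4)

    def test_tissue_peak_then_biexponential_decline(self, ref):
        times = np.linspace(0.0, 28.0, 1401)
        traj = full_sim(ref, DoseRegimen.single(40.0), times)
        assert times[np.argmax(traj.ct)] <= 3.0
        post = traj.ct[times > 5.0]
        assert np.all(np.diff(post) < 0)

    def test_transcript_relaxes_to_baseline_before_dystrophin(self, ref):
        # kout_s = 3.17/d >> kout_Dys = 0.044/d forces this hierarchy
        times = np.linspace(0.0, 600.0, 4001)
        traj = full_sim(ref, DoseRegimen.single(40.0), times)
        peak_t = times[np.argmax(traj.skmrna)]
        after = times > peak_t

        def settle(curve, base):
            ok = np.abs(curve - base) <= 0.05 * base
            idx = np.nonzero(after & ok)[0]
            return times[idx[0]]

        assert settle(traj.skmrna, 1.3) < settle(traj.dys, 0.10)

    def test_repeat_dose_trough_accumulation_is_limited(self, ref):
        troughs = np.array([28.0, 56, 84, 112, 140, 168])
        traj = full_sim(ref, DoseRegimen.repeated(40.0, 28.0, 6), troughs)
        ratio = traj.ct[-1] / traj.ct[0]
        # geometric-series oracle with the slow tissue hybrid rate constant
        t = ref.tissue
        b = t.kt1 + t.kt2 + t.k
        lam_slow = (b - np.sqrt(b * b - 4 * t.k * t.kt2)) / 2
        expected = (1 - np.exp(-6 * lam_slow * 28)) / (1 - np.exp(-lam_slow * 28))
        assert ratio == pytest.approx(expected, rel=0.02)
        assert 1.0 < ratio < 2.0  # limited accumulation, well below dystrophin's

    def test_states_nonnegative_on_ode_route(self, ref):
        times = np.linspace(0.0, 120.0, 60)
        rng = np.random.default_rng(3)
        for _ in range(3):
            f = np.exp(rng.uniform(-0.5, 0.5, size=4))
            tissue = TissuePKParams(kpt=0.023 * f[0], kt1=0.37 * f[1],
                                    kt2=0.26 * f[2], k=0.13 * f[3], vt=0.21)
            traj = simulate_full(ref.plasma, tissue, ref.transcript,
                                 ref.dystrophin,
                                 DoseRegimen.repeated(40.0, 28.0, 3), times,
                                 method="ode")
            for name in ("ac", "aper", "at", "a1", "skmrna", "dys"):
                assert np.all(getattr(traj, name) >= -1e-9)

    def test_tidy_export(self, ref):
        traj = full_sim(ref, DoseRegimen.single(40.0), [0.0, 1.0, 2.0])
        frame = traj.to_frame()
        assert set(frame.columns) == {"time_day", "variable", "value", "unit"}
        assert set(frame["variable"]) == {"Ac", "Aper", "Cp", "At", "A1", "Ct",
                                          "C1", "sk.mRNA", "Dys"}


def test_empty_regimen_is_all_zero(ref):
    traj = simulate_plasma(ref.plasma, DoseRegimen(events=()), [0.0, 1.0])
    assert np.all(traj.cp == 0)
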