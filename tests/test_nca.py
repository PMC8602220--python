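import math

import numpy as np
import pytest

from ppmopkpd import (
    ConcProfile,
    DoseRegimen,
    auc_linlog,
    nca_by_group,
    run_nca,
    simulate_plasma,
    terminal_slope,
)
from ppmopkpd.nca import NCAError, NoTerminalPhaseError


class TestAUC:
    def test_flat_segment_uses_linear_rule(self):
        auc, _ = auc_linlog(ConcProfile((0.0, 1.0), (10.0, 10.0), dose=1.0))
        assert auc == pytest.approx(10.0)

    def test_declining_segment_uses_log_rule(self):
        auc, _ = auc_linlog(ConcProfile((0.0, 1.0), (100.0, 50.0), dose=1.0))
        assert auc == pytest.approx(50.0 / math.log(2.0))

    def test_single_point_is_degenerate(self):
        with pytest.raises(NCAError):
            auc_linlog(ConcProfile((1.0,), (5.0,), dose=1.0))

    def test_unsorted_times_rejected(self):
        with pytest.raises(NCAError):
            ConcProfile((1.0, 0.5), (1.0, 2.0), dose=1.0)

    def test_additivity_over_partition(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 8.0])
        c = 100 * np.exp(-0.3 * t)
        whole, _ = auc_linlog(ConcProfile(tuple(t), tuple(c), dose=1.0))
        parts = sum(auc_linlog(ConcProfile(tuple(t[i:i + 2]),
                                           tuple(c[i:i + 2]), dose=1.0))[0]
                    for i in range(len(t) - 1))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_log_rule_continuous_at_equal_concentrations(self):
        # C2 -> C1 from below: log rule must approach the linear value
        linear, _ = auc_linlog(ConcProfile((0.0, 1.0), (10.0, 10.0), dose=1.0))
        approach, _ = auc_linlog(ConcProfile((0.0, 1.0), (10.0, 10.0 - 1e-9),
                                             dose=1.0))
        assert approach == pytest.approx(linear, rel=1e-9)

    def test_grid_refinement_approaches_analytic_auc(self):
        # biexponential: not log-linear within segments, so the trapezoid
        # error is genuine and must shrink as the grid refines
        def conc(t):
            return 80 * np.exp(-0.5 * t) + 20 * np.exp(-0.05 * t)

        exact = 80 / 0.5 * (1 - np.exp(-0.5 * 40)) \
            + 20 / 0.05 * (1 - np.exp(-0.05 * 40))
        errs = []
        for n in (8, 32, 128):
            t = np.linspace(0.0, 40.0, n)
            prof = ConcProfile(tuple(t), tuple(conc(t)), dose=1.0)
            errs.append(abs(auc_linlog(prof)[0] - exact))
        assert errs[0] > errs[1] > errs[2]


class TestTerminalSlope:
    def test_exact_monoexponential(self):
        t = np.array([1.0, 2.0, 3.0])
        prof = ConcProfile(tuple(t), tuple(100 * np.exp(-0.6931 * t)), dose=1.0)
        lam, t_half, n, r2 = terminal_slope(prof)
        assert t_half == pytest.approx(1.000, abs=1e-3)
        assert n == 3 and r2 == pytest.approx(1.0)

    def test_reference_biexponential_terminal_phase(self, ref):
        # sampled 4-24 h; distribution-phase contamination must stay within 10%
        times_d = np.array([4, 8, 12, 24.0]) / 24.0
        traj = simulate_plasma(ref.plasma, DoseRegimen.single(40.0), times_d)
        prof = ConcProfile(tuple(times_d * 24), tuple(traj.cp), dose=1e6)
        _, t_half, _, _ = terminal_slope(prof)
        assert t_half == pytest.approx(0.70, rel=0.10)

    def test_flat_profile_has_no_terminal_phase(self):
        with pytest.raises(NoTerminalPhaseError):
            terminal_slope(ConcProfile((0.0, 1, 2, 3, 4),
                                       (5.0, 5.0, 5.0, 5.0, 5.0), dose=1.0))


class TestRunNCA:
    def test_one_compartment_closed_forms_on_dense_grid(self):
        k, v, dose = 0.5, 5.0, 1e6
        t = np.linspace(0.001, 25.0, 3000)
        prof = ConcProfile(tuple(t), tuple((dose / v) * np.exp(-k * t)),
                           dose=dose)
        res = run_nca(prof)
        assert res.cl == pytest.approx(k * v, rel=1e-3)
        assert res.vss == pytest.approx(v, rel=1e-3)
        assert res.auc_inf >= res.auc_last

    def test_zero_profile_rejected(self):
        with pytest.raises(NCAError):
            run_nca(ConcProfile((0.0, 1.0, 2.0), (0.0, 0.0, 0.0), dose=1.0))

    def test_reference_profile_cl_within_quadrature_tolerance(self, ref):
        # oracle: analytic CL = Dose / integral(Cp) with the integral from
        # fine quadrature of the simulated curve
        design_h = np.array([5 / 60, 0.5, 2, 4, 8, 12, 24.0])
        traj = simulate_plasma(ref.plasma, DoseRegimen.single(80.0),
                               design_h / 24.0)
        prof = ConcProfile(tuple(design_h), tuple(traj.cp), dose=2e6)
        res = run_nca(prof)
        fine = np.concatenate([[0.0], np.geomspace(1e-5, 2.0, 4000)])
        cp = simulate_plasma(ref.plasma, DoseRegimen.single(80.0), fine).cp
        auc_d = np.trapezoid(cp, fine)
        cl_oracle = 2e6 / (auc_d * 24.0)
        assert res.cl == pytest.approx(cl_oracle, rel=0.15)

    def test_invariants(self, ref):
        design_h = np.array([5 / 60, 0.5, 2, 4, 8, 12, 24.0])
        traj = simulate_plasma(ref.plasma, DoseRegimen.single(40.0),
                               design_h / 24.0)
        res = run_nca(ConcProfile(tuple(design_h), tuple(traj.cp), dose=1e6))
        assert res.t_half == pytest.approx(math.log(2) / res.lambda_z)
        assert res.cl == pytest.approx(1e6 / res.auc_inf)
        assert res.vss == pytest.approx(res.cl * res.mrt)


def test_group_nca_table(plasma_ds):
    table = nca_by_group(plasma_ds)
    assert len(table) == 3
    assert sorted(table["dose_mgkg"]) == [10.0, 40.0, 80.0]
    assert (table["t_half_h"] < 1.0).all()  # fast plasma dissipation
    assert table["cl_ml_h_kg"].between(300, 3000).all()
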