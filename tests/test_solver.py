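"""Transient column solver: conservation, analytic limits, equilibria,
and the degeneration orderings."""

import math

import numpy as np
import pytest

from ivdflow.materials import Environment, MaterialCard
from ivdflow.rheology import equilibrium_time
from ivdflow.solver import (
    ColumnModel,
    ColumnPath,
    ColumnSolver,
    Layer,
    ProtocolSpec,
    Segment,
    SolverConfig,
    build_column,
    creep_protocol,
    equilibrium_0d,
    equilibrium_at_displacement,
    relaxation_protocol,
    run_protocol,
    swelling_protocol,
    terzaghi_reference,
)


def linear_column(cf0=0.0, k0=1.0, Em=1.0, nu=0.0, n_nodes=41, area=100.0, H=1.0):
    """Single-path single-layer column; k0 in tabulated 1e-4 mm^4/(N s)."""
    card = MaterialCard(
        tissue="NP", condition="healthy", Em=Em, nu=nu, beta_m=0.0, M=0.0,
        k0=k0, phi0w=0.8, cf0=cf0,
    )
    layer = Layer(card=card, thickness=H, n_nodes=n_nodes, constant_permeability=True)
    return ColumnModel(paths=(ColumnPath(name="core", area=area, layers=(layer,)),))


class TestBuildColumn:
    def test_areas_and_layers(self, mean_geometry, models):
        m = models["healthy"]
        np_path, af_path = m.paths
        assert np_path.area == pytest.approx(642.40, abs=0.01)
        assert af_path.area == pytest.approx(992.21, abs=0.01)
        for path in m.paths:
            assert [l.n_nodes for l in path.layers] == [2, 3, 10, 3, 2]
            assert [l.card.tissue for l in path.layers] == ["BEP", "CEP", path.name, "CEP", "BEP"]

    def test_degenerated_cep_permeability(self, models):
        cep = models["degenerated"].paths[0].layers[1]
        assert cep.card.k0 == 2.5

    def test_af_aggregate_fixed_charge(self, models):
        af_core = models["healthy"].paths[1].layers[2]
        assert af_core.card.cf0 == pytest.approx(-200.0)  # mean of -300 -> -100
        assert af_core.card.phi0w == pytest.approx(0.75)
        af_core_d = models["degenerated"].paths[1].layers[2]
        assert af_core_d.card.cf0 == pytest.approx(-125.0)


class TestEquilibrium0d:
    def test_no_charge_no_swelling(self):
        model = linear_column(cf0=0.0)
        eq = equilibrium_0d(model, 0.0)
        assert eq.u_top == pytest.approx(0.0, abs=1e-9)
        assert eq.core_stretch == pytest.approx(1.0, abs=1e-9)

    def test_free_swelling_expands_and_degeneration_reduces(self, models):
        eq_h = equilibrium_0d(models["healthy"], 0.0)
        eq_d = equilibrium_0d(models["degenerated"], 0.0)
        assert eq_h.core_stretch > 1.0
        assert eq_d.core_stretch > 1.0
        assert eq_d.u_top < eq_h.u_top

    def test_monotone_in_force(self, models):
        us = [equilibrium_0d(models["healthy"], f).u_top for f in (0.0, 100.0, 500.0, 1500.0)]
        assert np.all(np.diff(us) < 0)

    def test_bisection_oracle(self):
        """Independent bisection of the swelling balance on a single-layer
        charged column, with the laws written out longhand."""
        model = linear_column(cf0=-200.0, Em=0.5, nu=0.0, k0=1.0)
        eq = equilibrium_0d(model, 0.0)

        RT = 8.314 * 298.15 * 1e-6  # MPa per mol/m^3
        phi0w, c0, HA = 0.8, 150.0, 0.5

        def balance(lam):
            sig = HA * (lam**2 - 1) / (2 * lam)  # beta_m = 0
            cF = 200.0 * phi0w / (lam - 1 + phi0w)
            dpi = RT * (math.sqrt(cF**2 + 4 * c0**2) - 2 * c0)
            return sig - dpi

        lo, hi = 1.0, 3.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if balance(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert eq.core_stretch == pytest.approx(0.5 * (lo + hi), rel=1e-10)

    def test_force_balance_closes(self, models):
        eq = equilibrium_0d(models["healthy"], 750.0)
        areas = np.array([p.area for p in models["healthy"].paths])
        assert -(areas @ eq.sigma_paths) == pytest.approx(750.0, abs=1e-6)


class TestStep:
    def test_equilibrium_fixed_point(self):
        model = linear_column(cf0=0.0)
        s = ColumnSolver(model)
        st0 = s.initial_state()
        st1 = s.step(st0, 10.0, "force", 0.0, fcd_scale=0.0)
        assert np.allclose(st1.lam, 1.0, atol=1e-14)
        assert np.allclose(st1.p, 0.0, atol=1e-14)

    def test_terzaghi_linear_limit(self):
        """With no fixed charge, constant permeability and a small load the
        transient matches the classical consolidation series within 1 %."""
        model = linear_column(cf0=0.0, k0=1.0, Em=1.0, nu=0.0)
        cfg = SolverConfig(dt_init=0.2, dt_growth=1.04, dt_max=40.0)
        s = ColumnSolver(model, cfg)
        F = 0.3  # N over 100 mm^2 -> 0.3 % strain
        hist = s.simulate(
            [Segment("force", 0.0, F, 0.5, n_steps=10), Segment("force", F, F, 5000.0)]
        )
        times = np.geomspace(125.0, 5000.0, 24)  # Tv in [0.05, 2]
        u_num = -np.interp(times, hist.t, hist.u_top)
        u_ref = terzaghi_reference(H=1.0, HA=1.0, k=1e-4, load=F, times=times - 0.25, area=100.0)
        assert np.max(np.abs(u_num - u_ref) / u_ref) < 0.01

    def test_terzaghi_series_properties(self):
        # textbook value of the degree of consolidation at Tv = 0.2
        u = terzaghi_reference(1.0, 1.0, 1e-4, 1.0, np.array([0.2 * 0.25 / 1e-4]), area=1.0)
        assert u[0] == pytest.approx(0.504, abs=5e-4)
        # drained limit
        u_inf = terzaghi_reference(1.0, 1.0, 1e-4, 1.0, np.array([1e9]), area=1.0)
        assert u_inf[0] == pytest.approx(1.0, rel=1e-12)
        # no settlement at t = 0+ (series truncation sets the floor)
        u0 = terzaghi_reference(1.0, 1.0, 1e-4, 1.0, np.array([1e-9]), area=1.0, n_terms=50000)
        assert u0[0] == pytest.approx(0.0, abs=1e-4)

    def test_mass_conservation(self, solvers):
        """Interior fluid-content change equals the net boundary influx at
        every step of a swelling transient, to 1e-8 relative."""
        s = solvers["healthy"]
        st = s.initial_state()
        worst = 0.0
        dt = 1.0
        for i in range(60):
            fcd = min((i + 1) / 5.0, 1.0)
            new = s.step(st, dt, "force", 0.0, fcd_scale=fcd)
            for lhs, rhs in s.mass_balance_residual(st, new, dt):
                scale = max(abs(lhs), abs(rhs))
                if scale > 1e-12:
                    worst = max(worst, abs(lhs - rhs) / scale)
            st = new
            dt = min(dt * 1.3, 600.0)
        assert worst < 1e-8


class TestProtocols:
    def test_swelling_displacement_positive_and_monotone(self, solvers):
        ts = run_protocol(solvers["healthy"], swelling_protocol(0.0))
        assert ts.channel == "axial_displacement"
        assert ts.value[-1] > 0
        hold = ts.value[ts.t >= 1.0]
        assert np.all(np.diff(hold) >= -1e-9 * ts.value[-1])

    def test_creep_monotone_and_load_ordered(self, solvers, preloaded_states):
        s = solvers["healthy"]
        st = preloaded_states[("healthy", 20.0)]
        ts500 = run_protocol(s, creep_protocol(500.0), start_state=st)
        ts1500 = run_protocol(s, creep_protocol(1500.0), start_state=st)
        hold = ts500.value[ts500.t >= ts500.metadata["t_hold_start_s"]]
        assert np.all(np.diff(hold) >= -1e-9 * hold[-1])
        assert ts1500.value[-1] > ts500.value[-1]

    def test_relaxation_monotone_and_matches_equilibrium(self, models, solvers, preloaded_states):
        s = solvers["healthy"]
        ts = run_protocol(
            s, relaxation_protocol(0.10), start_state=preloaded_states[("healthy", 50.0)]
        )
        assert ts.channel == "reaction_force"
        hold = ts.value[ts.t >= ts.metadata["t_hold_start_s"]]
        assert np.all(np.diff(hold) <= 1e-9 * hold[0])
        f_eq = equilibrium_at_displacement(models["healthy"], ts.metadata["u_held_mm"]).force
        assert ts.value[-1] == pytest.approx(f_eq, rel=0.01)

    def test_terminal_matches_equilibrium(self, models, solvers, swollen_states, preloaded_states):
        m, s = models["healthy"], solvers["healthy"]
        eq = equilibrium_0d(m, 0.0)
        assert swollen_states["healthy"].u_top == pytest.approx(eq.u_top, rel=0.005)
        ts = run_protocol(s, creep_protocol(500.0), start_state=preloaded_states[("healthy", 20.0)])
        u_eq = equilibrium_0d(m, 20.0).u_top - equilibrium_0d(m, 500.0).u_top
        assert ts.value[-1] == pytest.approx(u_eq, rel=0.005)

    def test_degeneration_orderings(self, solvers, swollen_states, preloaded_states):
        """Surrogate restatement of the study's headline contrasts."""
        sw_h = run_protocol(solvers["healthy"], swelling_protocol(0.0))
        sw_d = run_protocol(solvers["degenerated"], swelling_protocol(0.0))
        # reduced swelling capacity with degeneration
        assert sw_h.value[-1] > sw_d.value[-1]
        # delayed equilibration when the endplate permeability is reduced
        assert equilibrium_time(sw_d, 0.95) > equilibrium_time(sw_h, 0.95)
        # larger creep deformation without osmotic load sharing
        cr_h = run_protocol(
            solvers["healthy"], creep_protocol(500.0),
            start_state=preloaded_states[("healthy", 20.0)],
        )
        cr_d = run_protocol(
            solvers["degenerated"], creep_protocol(500.0),
            start_state=preloaded_states[("degenerated", 20.0)],
        )
        assert cr_d.value[-1] > cr_h.value[-1]

    def test_time_step_robustness(self, mean_geometry):
        """Halving every dt cap moves the terminal displacement < 0.1 %."""
        model = build_column(mean_geometry, "healthy")
        coarse = ColumnSolver(model, SolverConfig())
        fine = ColumnSolver(
            model, SolverConfig(dt_init=0.5, dt_max=300.0, ramp_steps=40)
        )
        u_c = coarse.simulate(
            [Segment("force", 0.0, 0.0, 1.0, n_steps=5, fcd_start=0.0, fcd_end=1.0),
             Segment("force", 0.0, 0.0, 108000.0)],
        ).final_state.u_top
        u_f = fine.simulate(
            [Segment("force", 0.0, 0.0, 1.0, n_steps=10, fcd_start=0.0, fcd_end=1.0),
             Segment("force", 0.0, 0.0, 108000.0)],
        ).final_state.u_top
        assert abs(u_c - u_f) / abs(u_f) < 1e-3

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="creep", target=-1.0, ramp_duration=1.0)
        with pytest.raises(ValueError):
            ProtocolSpec(kind="torsion")
        with pytest.raises(ValueError):
            ProtocolSpec(kind="creep", target=500.0, ramp_duration=0.0)


class TestSeriesFormat:
    def test_csv_round_trip(self, solvers, tmp_path):
        ts = run_protocol(solvers["healthy"], swelling_protocol(0.0))
        path = tmp_path / "swell.csv"
        ts.to_csv(path)
        from ivdflow.series import TimeSeries

        back = TimeSeries.from_csv(path)
        assert back.channel == ts.channel
        assert np.allclose(back.t, ts.t)
        assert np.allclose(back.value, ts.value)
        assert back.metadata["protocol"] == "swelling_0N"
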