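import numpy as np
import pytest
from hypothesis import given, strategies as st

import stokesbd as sb
from stokesbd.engine import (
    ParticleSpec,
    ParticleState,
    StepPolicy,
    UniformField,
    ZeroField,
    advance_particle,
    handle_collision,
    propose_jump,
    solve_intermediate_dt,
)


class TestDiffusionCoefficient:
    def test_einstein_stokes_reference_value(self):
        # k_B * 310 / (6 pi * 2.5e-3 Pa s * 1e-7 m) = 9.08e-13 m^2/s
        assert sb.diffusion_coefficient(0.1, 310.0, 2.5) == pytest.approx(0.9082, abs=1e-3)

    def test_scalings(self):
        assert sb.diffusion_coefficient(0.01) / sb.diffusion_coefficient(0.1) == pytest.approx(10.0)
        assert sb.diffusion_coefficient(0.1, mu_cp=5.0) == pytest.approx(
            sb.diffusion_coefficient(0.1, mu_cp=2.5) / 2
        )

    @pytest.mark.parametrize("bad", [dict(a=0), dict(temperature=-1), dict(mu_cp=0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            sb.diffusion_coefficient(**{"a": 0.1, **bad})


class TestProposeJump:
    def test_pure_advection_when_d_zero(self):
        rng = np.random.default_rng(0)
        S = propose_jump([0, 0], 0.5, [2.0, -1.0], 0.0, rng)
        np.testing.assert_allclose(S, [1.0, -0.5])

    def test_diffusive_magnitude_is_deterministic(self):
        rng = np.random.default_rng(1)
        D, dt = 0.9, 0.05
        mags = [np.hypot(*propose_jump([0, 0], dt, [0, 0], D, rng)) for _ in range(50)]
        np.testing.assert_allclose(mags, np.sqrt(4 * D * dt), rtol=1e-12)

    def test_msd_per_step_and_bound(self):
        rng = np.random.default_rng(2)
        D, dt, v = 0.9, 0.05, np.array([1.0, 0.5])
        jumps = np.array([propose_jump([0, 0], dt, v, D, rng) for _ in range(4000)])
        msd = ((jumps - v * dt) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * D * dt, rel=1e-9)  # fixed-magnitude kicks
        bound = np.hypot(*v) * dt + np.sqrt(4 * D * dt)
        assert np.all(np.hypot(*jumps.T) <= bound + 1e-12)


class TestIntermediateStep:
    def test_closed_forms(self):
        assert solve_intermediate_dt(5.0, 1.0, 0.0, 2.0) == pytest.approx(16 / 8)
        assert solve_intermediate_dt(5.0, 1.0, 2.0, 0.0) == pytest.approx(2.0)

    @given(
        st.floats(0.2, 100.0),
        st.floats(1e-3, 0.1),
        st.floats(0.0, 10.0),
        st.floats(1e-3, 10.0),
    )
    def test_root_satisfies_gap_equation(self, gap, a, speed, D):
        R = a + gap
        dt = solve_intermediate_dt(R, a, speed, D)
        assert dt > 0
        assert speed * dt + np.sqrt(4 * D * dt) == pytest.approx(R - a, rel=1e-9)

    def test_contact_raises(self):
        with pytest.raises(ValueError):
            solve_intermediate_dt(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            solve_intermediate_dt(2.0, 1.0, 0.0, 0.0)


@pytest.fixture
def single_cell_setup():
    domain = sb.DomainSpec(100, 60)
    cells = sb.CellField(np.array([[50.0, 30.0]]), 10.0, np.pi * 100 / 6000)
    spec = ParticleSpec.from_physics(0.1, rho=0.5)
    return domain, cells, spec


class TestAdvanceParticle:
    def test_far_particle_takes_tier1(self, single_cell_setup):
        domain, cells, spec = single_cell_setup
        state = ParticleState(np.array([20.0, 30.0]))
        rng = np.random.default_rng(0)
        out = advance_particle(state, spec, StepPolicy(), ZeroField(), domain, cells, rng)
        assert out.last_tier == 1 and out.time == pytest.approx(0.1)
        step = np.hypot(*(out.position - [20.0, 30.0]))
        assert step == pytest.approx(np.sqrt(4 * spec.diffusion * 0.1))

    def test_wall_hugging_particle_reaches_tier3(self, single_cell_setup):
        domain, cells, spec = single_cell_setup
        rng = np.random.default_rng(1)
        state = ParticleState(np.array([0.15, 30.0]))  # 0.15 um from the inlet
        tiers = set()
        for _ in range(50):
            if state.status != "mobile":
                break
            state = advance_particle(state, spec, StepPolicy(), ZeroField(), domain, cells, rng)
            tiers.add(state.last_tier)
        assert 3 in tiers

    def test_advancing_nonmobile_raises(self, single_cell_setup):
        domain, cells, spec = single_cell_setup
        state = ParticleState(np.array([20.0, 30.0]), status="captured")
        with pytest.raises(ValueError):
            advance_particle(state, spec, StepPolicy(), ZeroField(), domain, cells,
                             np.random.default_rng(0))

    def test_particle_inside_cell_is_geometry_error(self, single_cell_setup):
        domain, cells, spec = single_cell_setup
        state = ParticleState(np.array([50.0, 30.0]))
        with pytest.raises(RuntimeError, match="inside a cell"):
            advance_particle(state, spec, StepPolicy(), ZeroField(), domain, cells,
                             np.random.default_rng(0))

    def test_guard_no_interpenetration_along_trajectory(self, single_cell_setup):
        """After every accepted step the particle circle overlaps nothing."""
        domain, cells, spec = single_cell_setup
        rng = np.random.default_rng(4)
        for start in ([38.5, 30.0], [2.0, 5.0], [60.5, 30.0]):
            state = ParticleState(np.array(start))
            for _ in range(400):
                if state.status != "mobile":
                    break
                state = advance_particle(
                    state, spec, StepPolicy(), ZeroField(), domain, cells, rng
                )
                dist_cell = np.hypot(*(state.position - cells.centers[0]))
                if state.status == "captured":
                    assert dist_cell == pytest.approx(cells.cell_radius + spec.radius)
                    break
                assert dist_cell > cells.cell_radius + spec.radius - 1e-9
                assert spec.radius - 1e-9 <= state.position[1] <= domain.height - spec.radius + 1e-9
                assert state.position[0] >= spec.radius - 1e-9


class TestHandleCollision:
    def test_certain_capture_lands_on_contact_point(self, single_cell_setup):
        domain, cells, _ = single_cell_setup
        spec = ParticleSpec.from_physics(0.1, rho=1.0)
        state = ParticleState(np.array([38.0, 30.0]))  # 1.9 um gap to contact
        attempted = np.array([41.0, 30.0])  # head-on, ends inside the cell
        out = handle_collision(state, attempted, 0, cells, spec, np.random.default_rng(0), domain)
        assert out.status == "captured" and out.capture_cell == 0 and out.collisions == 1
        np.testing.assert_allclose(out.position, [39.9, 30.0], atol=1e-12)

    def test_head_on_reflection_preserves_penetration_depth(self, single_cell_setup):
        domain, cells, _ = single_cell_setup
        spec = ParticleSpec.from_physics(0.1, rho=0.0)
        state = ParticleState(np.array([38.0, 30.0]))
        attempted = np.array([41.0, 30.0])  # would penetrate 1.1 um past contact
        out = handle_collision(state, attempted, 0, cells, spec, np.random.default_rng(0), domain)
        assert out.status == "mobile" and out.collisions == 1
        np.testing.assert_allclose(out.position, [38.8, 30.0], atol=1e-12)


class TestEnsembles:
    def test_empty_ensemble(self, no_cells):
        cfg = sb.RunConfig(porosity=1.0, n_particles=0, v_in=0.0, seed=1)
        res = sb.simulate_ensemble(cfg, cells=no_cells)
        assert res.n_particles == 0

    def test_same_seed_reproduces_exactly(self, tissue):
        cfg, cells = tissue
        cfg = cfg.replace(v_in=0.0, n_particles=100, t_end=20.0)
        a = sb.simulate_ensemble(cfg, cells=cells)
        b = sb.simulate_ensemble(cfg, cells=cells)
        c = sb.simulate_ensemble(cfg.replace(seed=cfg.seed + 1), cells=cells)
        assert a.data.equals(b.data)
        assert not a.data["x"].equals(c.data["x"])

    def test_geometric_capture_law(self, single_cell_capture_run):
        """Contacts before capture at a sticky wall are geometric, mean 1/rho."""
        cap = single_cell_capture_run.data.query("status == 'captured'")
        assert len(cap) == single_cell_capture_run.n_particles  # closed box
        contacts = cap["collisions"].to_numpy()
        se = contacts.std(ddof=1) / np.sqrt(len(contacts))
        assert abs(contacts.mean() - 1 / 0.2) <= 3 * se

    def test_rho_extremes(self):
        cells = sb.CellField(np.array([[15.0, 15.0]]), 10.0, np.pi * 100 / 900)
        base = sb.RunConfig(domain_width=30, domain_height=30, porosity=1.0, v_in=0.0,
                            n_particles=200, t_end=300.0, seed=8)
        entry = np.column_stack([np.full(200, 2.0), np.full(200, 15.0)])
        never = sb.simulate_ensemble(base.replace(capture_probability=0.0),
                                     cells=cells, entry_positions=entry)
        assert never.captured_fraction == 0.0
        assert never.data["collisions"].sum() > 0  # they do collide, just never stick
        always = sb.simulate_ensemble(base.replace(capture_probability=1.0),
                                      cells=cells, entry_positions=entry)
        # a finite horizon cannot guarantee every walker meets the cell,
        # but in this closed box nearly all do, and each capture is final
        assert always.captured_fraction > 0.95
        cap = always.data.query("status == 'captured'")
        assert np.all(cap["collisions"] == 1)  # first contact captures
        d = np.hypot(cap["x"] - 15, cap["y"] - 15)
        np.testing.assert_allclose(d, 10.1, atol=1e-9)  # parked on the rim

    def test_python_step_agrees_with_compiled_ensemble(self, no_cells):
        """The readable per-step implementation and the compiled kernels
        realize the same process: cell-free MSD matches 4Dt for both."""
        D = sb.diffusion_coefficient(0.1)
        spec = ParticleSpec.from_physics(0.1, rho=0.0)
        domain = sb.DomainSpec(1000, 500)
        rng = np.random.default_rng(12)
        n_py, t_end = 150, 10.0
        msds = []
        for _ in range(n_py):
            state = ParticleState(np.array([500.0, 250.0]))
            while state.time < t_end - 1e-9:
                state = advance_particle(state, spec, StepPolicy(), ZeroField(),
                                         domain, no_cells, rng)
            msds.append(((state.position - [500.0, 250.0]) ** 2).sum())
        msds = np.asarray(msds)
        py_ratio = msds.mean() / (4 * D * t_end)
        se = msds.std(ddof=1) / np.sqrt(n_py) / (4 * D * t_end)
        assert py_ratio == pytest.approx(1.0, abs=3 * se)

        cfg = sb.RunConfig(porosity=1.0, v_in=0.0, n_particles=2000, t_end=t_end, seed=13)
        entry = np.column_stack([np.full(2000, 500.0), np.full(2000, 250.0)])
        res = sb.simulate_ensemble(cfg, cells=no_cells, entry_positions=entry)
        nb = ((res.data.x - 500) ** 2 + (res.data.y - 250) ** 2).to_numpy()
        nb_ratio = nb.mean() / (4 * D * t_end)
        comb = 3 * np.hypot(se, nb.std(ddof=1) / np.sqrt(len(nb)) / (4 * D * t_end))
        assert abs(py_ratio - nb_ratio) <= comb

    def test_exit_through_open_right_edge_recorded(self, no_cells):
        cfg = sb.RunConfig(domain_width=20, domain_height=100, cell_radius=2.0,
                           porosity=1.0, v_in=1.0, n_particles=50, t_end=100.0, seed=3)
        res = sb.simulate_ensemble(cfg, cells=no_cells)
        assert (res.data["status"] == "exited_right").all()
        assert (res.data["t_final"] < 100.0).all()

    def test_fixed_step_layer_controls_capture(self, tissue):
        """A vanishing interaction layer is jumped over: captures disappear."""
        cfg, cells = tissue
        cfg = cfg.replace(v_in=0.0, n_particles=300, t_end=50.0)
        thin = sb.simulate_fixed_step(cfg, dt=0.01, layer=1e-4, rho=1.0, cells=cells)
        thick = sb.simulate_fixed_step(cfg, dt=0.01, layer=0.25, rho=1.0, cells=cells)
        assert thin.captured_fraction < 0.05
        assert thick.captured_fraction > 5 * max(thin.captured_fraction, 0.02)

    def test_cross_engine_agreement_without_capture(self, tissue):
        """With rho = 0 the adaptive and fixed-step engines describe the same
        physics; penetration statistics agree within sampling error."""
        cfg, cells = tissue
        cfg = cfg.replace(v_in=0.0, capture_probability=0.0, n_particles=800, t_end=100.0)
        ma = sb.mean_penetration_depth(sb.simulate_ensemble(cfg, cells=cells))
        mf = sb.mean_penetration_depth(
            sb.simulate_fixed_step(cfg, dt=1e-3, layer=0.25, rho=0.0, cells=cells)
        )
        assert abs(ma.mean - mf.mean) <= 3 * np.hypot(ma.se, mf.se)
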