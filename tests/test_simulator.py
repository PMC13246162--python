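"""Simulator: potentials, integrator physics, protocol and pressure."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from condsieve import simulator as sim
from condsieve.units import kbt_mech, pa_per_kbt_nm3


def pair_state(t1, t2, r, ff, bond_class=None, box=30.0):
    """Two beads a distance r apart, optionally bonded."""
    types = np.array([t1, t2], np.int32)
    mol = np.zeros(2, np.int32) if bond_class else np.array([0, 1], np.int32)
    if bond_class:
        kind, p1, p2, beps, bsig = ff.bond_params(bond_class)
        topo = sim.Topology(
            types, mol, np.array([0], np.int32), np.array([1], np.int32),
            np.array([kind], np.int32), np.array([[p1, p2, beps, bsig]]),
        )
    else:
        topo = sim.Topology(
            types, mol, np.empty(0, np.int32), np.empty(0, np.int32),
            np.empty(0, np.int32), np.empty((0, 4)),
        )
    state = sim.SystemState(
        pos=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        vel=np.zeros((2, 3)),
        types=types, mol=mol, box=np.array([box] * 3, float),
    )
    return state, topo


def pair_energy(t1, t2, r, ff, bond_class=None):
    state, topo = pair_state(t1, t2, r, ff, bond_class)
    epot, _, _ = sim.potential_energy(state, ff, topo)
    return epot


class TestPotentials:
    def test_wca_endpoint_identities(self):
        ff = sim.forcefield_compact()
        sigma = 2.0  # C-C
        assert pair_energy(2, 2, sigma, ff) == pytest.approx(ff.wca_eps, abs=1e-12)
        assert pair_energy(2, 2, 2 ** (1 / 6) * sigma, ff) == pytest.approx(
            0.0, abs=1e-12
        )
        assert pair_energy(2, 2, 3.0, ff) == 0.0

    def test_sticker_attraction_endpoints(self):
        ff = sim.forcefield_compact()  # u0 = 18.8, r0 = 0.3
        assert pair_energy(0, 1, 1e-12, ff) == pytest.approx(-18.8, rel=1e-9)
        assert pair_energy(0, 1, 0.3 - 1e-12, ff) == pytest.approx(0.0, abs=1e-9)

    def test_client_shell_endpoints(self):
        ff = sim.forcefield_compact(client_eps=5.0)
        assert pair_energy(0, 3, 1.5, ff) == pytest.approx(-5.0, rel=1e-12)
        assert pair_energy(0, 3, 1.8 - 1e-10, ff) == pytest.approx(0.0, abs=1e-8)
        assert pair_energy(0, 3, 1.0, ff) == 0.0

    def test_fene_spring_vanishes_at_zero_extension(self):
        """The FENE log term alone is zero at r -> 0 (its WCA core off)."""
        ff = dataclasses.replace(sim.forcefield_compact(), wca_eps=0.0)
        assert pair_energy(2, 2, 1e-9, ff, "backbone") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_fene_overextension_raises(self):
        ff = sim.forcefield_compact()
        with pytest.raises(sim.SimulationError):
            pair_energy(2, 2, 14.5, ff, "backbone")

    def test_forces_match_energy_gradient(self):
        """Analytic forces agree with central finite differences."""
        ff = sim.forcefield_compact(client_eps=3.0)
        topo = sim.compact_spacer_topology(2, 3, ff)
        cfg = sim.SimulationConfig(box=(25.0, 25.0, 25.0), wall_x=None, seed=4)
        state = sim.build_system(topo, cfg, ff, np.random.default_rng(4))
        _, forces, _ = sim.potential_energy(state, ff, topo)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(12):
            i = rng.integers(state.n)
            d = rng.integers(3)
            state.pos[i, d] += h
            e_hi, _, _ = sim.potential_energy(state, ff, topo)
            state.pos[i, d] -= 2 * h
            e_lo, _, _ = sim.potential_energy(state, ff, topo)
            state.pos[i, d] += h
            fd = -(e_hi - e_lo) / (2 * h)
            scale = max(abs(fd), np.abs(forces).max(), 1.0)
            assert abs(fd - forces[i, d]) / scale < 1e-6


class TestSystemConstruction:
    def test_full_scale_topology_counts(self):
        topo = sim.compact_spacer_topology(50, 50)
        assert topo.n == 50 * 20 + 50  # 10 spacers + 10 stickers each, 50 D
        topo = sim.spacers_only_topology(60, 450)
        assert topo.n == 27000

    def test_preset_polymer_volumes_follow_printed_geometry(self):
        """Per-polymer excluded volume from the printed bead counts/radii:
        10 spheres of 1 nm (41.9 nm^3) vs 450 of 0.3 nm (50.9 nm^3)."""
        v_compact = 10 * (4 / 3) * math.pi * 1.0**3
        v_idr = 450 * (4 / 3) * math.pi * 0.3**3
        assert v_compact == pytest.approx(41.89, abs=0.01)
        assert v_idr == pytest.approx(50.89, abs=0.01)

    def test_empty_topology_gives_empty_state(self):
        topo = sim.particles_only_topology(0)
        cfg = sim.SimulationConfig(box=(10.0, 10.0, 10.0), wall_x=None)
        state = sim.build_system(topo, cfg, sim.forcefield_compact(), 0)
        assert state.n == 0

    def test_infeasible_packing_rejected(self):
        topo = sim.particles_only_topology(2000)
        cfg = sim.SimulationConfig(box=(12.0, 12.0, 12.0), wall_x=None)
        with pytest.raises(ValueError):
            sim.build_system(topo, cfg, sim.forcefield_compact(), 0)

    def test_confined_polymers_start_inside_walls(self):
        topo, ff, cfg = sim.coexistence_preset("compact", "mini", n_particles=0, seed=0)
        state = sim.build_system(topo, cfg, ff, 0)
        poly = state.types != sim.TYPE_D
        assert np.all(np.abs(state.pos[poly, 0]) < cfg.wall_x + 1.0)


class TestIntegrator:
    def test_static_without_forces_and_noise(self):
        topo = sim.particles_only_topology(5)
        ff = dataclasses.replace(sim.forcefield_compact(), wca_eps=0.0)
        cfg = sim.SimulationConfig(box=(40.0, 40.0, 40.0), wall_x=None)
        state = sim.build_system(topo, cfg, ff, 1)
        state.vel[:] = 0.0
        before = state.pos.copy()
        eng = sim.Engine(topo, ff, cfg)
        eng.run(state, 100, np.random.default_rng(0), thermostat=False)
        assert np.array_equal(state.pos, before)

    def test_identical_seeds_identical_trajectories(self):
        runs = []
        for _ in range(2):
            topo, ff, cfg = sim.coexistence_preset("compact", "mini",
                                                   n_particles=4, seed=9)
            cfg = dataclasses.replace(
                cfg, steps_soft=500, steps_initial=500, steps_anneal=1000,
                steps_equilibrate=500, steps_release=500,
                steps_production=1000, record_every=500,
            )
            runs.append(sim.run_protocol(topo, cfg, ff))
        for f1, f2 in zip(runs[0].frames, runs[1].frames):
            assert np.array_equal(f1, f2)

    def test_zero_production_yields_initial_frame_only(self):
        topo, ff, cfg = sim.coexistence_preset("compact", "mini", n_particles=0, seed=9)
        cfg = dataclasses.replace(
            cfg, steps_soft=200, steps_initial=200, steps_anneal=400,
            steps_equilibrate=200, steps_release=200, steps_production=0,
        )
        traj = sim.run_protocol(topo, cfg, ff)
        assert traj.n_frames == 1

    def test_energy_conservation_without_thermostat(self):
        """Velocity-Verlet core: relative drift < 1e-4 over 1e4 steps at dt/10."""
        topo, ff, cfg = sim.coexistence_preset("compact", "mini", n_particles=10, seed=1)
        cfg = dataclasses.replace(cfg, dt=cfg.dt / 10)
        rng = np.random.default_rng(0)
        state = sim.build_system(topo, cfg, ff, rng)
        eng = sim.Engine(topo, ff, cfg)
        eng.run(state, 2_000, rng, thermostat=True)  # settle contacts first
        mass = np.array([bt.mass for bt in ff.bead_types])[state.types]

        def total_energy():
            epot, _, _ = sim.potential_energy(state, ff, topo)
            ke = 0.5 * np.sum(mass[:, None] * state.vel**2) / kbt_mech(300.0)
            return epot + ke

        e0 = total_energy()
        eng.run(state, 10_000, rng, thermostat=False)
        assert abs(total_energy() - e0) / abs(e0) < 1e-4

    def test_equipartition_temperature(self, equipartition_run):
        t_mean = equipartition_run.mean()
        assert t_mean == pytest.approx(300.0, rel=0.02)

    def test_free_particle_diffusion(self, free_particle_run):
        """Windowed MSD slope reproduces D = kBT/(6 pi eta r) for water."""
        snaps = free_particle_run["snapshots"]
        dt_w = free_particle_run["dt_window"]
        tau = 1.0
        disp2 = [
            np.sum((b - a) ** 2, axis=1) for a, b in zip(snaps[:-1], snaps[1:])
        ]
        msd = float(np.mean(disp2))
        d_meas = msd / (6.0 * (dt_w - tau))  # inertial correction t >> tau
        from condsieve.units import stokes_einstein_diffusivity

        d_expect = stokes_einstein_diffusivity(1.5)
        assert d_meas == pytest.approx(d_expect, rel=0.05)


class TestPressure:
    def _ideal_traj(self, box):
        topo = sim.particles_only_topology(100)
        rng = np.random.default_rng(0)
        frames = [rng.uniform(-box[0] / 2, box[0] / 2, (100, 3)) for _ in range(3)]
        return topo, sim.Trajectory(
            frames=frames, steps=[0, 1, 2], box=np.asarray(box, float),
            types=topo.types, mol=topo.mol, type_radii=np.array([0.3, 0.3, 1.0, 1.5]),
        )

    def test_ideal_gas_is_exact(self):
        topo, traj = self._ideal_traj((30.0, 30.0, 30.0))
        ff = dataclasses.replace(sim.forcefield_compact(), wca_eps=0.0)
        p, _ = sim.osmotic_pressure(traj, ff, topo)
        assert p == pytest.approx(100 / 30**3 * pa_per_kbt_nm3(300.0), rel=1e-12)

    def test_ideal_gas_halves_on_volume_doubling(self):
        ff = dataclasses.replace(sim.forcefield_compact(), wca_eps=0.0)
        topo, traj1 = self._ideal_traj((30.0, 30.0, 30.0))
        _, traj2 = self._ideal_traj((30.0, 30.0, 60.0))
        p1, _ = sim.osmotic_pressure(traj1, ff, topo)
        p2, _ = sim.osmotic_pressure(traj2, ff, topo)
        assert p2 == pytest.approx(p1 / 2)

    def test_virial_matches_bruteforce_recomputation(self, spacers_mini):
        """Cell-list virial equals an all-pairs numpy recomputation, and the
        block-averaged pressure sits within 3 sigma of the oracle average."""
        traj, topo, ff = (spacers_mini[k] for k in ("traj", "topo", "ff"))
        box = traj.box
        bonded = set(zip(topo.bond_i.tolist(), topo.bond_j.tolist()))
        oracle_p = []
        for frame in traj.frames[-4:]:
            d = frame[:, None, :] - frame[None, :, :]
            d -= box * np.round(d / box)
            r2 = np.sum(d**2, axis=-1)
            iu = np.triu_indices(frame.shape[0], 1)
            w = 0.0
            sig2 = 0.36
            for k in np.where(r2[iu] < 2 ** (1 / 3) * sig2)[0]:
                i, j = iu[0][k], iu[1][k]
                if (i, j) in bonded or (j, i) in bonded:
                    continue
                s6 = (sig2 / r2[iu][k]) ** 3
                w += 24.0 * (2 * s6 * s6 - s6)
            for b in range(topo.bond_i.size):
                i, j = topo.bond_i[b], topo.bond_j[b]
                dv = frame[i] - frame[j]
                dv -= box * np.round(dv / box)
                r = np.linalg.norm(dv)
                w += -2.0 * 692.0 * (r - 0.38) * r
            impl = sim.frame_virial(frame, traj, ff, topo)
            assert impl == pytest.approx(w, rel=1e-8)
            oracle_p.append((frame.shape[0] + w / 3) / np.prod(box))
        p, err = sim.osmotic_pressure(traj, ff, topo)
        oracle = np.mean(oracle_p) * pa_per_kbt_nm3(300.0)
        assert abs(p - oracle) < max(3 * err, 0.5 * abs(oracle)) + 1e-9


class TestChainStatistics:
    def test_self_avoiding_exponent(self, saw_scaling):
        """End-to-end distance scales as N^nu with nu near 0.588."""
        ns = np.array(sorted(saw_scaling))
        rs = np.array([saw_scaling[n] for n in ns])
        res = stats.linregress(np.log(ns), np.log(rs))
        assert 0.55 <= res.slope <= 0.63


class TestCoexistence:
    def test_one_to_one_sticker_binding(self, compact_mini):
        """Same-type repulsion keeps A:B binding one-to-one: under 5% of
        bound stickers hold two or more partners within the well range."""
        traj = compact_mini["traj"]
        from scipy.spatial import cKDTree

        multi = 0
        bound = 0
        for frame in traj.frames[-5:]:
            a = frame[traj.types == sim.TYPE_A]
            b = frame[traj.types == sim.TYPE_B]
            tree = cKDTree(np.mod(b + traj.box / 2, traj.box), boxsize=traj.box)
            counts = tree.query_ball_point(
                np.mod(a + traj.box / 2, traj.box), r=0.3, return_length=True
            )
            bound += int(np.sum(counts >= 1))
            multi += int(np.sum(counts >= 2))
        assert bound > 0
        assert multi / max(bound, 1) < 0.05

    def test_single_dense_cluster_forms(self, compact_mini, idr_mini):
        """The IDR condensate keeps essentially every chain in one cluster;
        the weakly excluding compact condensate sustains a real dilute
        polymer population, so its largest-cluster fraction sits lower."""
        from condsieve.analysis import largest_cluster_fraction

        for data, bound in ((compact_mini, 0.6), (idr_mini, 0.8)):
            traj = data["traj"]
            frac = largest_cluster_fraction(
                traj.frames[-1], traj.types, traj.mol, traj.box, traj.type_radii
            )
            assert frac > bound
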