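"""Shared fixtures: desk-scale simulations are expensive, so every
coexistence/recruitment trajectory is computed once per session and shared
between the unit tests and the acceptance suite."""

import dataclasses

import numpy as np
import pytest

from condsieve import analysis, simulator as sim, widom


@pytest.fixture(scope="session")
def compact_mini():
    """Desk-scale compact-spacer coexistence run with 40 neutral particles."""
    topo, ff, cfg = sim.coexistence_preset("compact", "mini", n_particles=40, seed=3)
    traj = analysis.recenter_trajectory(sim.run_protocol(topo, cfg, ff))
    return {"traj": traj, "topo": topo, "ff": ff, "cfg": cfg}


@pytest.fixture(scope="session")
def idr_mini():
    """Desk-scale IDR-spacer coexistence run (450-mer chains, no particles)."""
    topo, ff, cfg = sim.coexistence_preset("idr", "mini", n_particles=0, seed=3)
    traj = analysis.recenter_trajectory(sim.run_protocol(topo, cfg, ff))
    return {"traj": traj, "topo": topo, "ff": ff, "cfg": cfg}


@pytest.fixture(scope="session")
def recruit_sweep():
    """Client-attraction sweep on the compact system, eps = 2, 6, 10 kBT.

    For each attraction strength: the coexistence trajectory, the measured
    partitioning of the particles, the dense-phase KD/site-density, and the
    Widom exclusion free energy of a client-sized probe.
    """
    regions = analysis.PhaseRegions(7.0, 24.0)
    out = {}
    for eps in (2.0, 6.0, 10.0):
        topo, ff, cfg = sim.coexistence_preset(
            "compact", "mini", n_particles=60, seed=7, client_eps=eps
        )
        cfg = dataclasses.replace(cfg, steps_production=250_000, record_every=5_000)
        traj = analysis.recenter_trajectory(sim.run_protocol(topo, cfg, ff))
        prof = analysis.density_profile(traj, species=("C", "D"))
        part = analysis.partition_coefficient_measured(prof, regions, species="D")
        kd = analysis.measure_KD(traj, regions, binding_range=1.8)
        job = widom.InsertionJob(
            probe_radii=(1.5,), grid_shape=(40, 40, 40), slab=(-7.0, 7.0)
        )
        res = widom.insert_hard_spheres(traj, job)
        df0 = float(res.free_energy[0])
        out[eps] = {
            "traj": traj,
            "partition": part,
            "kd": kd,
            "delta_f0": df0,
            "predicted": -kd.rho_sites / kd.kd + df0,
        }
    return {"regions": regions, "sweep": out}


@pytest.fixture(scope="session")
def spacers_mini():
    """Homogeneous self-avoiding chain box (fast-bead parameters)."""
    topo, ff, cfg = sim.spacers_only_preset("mini", seed=1)
    traj = sim.run_protocol(topo, cfg, ff)
    return {"traj": traj, "topo": topo, "ff": ff, "cfg": cfg}


@pytest.fixture(scope="session")
def free_particle_run():
    """Dilute non-bonded D beads: windowed displacements and temperatures."""
    topo = sim.particles_only_topology(192)
    ff = sim.forcefield_compact()
    cfg = sim.SimulationConfig(box=(250.0, 250.0, 250.0), wall_x=None)
    rng = np.random.default_rng(21)
    state = sim.build_system(topo, cfg, ff, rng)
    eng = sim.Engine(topo, ff, cfg)
    eng.run(state, 5_000, rng)  # velocity decorrelation
    snapshots = [state.pos.copy()]
    temps = []
    for _ in range(24):
        eng.run(state, 5_000, rng)
        snapshots.append(state.pos.copy())
        temps.append(sim.kinetic_temperature(state, ff))
    return {
        "snapshots": snapshots,
        "temps": np.array(temps),
        "dt_window": 5_000 * cfg.dt,
        "ff": ff,
    }


@pytest.fixture(scope="session")
def equipartition_run():
    """Interacting compact-spacer fluid with thermostat at 300 K."""
    topo, ff, cfg = sim.coexistence_preset("compact", "mini", n_particles=10, seed=1)
    rng = np.random.default_rng(2)
    state = sim.build_system(topo, cfg, ff, rng)
    eng = sim.Engine(topo, ff, cfg)
    eng.run(state, 5_000, rng, walls=True)
    temps = []
    for _ in range(60):
        eng.run(state, 1_000, rng, walls=True)
        temps.append(sim.kinetic_temperature(state, ff))
    return np.array(temps)


@pytest.fixture(scope="session")
def saw_scaling():
    """End-to-end statistics of dilute self-avoiding chains, N = 25/50/100."""
    from condsieve.analysis import chain_end_to_end

    means = {}
    for n_mono, steps, n_chains in ((25, 150_000, 12), (50, 300_000, 10),
                                    (100, 600_000, 8)):
        ff = sim.forcefield_spacers_only()
        topo = sim.spacers_only_topology(n_chains, n_mono, ff)
        cfg = sim.SimulationConfig(
            box=(80.0, 80.0, 80.0), wall_x=None, tau=0.1, dt=1e-3, chunk_steps=500
        )
        rng = np.random.default_rng(11)
        state = sim.build_system(topo, cfg, ff, rng)
        eng = sim.Engine(topo, ff, cfg)
        eng.run(state, steps // 2, rng)
        samples = []
        for _ in range(10):
            eng.run(state, steps // 20, rng)
            samples.append(chain_end_to_end(state.pos, topo) ** 2)
        means[n_mono] = float(np.sqrt(np.mean(samples)))
    return means
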