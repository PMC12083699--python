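"""Shared fixtures.

The two session-scoped fixtures below are the expensive experimental setups:
``drift_replicates`` runs replicate full-scale simulations to MCS 2100 for
the 100-MCS baseline-drift measurement, and ``e2e_artifacts`` runs the
desk-scale end-to-end experiment (small lattice, short simulations, small
U-Net) used to check that the trained surrogate carries predictive signal.
Everything else is cheap and function-scoped.
"""

import numpy as np
import pytest

from pottsnet import (
    CPMParams, SurrogateConfig, Trajectory, TrajectoryRecorder,
    build_pairs, build_surrogate, initialize_simulation, run, train,
)


def make_state(sigma, params):
    from pottsnet.cpm import SimState

    sigma = np.asarray(sigma, dtype=np.int32)
    return SimState(sigma, np.zeros_like(sigma, dtype=np.float64), params)


def random_state(rng, params, n_cells=3):
    """Small random-blob state with a random nonnegative field."""
    state = initialize_simulation(params, n_cells=n_cells, rng=rng)
    state.field = rng.random(state.field.shape)
    return state


@pytest.fixture
def small_params():
    return CPMParams(lattice_size=16, pde_substeps_per_mcs=13)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def _simulate(params, n_cells, mcs_end, seed, select):
    rg = np.random.default_rng(seed)
    state = initialize_simulation(params, n_cells=n_cells, rng=rg)
    traj = Trajectory(params=params, seed=seed, sim_id=f"sim{seed}")
    rec = TrajectoryRecorder(traj, select=select)
    run(state, params, mcs_end, rg, recorder=rec)
    return traj, state


@pytest.fixture(scope="session")
def drift_replicates():
    """Five replicate vasculogenesis simulations at full scale (256^2,
    ~1000 cells) run to MCS 2100, keeping the MCS-2000 and MCS-2100 frames."""
    params = CPMParams()
    out = []
    for seed in range(5):
        traj, _ = _simulate(params, n_cells=1000, mcs_end=2100, seed=seed,
                            select={2000, 2100})
        out.append(traj)
    return params, out


E2E_LATTICE = 64
E2E_N_CELLS = 60          # matches the full-scale area density
E2E_MCS_END = 3000
E2E_RECORD_STRIDE = 25
E2E_PAIR_STRIDE = 50
E2E_N_TRAIN_SIMS = 4


@pytest.fixture(scope="session")
def e2e_artifacts():
    """Desk-scale end-to-end experiment: 4 training simulations plus one
    held-out simulation on a 64^2 lattice, and a depth-3/base-16 U-Net
    trained for 20 epochs on 100-MCS pairs."""
    params = CPMParams(lattice_size=E2E_LATTICE)
    trajs = []
    for seed in range(E2E_N_TRAIN_SIMS + 1):
        traj, _ = _simulate(params, n_cells=E2E_N_CELLS, mcs_end=E2E_MCS_END,
                            seed=100 + seed,
                            select=(200, E2E_MCS_END, E2E_RECORD_STRIDE))
        trajs.append(traj)
    train_trajs, holdout = trajs[:E2E_N_TRAIN_SIMS], trajs[-1]
    pairs = []
    for traj in train_trajs:
        pairs.extend(build_pairs(traj, 200, E2E_MCS_END, lag=100,
                                 step=E2E_PAIR_STRIDE))
    config = SurrogateConfig(depth=3, base_channels=16, epochs=20,
                             batch_size=8, learning_rate=1e-3, seed=0,
                             lattice_size=E2E_LATTICE)
    model = build_surrogate(config)
    model, history = train(model, pairs, [], config)
    return {"params": params, "model": model, "history": history,
            "holdout": holdout, "config": config}
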