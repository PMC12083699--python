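"""Copy-attempt dynamics: bookkeeping audits, determinism, limits."""

import numpy as np
import pytest

from pottsnet import (
    CPMParams, attempt_copy, initialize_simulation, monte_carlo_step, run,
)
from pottsnet.errors import ContractViolation, ParameterError, PackingError
from pottsnet.trajectory import (
    Trajectory, TrajectoryRecorder, load_checkpoint, save_checkpoint,
)

from conftest import make_state, random_state


def test_frozen_at_low_temperature():
    """With only a volume constraint at exactly V = v_target, every possible
    copy raises the energy, so at vanishing temperature nothing ever moves."""
    params = CPMParams(lattice_size=16, j_cell_medium=0.0, j_cell_cell=0.0,
                       lambda_surface=0.0, lambda_chemotaxis=0.0,
                       v_target=9.0, temperature=1e-9, secretion_rate=0.0,
                       pde_substeps_per_mcs=13)
    sigma = np.zeros((16, 16), dtype=int)
    sigma[4:7, 4:7] = 1
    sigma[10:13, 10:13] = 2
    state = make_state(sigma, params)
    rng = np.random.default_rng(0)
    before = state.sigma.copy()
    for _ in range(20):
        monte_carlo_step(state, params, rng)
    assert np.array_equal(state.sigma, before)


def test_extinct_cell_leaves_registry():
    """A one-pixel cell overwritten by medium disappears from the registry."""
    params = CPMParams(lattice_size=16, v_target=1.0, lambda_surface=0.0,
                       lambda_chemotaxis=0.0, pde_substeps_per_mcs=13)
    sigma = np.zeros((16, 16), dtype=int)
    sigma[8, 8] = 1
    state = make_state(sigma, params)
    rng = np.random.default_rng(1)
    for _ in range(20000):
        attempt_copy(state, rng, params)
        if not state.cells:
            break
    assert state.cells == {}
    assert (state.sigma == 0).all()
    state.audit(params)


def test_caches_survive_many_attempts(rng):
    """Incrementally maintained volumes/surfaces equal lattice recomputation
    after a long random attempt sequence."""
    params = CPMParams(lattice_size=32, pde_substeps_per_mcs=13)
    state = random_state(rng, params, n_cells=12)
    for _ in range(10000):
        attempt_copy(state, rng, params)
    state.audit(params)


def test_registry_volumes_match_lattice(rng):
    params = CPMParams(lattice_size=32, pde_substeps_per_mcs=13)
    state = random_state(rng, params, n_cells=8)
    for _ in range(2000):
        attempt_copy(state, rng, params)
    for cid, info in state.cells.items():
        assert info.volume == int((state.sigma == cid).sum())


def test_mcs_deterministic_given_seed():
    params = CPMParams(lattice_size=16, pde_substeps_per_mcs=13)
    results = []
    for _ in range(2):
        rng = np.random.default_rng(123)
        state = initialize_simulation(params, n_cells=3, rng=rng)
        for _ in range(10):
            monte_carlo_step(state, params, rng)
        results.append((state.sigma.copy(), state.field.copy()))
    assert np.array_equal(results[0][0], results[1][0])
    assert np.array_equal(results[0][1], results[1][1])


def test_mcs_without_cells_only_decays_field(small_params):
    state = make_state(np.zeros((16, 16), dtype=int), small_params)
    state.field[:] = 1.0
    rng = np.random.default_rng(0)
    monte_carlo_step(state, small_params, rng)
    assert (state.sigma == 0).all()
    expected = (1.0 - small_params.k_decay * small_params.dt) \
        ** small_params.pde_substeps_per_mcs
    np.testing.assert_allclose(state.field, expected, rtol=1e-12)
    assert state.mcs == 1


def test_audits_pass_after_100_mcs():
    params = CPMParams(lattice_size=64, pde_substeps_per_mcs=13)
    rng = np.random.default_rng(5)
    state = initialize_simulation(params, n_cells=55, rng=rng)
    run(state, params, 100, rng)
    state.audit(params)
    assert state.mcs == 100


# -- initialization ---------------------------------------------------------

def test_initialize_empty():
    params = CPMParams(lattice_size=32, pde_substeps_per_mcs=13)
    state = initialize_simulation(params, n_cells=0, seed=0)
    assert (state.sigma == 0).all()
    assert state.cells == {}
    assert state.mcs == 0
    assert (state.field == 0).all()


def test_initialize_density_and_audit():
    params = CPMParams(lattice_size=64, pde_substeps_per_mcs=13)
    state = initialize_simulation(params, n_cells=60, seed=3)
    assert len(state.cells) == 60
    total = int((state.sigma > 0).sum())
    assert total == sum(c.volume for c in state.cells.values())
    assert total <= 64 * 64
    state.audit(params)


def test_initialize_reproducible():
    params = CPMParams(lattice_size=64, pde_substeps_per_mcs=13)
    a = initialize_simulation(params, n_cells=40, seed=9)
    b = initialize_simulation(params, n_cells=40, seed=9)
    assert np.array_equal(a.sigma, b.sigma)


def test_initialize_infeasible():
    params = CPMParams(lattice_size=16, pde_substeps_per_mcs=13)
    with pytest.raises(ParameterError):
        initialize_simulation(params, n_cells=10, seed=0)  # 500 px > 256
    with pytest.raises(PackingError):
        # area-feasible but unplaceable under bounded retries
        initialize_simulation(params, n_cells=5, seed=0, max_tries_per_cell=1)


# -- run / recording / resume ----------------------------------------------

def test_run_records_one_frame_per_mcs(small_params):
    state = make_state(np.zeros((16, 16), dtype=int), small_params)
    traj = Trajectory(params=small_params)
    rec = TrajectoryRecorder(traj)
    rng = np.random.default_rng(0)
    run(state, small_params, state.mcs + 1, rng, recorder=rec)
    assert traj.mcs_list == [1]
    with pytest.raises(ContractViolation):
        run(state, small_params, state.mcs, rng)


def test_recorded_frame_count_over_protocol_window():
    """Recording every MCS of [200, 20000] yields 19801 frames."""
    params = CPMParams(lattice_size=8, pde_substeps_per_mcs=13)
    state = make_state(np.zeros((8, 8), dtype=int), params)
    counter = {"n": 0}

    def recorder(s):
        if 200 <= s.mcs <= 20000:
            counter["n"] += 1

    run(state, params, 20000, np.random.default_rng(0), recorder=recorder)
    assert counter["n"] == 19801


def test_interrupted_run_resumes_identically(tmp_path):
    params = CPMParams(lattice_size=16, pde_substeps_per_mcs=13)
    rng = np.random.default_rng(77)
    state = initialize_simulation(params, n_cells=3, rng=rng)
    run(state, params, 10, rng)
    ckpt = tmp_path / "state.npz"
    save_checkpoint(ckpt, state, rng, params)
    run(state, params, 20, rng)  # continue the original

    resumed, rng2, params2 = load_checkpoint(ckpt)
    assert params2 == params
    run(resumed, params2, 20, rng2)
    assert np.array_equal(resumed.sigma, state.sigma)
    np.testing.assert_array_equal(resumed.field, state.field)
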