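"""Cellular-Potts simulator of vasculogenesis on a periodic 2-D lattice.

The model couples Metropolis pixel-copy dynamics under an effective energy

    H = sum_contacts J(tau, tau') + sum_cells [ lambda_v (V - V_t)^2
        + lambda_s (S - S_t)^2 ]  (+ a per-copy saturating chemotaxis bias)

to a secretion-diffusion-decay chemical field dc/dt = D lap(c) - k c + a(x).
Cells secrete the field and chemotax up its gradient, which drives the
aggregation of ~1000 randomly seeded cells into a vascular-like network with
enclosed lacunae.

A copy attempt picks a random site y and a random neighbor y'; the index at y
invades y' with Boltzmann probability exp(-max(0, dH)/H').  One Monte-Carlo
step (MCS) is lattice_size^2 attempts followed by the PDE substeps for one
time unit.  The chemotaxis term exists only for copies (it compares the field
at the source and destination of a move) and therefore contributes to dH but
not to the static energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .errors import ContractViolation, CorruptStateError, PackingError, ParameterError
from .params import CPMParams

__all__ = [
    "CellInfo", "SimState", "CopyAttempt",
    "compute_volumes", "compute_surfaces",
    "total_energy", "delta_h", "acceptance_probability", "attempt_copy",
    "diffusion_step", "monte_carlo_step", "initialize_simulation", "run",
]


@dataclass
class CellInfo:
    """Registry entry for one cell: type, volume, raw boundary-contact count."""
    type: int
    volume: int
    surface: int


@dataclass
class CopyAttempt:
    """A proposed pixel copy from ``source`` onto neighboring ``dest``."""
    source: tuple
    dest: tuple
    delta_h: float


def compute_volumes(sigma: np.ndarray, capacity: int) -> np.ndarray:
    """Pixel count per cell index, from the lattice (index 0 = medium is not
    tracked and reports 0)."""
    vol = np.bincount(sigma.ravel(), minlength=capacity).astype(np.int64)
    vol[0] = 0
    return vol


def compute_surfaces(sigma: np.ndarray, offsets: np.ndarray, capacity: int) -> np.ndarray:
    """Heterotypic (site, neighbor) contact count per cell index.

    Counts, for every pixel of a cell, its neighbors under ``offsets`` that
    hold a different index (periodic wrap).  Index 0 (medium) is zeroed.
    """
    surf = np.zeros(capacity, dtype=np.int64)
    for dy, dx in offsets:
        rolled = np.roll(sigma, (-int(dy), -int(dx)), axis=(0, 1))
        mism = sigma != rolled
        surf += np.bincount(sigma[mism], minlength=capacity)
    surf[0] = 0
    return surf


class SimState:
    """One simulation snapshot: cell-index lattice, chemical field, registry.

    ``sigma`` holds the cell index at each site (0 = medium); ``field`` the
    chemical concentration.  Per-cell volume and boundary-contact counts are
    cached in flat arrays indexed by cell id and kept incrementally up to
    date by the dynamics; ``audit`` recomputes them from the lattice.
    """

    def __init__(self, sigma: np.ndarray, field: np.ndarray, params: CPMParams,
                 mcs: int = 0):
        sigma = np.ascontiguousarray(sigma, dtype=np.int32)
        field = np.ascontiguousarray(field, dtype=np.float64)
        if sigma.shape != field.shape or sigma.ndim != 2:
            raise ContractViolation("sigma and field must be equal-shape 2-D arrays")
        self.sigma = sigma
        self.field = field
        self.mcs = int(mcs)
        cap = int(sigma.max()) + 1
        self._vol = compute_volumes(sigma, cap)
        self._surf = compute_surfaces(sigma, params.surface_offsets, cap)

    @property
    def capacity(self) -> int:
        return self._vol.shape[0]

    @property
    def cells(self) -> dict:
        """Registry view: cell index -> CellInfo for every live cell."""
        return {
            int(i): CellInfo(type=1, volume=int(self._vol[i]), surface=int(self._surf[i]))
            for i in np.nonzero(self._vol[1:])[0] + 1
        }

    def copy(self) -> "SimState":
        new = object.__new__(SimState)
        new.sigma = self.sigma.copy()
        new.field = self.field.copy()
        new.mcs = self.mcs
        new._vol = self._vol.copy()
        new._surf = self._surf.copy()
        return new

    def cell_mask(self) -> np.ndarray:
        return self.sigma > 0

    def audit(self, params: CPMParams) -> None:
        """Verify cached volumes/surfaces against the lattice and the field's
        sanity; raises CorruptStateError on any mismatch."""
        vol = compute_volumes(self.sigma, self.capacity)
        if not np.array_equal(vol, self._vol):
            raise CorruptStateError("cached cell volumes disagree with lattice")
        surf = compute_surfaces(self.sigma, params.surface_offsets, self.capacity)
        surf_cached = self._surf.copy()
        surf_cached[vol == 0] = 0
        surf[vol == 0] = 0
        if not np.array_equal(surf, surf_cached):
            raise CorruptStateError("cached cell surfaces disagree with lattice")
        if not np.all(np.isfinite(self.field)) or np.any(self.field < 0):
            raise CorruptStateError("field has non-finite or negative values")


def _kernel_args(params: CPMParams):
    return (
        params.lambda_volume, params.v_target,
        params.lambda_surface, params.s_target, params.surface_scale,
        params.j_cell_medium, params.j_cell_cell,
        params.lambda_chemotaxis, params.s_saturation,
    )


def total_energy(state: SimState, params: CPMParams) -> float:
    """Static effective energy: contact + volume + surface terms over the
    whole lattice (the chemotaxis bias is per-copy and excluded here).
    Recomputed from the lattice; deterministic."""
    sigma = state.sigma
    lattice_ids = np.unique(sigma)
    lattice_ids = lattice_ids[lattice_ids > 0]
    live = set(state.cells)
    if not set(int(i) for i in lattice_ids) <= live:
        raise CorruptStateError("lattice holds an unregistered cell index")

    # Contact energy: each unordered neighbor pair once, via half-offsets.
    half = [(dy, dx) for dy, dx in {(int(a), int(b)) for a, b in params.copy_offsets}
            if dy > 0 or (dy == 0 and dx > 0)]
    e_contact = 0.0
    for dy, dx in half:
        rolled = np.roll(sigma, (-dy, -dx), axis=(0, 1))
        differ = sigma != rolled
        both_cell = differ & (sigma > 0) & (rolled > 0)
        n_cc = int(both_cell.sum())
        n_cm = int(differ.sum()) - n_cc
        e_contact += n_cc * params.j_cell_cell + n_cm * params.j_cell_medium

    cap = state.capacity
    vol = compute_volumes(sigma, cap)
    surf = compute_surfaces(sigma, params.surface_offsets, cap)
    alive = vol[1:] > 0
    e_vol = params.lambda_volume * np.sum((vol[1:][alive] - params.v_target) ** 2)
    e_surf = params.lambda_surface * np.sum(
        (params.surface_scale * surf[1:][alive] - params.s_target) ** 2)
    return float(e_contact + e_vol + e_surf)


def _check_neighbor(y, y_prime, params: CPMParams, shape):
    H, W = shape
    dy = (y_prime[0] - y[0]) % H
    dx = (y_prime[1] - y[1]) % W
    if dy > H // 2:
        dy -= H
    if dx > W // 2:
        dx -= W
    offs = {(int(a), int(b)) for a, b in params.copy_offsets}
    if (dy, dx) not in offs:
        raise ContractViolation(f"sites {y} and {y_prime} are not lattice neighbors")


def delta_h(state: SimState, y: tuple, y_prime: tuple, params: CPMParams) -> float:
    """Exact energy change of copying sigma[y] onto neighboring y_prime,
    including the per-copy chemotaxis bias.  Matches
    total_energy(after) - total_energy(before) plus the chemotaxis term."""
    _check_neighbor(y, y_prime, params, state.sigma.shape)
    if state.sigma[y] == state.sigma[y_prime]:
        raise ContractViolation("copy must change the lattice: sigma(y) == sigma(y')")
    dh, _, _ = _kernels.attempt_delta_h(
        state.sigma, state.field, state._vol, state._surf,
        y[0], y[1], y_prime[0], y_prime[1],
        *_kernel_args(params), params.copy_offsets, params.surface_offsets)
    return float(dh)


def acceptance_probability(delta_h: float, temperature: float) -> float:
    """Boltzmann acceptance exp(-max(0, dH)/H'); 1 for all dH <= 0."""
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    return math.exp(-max(0.0, delta_h) / temperature)


def attempt_copy(state: SimState, rng: np.random.Generator, params: CPMParams) -> bool:
    """One random copy attempt, updating lattice and cached registry in place.

    Draws a uniform site, a uniform neighbor and an acceptance uniform (all
    three are consumed even for the same-index no-op).  A cell whose volume
    reaches 0 disappears from the registry view.
    """
    n = state.sigma.size
    site = np.asarray([rng.integers(n)], dtype=np.int64)
    nei = np.asarray([rng.integers(len(params.copy_offsets))], dtype=np.int64)
    u = np.asarray([rng.random()], dtype=np.float64)
    acc = _kernels.run_attempts(
        state.sigma, state.field, state._vol, state._surf, site, nei, u,
        *_kernel_args(params), params.temperature,
        params.copy_offsets, params.surface_offsets)
    return bool(acc)


def diffusion_step(field: np.ndarray, cell_sites: np.ndarray, params: CPMParams,
                   dt: float) -> np.ndarray:
    """One forward-Euler update of the secretion-diffusion-decay field.

    c <- c + dt (D lap c - k c) with a periodic 5-point Laplacian, plus
    dt * secretion_rate at every cell-occupied site; negatives clipped to 0.
    """
    if dt > params.stable_dt_bound() + 1e-12:
        raise ParameterError("dt violates the stability bound dt <= 1/(4 D + k)")
    lap = (np.roll(field, 1, axis=0) + np.roll(field, -1, axis=0)
           + np.roll(field, 1, axis=1) + np.roll(field, -1, axis=1) - 4.0 * field)
    out = field + dt * (params.d_diffusion * lap - params.k_decay * field)
    out += dt * params.secretion_rate * cell_sites
    np.clip(out, 0.0, None, out=out)
    return out


def monte_carlo_step(state: SimState, params: CPMParams,
                     rng: np.random.Generator) -> SimState:
    """One MCS: lattice_size^2 copy attempts, then the PDE substeps for one
    time unit.  Mutates and returns ``state``; mcs increments by 1."""
    n = state.sigma.size
    n_off = len(params.copy_offsets)
    sites = rng.integers(0, n, size=n, dtype=np.int64)
    neis = rng.integers(0, n_off, size=n, dtype=np.int64)
    us = rng.random(n)
    _kernels.run_attempts(
        state.sigma, state.field, state._vol, state._surf, sites, neis, us,
        *_kernel_args(params), params.temperature,
        params.copy_offsets, params.surface_offsets)
    state.field = _kernels.pde_steps(
        state.field, state.sigma, params.d_diffusion, params.k_decay,
        params.secretion_rate, params.dt, params.pde_substeps_per_mcs)
    state.mcs += 1
    return state


def initialize_simulation(params: CPMParams, n_cells: int = 1000,
                          seed=None, rng: Optional[np.random.Generator] = None,
                          max_tries_per_cell: int = 2000) -> SimState:
    """Seed ``n_cells`` non-overlapping square cell patches at uniform-random
    torus positions; field starts at 0, mcs at 0.

    Patches are ~v_target/2 pixels: at the model's density (1000 cells of 50
    px on 256^2, i.e. 76% final coverage) full-size patches cannot be placed
    by random sequential adsorption, whereas half-size seeds keep initial
    coverage below the jamming limit and cells inflate to v_target within the
    first few MCS under the volume constraint.
    """
    L = params.lattice_size
    if n_cells * params.v_target > L * L:
        raise ParameterError("n_cells * v_target exceeds the lattice area")
    if rng is None:
        rng = np.random.default_rng(seed)
    side = max(1, int(round(math.sqrt(params.v_target / 2.0))))
    sigma = np.zeros((L, L), dtype=np.int32)
    occupied = np.zeros((L, L), dtype=bool)
    ii = np.arange(side)
    for cid in range(1, n_cells + 1):
        for _ in range(max_tries_per_cell):
            r = int(rng.integers(L))
            c = int(rng.integers(L))
            rows = (r + ii) % L
            cols = (c + ii) % L
            block = occupied[np.ix_(rows, cols)]
            if not block.any():
                occupied[np.ix_(rows, cols)] = True
                sigma[np.ix_(rows, cols)] = cid
                break
        else:
            raise PackingError(
                f"could not place cell {cid} of {n_cells} after "
                f"{max_tries_per_cell} tries")
    return SimState(sigma, np.zeros((L, L)), params, mcs=0)


def run(state: SimState, params: CPMParams, mcs_end: int,
        rng: np.random.Generator,
        recorder: Optional[Callable[[SimState], None]] = None) -> SimState:
    """Advance ``state`` to ``mcs_end``, invoking ``recorder(state)`` after
    every MCS.  The state is mutated in place, so a run interrupted after any
    MCS resumes identically by calling ``run`` again with the same rng."""
    if mcs_end <= state.mcs:
        raise ContractViolation("mcs_end must exceed the state's current mcs")
    while state.mcs < mcs_end:
        monte_carlo_step(state, params, rng)
        if recorder is not None:
            recorder(state)
    return state
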