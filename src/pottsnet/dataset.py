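"""Surrogate training data: 2-channel frame encoding, lag pairing, splits.

A simulation snapshot is encoded as a 2-channel raster: a binary cell mask
(1 = any cell) and the chemical field divided by a fixed global scale and
clipped to [0, 1].  The scale is a documented constant (default 1.0, the
steady-state plateau secretion/decay of the default parameters) rather than a
per-frame normalization, so squared-error comparisons are meaningful across
frames.  Training examples pair the frame at MCS t with the frame at t+100
from the same simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation, ParameterError
from .trajectory import Trajectory

DEFAULT_NORM_SCALE = 1.0
DEFAULT_LAG = 100


@dataclass
class EncodedFrame:
    """2-channel surrogate input/output raster."""
    cell: np.ndarray    # uint8 in {0,1}
    field: np.ndarray   # float32 in [0,1]
    mcs: int = -1
    sim_id: str = ""

    def stacked(self) -> np.ndarray:
        """(2, H, W) float32 array: cell mask then field channel."""
        return np.stack([self.cell.astype(np.float32),
                         self.field.astype(np.float32)])


@dataclass
class TrainingPair:
    """Index view of an (input, target) pair over a trajectory store."""
    trajectory: Trajectory
    mcs_in: int
    mcs_out: int
    norm_scale: float = DEFAULT_NORM_SCALE

    @property
    def sim_id(self) -> str:
        return self.trajectory.sim_id

    def input(self) -> EncodedFrame:
        return encode_arrays(self.trajectory.sigma(self.mcs_in),
                             self.trajectory.field(self.mcs_in),
                             self.norm_scale, mcs=self.mcs_in, sim_id=self.sim_id)

    def target(self) -> EncodedFrame:
        return encode_arrays(self.trajectory.sigma(self.mcs_out),
                             self.trajectory.field(self.mcs_out),
                             self.norm_scale, mcs=self.mcs_out, sim_id=self.sim_id)


def encode_arrays(sigma: np.ndarray, field: np.ndarray,
                  norm_scale: float = DEFAULT_NORM_SCALE,
                  mcs: int = -1, sim_id: str = "") -> EncodedFrame:
    """Encode raw lattice arrays: indicator(sigma > 0) and clip(c/scale, 0, 1).

    The mask channel is lossless; the field channel is lossy above
    ``norm_scale`` (values clip to 1), which the default parameters only
    reach at the secretion/decay plateau.
    """
    if norm_scale <= 0:
        raise ParameterError("norm_scale must be > 0")
    cell = (np.asarray(sigma) > 0).astype(np.uint8)
    fld = np.clip(np.asarray(field, dtype=np.float32) / norm_scale, 0.0, 1.0)
    return EncodedFrame(cell=cell, field=fld, mcs=int(mcs), sim_id=sim_id)


def encode_state(state, norm_scale: float = DEFAULT_NORM_SCALE,
                 sim_id: str = "") -> EncodedFrame:
    """Encode a ``SimState`` into the 2-channel representation."""
    return encode_arrays(state.sigma, state.field, norm_scale,
                         mcs=state.mcs, sim_id=sim_id)


def build_pairs(trajectory: Trajectory, start: int = 200, end: int = 20000,
                lag: int = DEFAULT_LAG, step: int = 1,
                norm_scale: float = DEFAULT_NORM_SCALE) -> list[TrainingPair]:
    """One pair per t in [start, end - lag] (stride ``step``): frame(t) with
    frame(t + lag).  With step=1 the count is end - lag - start + 1.

    Raises TrajectoryGapError listing absent MCS if the trajectory does not
    hold every required frame.
    """
    if lag <= 0 or step <= 0:
        raise ParameterError("lag and step must be positive")
    t_in = list(range(start, end - lag + 1, step))
    trajectory.require(sorted({*t_in, *(t + lag for t in t_in)}))
    return [TrainingPair(trajectory, t, t + lag, norm_scale) for t in t_in]


def split_dataset(pairs: list, train_fraction: float = 0.8, seed=0,
                  granularity: str = "pair"):
    """Disjoint, exhaustive, seeded-shuffled train/test split.

    granularity="pair" shuffles individual pairs (train size ceil(f*n));
    granularity="simulation" assigns whole simulations to one side, which is
    the leakage-safe choice when frames overlap between pairs.
    """
    if not pairs:
        raise ParameterError("pairs must be nonempty")
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if granularity == "pair":
        order = rng.permutation(len(pairs))
        n_train = math.ceil(train_fraction * len(pairs))
        train = [pairs[i] for i in order[:n_train]]
        test = [pairs[i] for i in order[n_train:]]
    elif granularity == "simulation":
        sims = sorted({p.sim_id for p in pairs})
        order = rng.permutation(len(sims))
        n_train = math.ceil(train_fraction * len(sims))
        train_sims = {sims[i] for i in order[:n_train]}
        train = [p for p in pairs if p.sim_id in train_sims]
        test = [p for p in pairs if p.sim_id not in train_sims]
    else:
        raise ParameterError("granularity must be 'pair' or 'simulation'")
    return train, test


def write_manifest(path, trajectory_files, start, end, lag, step,
                   train_fraction, seed, norm_scale, granularity) -> None:
    """JSON manifest recording how a dataset was assembled."""
    with open(path, "w") as fh:
        json.dump({
            "trajectories": [str(p) for p in trajectory_files],
            "start": start, "end": end, "lag": lag, "step": step,
            "train_fraction": train_fraction, "seed": seed,
            "norm_scale": norm_scale, "granularity": granularity,
        }, fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
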