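"""Trajectory storage: in-memory frame store, HDF5 persistence, recorders.

A trajectory holds (sigma, field) snapshots keyed by MCS for one simulation,
plus the parameters and seed that produced it.  Recorders are callables
handed to ``cpm.run``; they decide which MCS to persist, so a 20,000-MCS run
can keep every frame, a strided subset, or just two snapshots.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

import h5py
import numpy as np

from .errors import TrajectoryGapError
from .params import CPMParams


class Trajectory:
    """Ordered (sigma, field) snapshots for one simulation."""

    def __init__(self, params: Optional[CPMParams] = None, seed=None,
                 sim_id: str = "sim"):
        self.params = params
        self.seed = seed
        self.sim_id = sim_id
        self._frames: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self._frames)

    def __contains__(self, mcs: int) -> bool:
        return int(mcs) in self._frames

    @property
    def mcs_list(self) -> list[int]:
        return sorted(self._frames)

    def add(self, mcs: int, sigma: np.ndarray, field: np.ndarray) -> None:
        self._frames[int(mcs)] = (
            np.asarray(sigma, dtype=np.int32).copy(),
            np.asarray(field, dtype=np.float64).copy(),
        )

    def sigma(self, mcs: int) -> np.ndarray:
        return self._frames[int(mcs)][0]

    def field(self, mcs: int) -> np.ndarray:
        return self._frames[int(mcs)][1]

    def require(self, mcs_values: Iterable[int]) -> None:
        """Raise TrajectoryGapError listing any absent MCS."""
        missing = [m for m in mcs_values if int(m) not in self._frames]
        if missing:
            raise TrajectoryGapError(missing)

    # -- persistence -------------------------------------------------------

    def save_h5(self, path) -> None:
        mcs = np.asarray(self.mcs_list, dtype=np.int64)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("mcs", data=mcs)
            if len(mcs):
                sig = np.stack([self._frames[m][0] for m in mcs])
                fld = np.stack([self._frames[m][1] for m in mcs])
                fh.create_dataset("sigma", data=sig, compression="gzip", compression_opts=1)
                fh.create_dataset("field", data=fld, compression="gzip", compression_opts=1)
            fh.attrs["sim_id"] = self.sim_id
            fh.attrs["seed"] = json.dumps(self.seed)
            if self.params is not None:
                fh.attrs["params"] = json.dumps(self.params.to_dict())

    @classmethod
    def load_h5(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as fh:
            params = None
            if "params" in fh.attrs:
                params = CPMParams.from_dict(json.loads(fh.attrs["params"]))
            seed = json.loads(fh.attrs.get("seed", "null"))
            traj = cls(params=params, seed=seed, sim_id=str(fh.attrs.get("sim_id", "sim")))
            mcs = fh["mcs"][...]
            if len(mcs):
                sig = fh["sigma"][...]
                fld = fh["field"][...]
                for i, m in enumerate(mcs):
                    traj._frames[int(m)] = (sig[i], fld[i])
        return traj

    def export_png(self, mcs: int, path) -> None:
        """Write the binary cell mask at ``mcs`` as an 8-bit PNG for inspection."""
        import imageio.v3 as iio

        mask = (self.sigma(mcs) > 0).astype(np.uint8) * 255
        iio.imwrite(path, mask)


class TrajectoryRecorder:
    """Recorder for ``cpm.run`` persisting frames whose MCS passes a filter.

    ``select`` may be None (keep every MCS), a collection of MCS values, or a
    (start, stop, stride) tuple interpreted like an inclusive range.
    """

    def __init__(self, trajectory: Trajectory, select=None):
        self.trajectory = trajectory
        if select is None:
            self._keep = lambda m: True
        elif isinstance(select, tuple) and len(select) == 3:
            start, stop, stride = select
            self._keep = lambda m: start <= m <= stop and (m - start) % stride == 0
        else:
            wanted = {int(m) for m in select}
            self._keep = lambda m: m in wanted
        self.n_recorded = 0

    def __call__(self, state) -> None:
        if self._keep(state.mcs):
            self.trajectory.add(state.mcs, state.sigma, state.field)
            self.n_recorded += 1


def save_checkpoint(path, state, rng: np.random.Generator,
                    params: CPMParams) -> None:
    """Persist a resumable snapshot: lattice, field, mcs, params and the full
    bit-generator state, so a continued run is bit-identical."""
    np.savez_compressed(
        path, sigma=state.sigma, field=state.field, mcs=state.mcs,
        params=json.dumps(params.to_dict()),
        rng_state=json.dumps(rng.bit_generator.state))


def load_checkpoint(path):
    """Inverse of ``save_checkpoint``; returns (state, rng, params)."""
    from .cpm import SimState

    with np.load(path, allow_pickle=False) as data:
        params = CPMParams.from_dict(json.loads(str(data["params"])))
        state = SimState(data["sigma"], data["field"], params, mcs=int(data["mcs"]))
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(str(data["rng_state"]))
    return state, rng, params
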