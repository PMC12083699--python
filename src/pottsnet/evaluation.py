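"""Recursive-rollout benchmarking of a surrogate against ground truth.

The protocol: freeze a reference state (default MCS 2000) from a held-out
simulation, roll the surrogate forward in 100-MCS increments, and at every
iteration compare both the prediction and the *unchanged* reference frame
against the true trajectory.  The frozen reference is the "do nothing"
baseline: a surrogate is only informative where its metrics beat it.

Each rollout yields a per-iteration table (Dice, field MSE, lacunae-area
EMD, vessel area, field mass, for prediction and reference); replicate
tables aggregate into per-iteration mean/s.d. with pairwise-deleted EMD
(an EMD entry is missing when one of the two area distributions is empty).
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .dataset import DEFAULT_NORM_SCALE, encode_arrays
from .errors import ContractViolation, CoverageError
from .metrics import dice, emd, field_mse, lacunae_areas, summarize_state
from .surrogate import DEFAULT_THRESHOLD, predict_step
from .trajectory import Trajectory

METRIC_COLUMNS = [
    "dice_pred", "dice_ref", "mse_pred", "mse_ref", "emd_pred", "emd_ref",
    "vessel_area_pred", "vessel_area_truth", "field_mass_pred", "field_mass_truth",
]


class IdentitySurrogate:
    """Trivial surrogate returning its input; the frozen-reference baseline
    expressed as a model (pred metrics == ref metrics, used in tests)."""

    class config:
        lattice_size = None
        threshold = DEFAULT_THRESHOLD


def _predict(model, frame, threshold):
    from .surrogate import PredictionFrame

    if isinstance(model, IdentitySurrogate):
        prob = frame.cell.astype(np.float64)
        return PredictionFrame(cell_prob=prob, cell_mask=frame.cell.astype(bool),
                               field=frame.field.astype(np.float64),
                               mcs=frame.mcs + 100)
    return predict_step(model, frame, threshold)


def evaluate_rollout(model, truth: Trajectory, reference_mcs: int = 2000,
                     n_iterations: int = 100,
                     norm_scale: float = DEFAULT_NORM_SCALE,
                     threshold: float = DEFAULT_THRESHOLD,
                     lag: int = 100,
                     lacunae_method: str = "seam") -> pd.DataFrame:
    """Roll the surrogate out from ``reference_mcs`` and score every step.

    Returns a DataFrame with one row per iteration i (mcs = reference + lag*i)
    holding prediction-vs-truth and frozen-reference-vs-truth metrics.
    """
    needed = [reference_mcs + lag * i for i in range(n_iterations + 1)]
    missing = [m for m in needed if m not in truth]
    if missing:
        raise CoverageError(
            f"truth trajectory does not cover MCS {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    ref = encode_arrays(truth.sigma(reference_mcs), truth.field(reference_mcs),
                        norm_scale, mcs=reference_mcs, sim_id=truth.sim_id)
    ref_lac = lacunae_areas(ref.cell, method=lacunae_method)

    rows = []
    current = ref
    for i in range(1, n_iterations + 1):
        pred = _predict(model, current, threshold)
        mcs = reference_mcs + lag * i
        true = encode_arrays(truth.sigma(mcs), truth.field(mcs), norm_scale,
                             mcs=mcs, sim_id=truth.sim_id)
        true_lac = lacunae_areas(true.cell, method=lacunae_method)
        pred_lac = lacunae_areas(pred.cell_mask.astype(np.uint8),
                                 method=lacunae_method)
        pred_sum = summarize_state(pred.to_encoded())
        true_sum = summarize_state(true)
        rows.append({
            "iteration": i,
            "mcs": mcs,
            "dice_pred": dice(pred.cell_mask, true.cell),
            "dice_ref": dice(ref.cell, true.cell),
            "mse_pred": field_mse(pred.field, true.field),
            "mse_ref": field_mse(ref.field, true.field),
            "emd_pred": _safe_emd(pred_lac, true_lac),
            "emd_ref": _safe_emd(ref_lac, true_lac),
            "vessel_area_pred": pred_sum.vessel_area,
            "vessel_area_truth": true_sum.vessel_area,
            "field_mass_pred": pred_sum.field_mass,
            "field_mass_truth": true_sum.field_mass,
        })
        current = pred.to_encoded()
    return pd.DataFrame(rows)


def _safe_emd(a, b) -> float:
    if len(a) == 0 and len(b) == 0:
        return float("nan")
    return emd(a, b)


def aggregate(series_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-iteration mean and s.d. of every metric over replicate rollouts.

    NaN EMD entries (empty lacunae distributions) are excluded pairwise;
    ``n_<col>`` columns report how many replicates contributed.  With a
    single replicate every s.d. is 0.
    """
    if not series_list:
        raise ContractViolation("series list must be nonempty")
    lengths = {len(s) for s in series_list}
    if len(lengths) != 1:
        raise ContractViolation(f"series lengths differ: {sorted(lengths)}")
    out = {"iteration": series_list[0]["iteration"].to_numpy(),
           "mcs": series_list[0]["mcs"].to_numpy(),
           "n_replicates": np.full(len(series_list[0]), len(series_list))}
    import warnings

    for col in METRIC_COLUMNS:
        stacked = np.stack([s[col].to_numpy(dtype=np.float64) for s in series_list])
        with warnings.catch_warnings():
            # an all-missing iteration legitimately aggregates to NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"mean_{col}"] = np.nanmean(stacked, axis=0)
            out[f"sd_{col}"] = np.nanstd(stacked, axis=0, ddof=0)
        out[f"n_{col}"] = np.sum(~np.isnan(stacked), axis=0)
    return pd.DataFrame(out)


def timing_harness(model, params, n_configs: int = 100, mcs: int = 100,
                   seed: int = 0, n_cells: int | None = None) -> pd.DataFrame:
    """Wall-clock comparison: advancing the simulator by ``mcs`` steps versus
    one surrogate evaluation, over ``n_configs`` random configurations.

    Informational only - the numbers are hardware-dependent.  Returns a
    fixed-schema table with per-method medians and their ratio.
    """
    from .cpm import initialize_simulation, run
    from .dataset import encode_state

    if n_cells is None:
        n_cells = max(4, int(0.76 * params.lattice_size ** 2 / params.v_target))
    rng = np.random.default_rng(seed)
    sim_times, sur_times = [], []
    for _ in range(n_configs):
        state = initialize_simulation(params, n_cells=n_cells, rng=rng)
        t0 = time.perf_counter()
        run(state, params, state.mcs + mcs, rng)
        sim_times.append(time.perf_counter() - t0)
        frame = encode_state(state)
        t0 = time.perf_counter()
        _predict(model, frame, DEFAULT_THRESHOLD)
        sur_times.append(time.perf_counter() - t0)
    med_sim = float(np.median(sim_times))
    med_sur = float(np.median(sur_times))
    return pd.DataFrame([
        {"method": "cpm", "median_s": med_sim, "sd_s": float(np.std(sim_times)),
         "n": n_configs, "ratio_vs_surrogate": med_sim / med_sur},
        {"method": "surrogate", "median_s": med_sur, "sd_s": float(np.std(sur_times)),
         "n": n_configs, "ratio_vs_surrogate": 1.0},
    ])
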