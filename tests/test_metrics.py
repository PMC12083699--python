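"""Dice, field MSE, periodic lacunae-area extraction, and EMD.

The torus union-find oracle below is an independent breadth-first flood fill
over wrapped coordinates; it arbitrates the periodic labeling in
``lacunae_areas`` on randomized masks.
"""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pottsnet import dice, emd, field_mse, lacunae_areas, summarize_state
from pottsnet.dataset import EncodedFrame
from pottsnet.errors import ContractViolation, PottsNetError


def torus_region_areas_oracle(medium):
    """Flood-fill areas of 4-connected medium components with wraparound."""
    h, w = medium.shape
    seen = np.zeros_like(medium, dtype=bool)
    areas = []
    for i in range(h):
        for j in range(w):
            if not medium[i, j] or seen[i, j]:
                continue
            area = 0
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                a, b = queue.popleft()
                area += 1
                for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    na, nb = (a + da) % h, (b + db) % w
                    if medium[na, nb] and not seen[na, nb]:
                        seen[na, nb] = True
                        queue.append((na, nb))
            areas.append(area)
    return sorted(areas)


# -- dice -------------------------------------------------------------------

def test_dice_identities(rng):
    m = rng.random((12, 12)) > 0.5
    assert dice(m, m) == 1.0
    assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0  # both empty
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[0, 0] = True
    b[3, 3] = True
    assert dice(a, b) == 0.0


def test_dice_counted_example():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[0, :4] = True            # |A| = 4
    b[0, 2:] = True
    b[1, :2] = True            # |B| = 4, overlap 2
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_shape_mismatch():
    with pytest.raises(ContractViolation):
        dice(np.zeros((4, 4)), np.zeros((5, 4)))


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
def test_dice_symmetric_and_bounded(bits_a, bits_b):
    a = np.array([(bits_a >> k) & 1 for k in range(16)]).reshape(4, 4)
    b = np.array([(bits_b >> k) & 1 for k in range(16)]).reshape(4, 4)
    d = dice(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice(b, a)


# -- field mse --------------------------------------------------------------

def test_field_mse_identities(rng):
    f = rng.random((8, 8))
    assert field_mse(f, f) == 0.0
    assert field_mse(f, f + 0.3) == pytest.approx(0.09)
    g = rng.random((8, 8))
    brute = sum((f[i, j] - g[i, j]) ** 2 for i in range(8) for j in range(8)) / 64
    assert field_mse(f, g) == pytest.approx(brute, rel=1e-12)
    with pytest.raises(ContractViolation):
        field_mse(f, np.zeros((4, 4)))


# -- lacunae ----------------------------------------------------------------

@pytest.mark.parametrize("method", ["seam", "tiled"])
def test_all_medium_is_one_torus_lacuna(method):
    dist = lacunae_areas(np.zeros((16, 16), dtype=int), method=method)
    assert list(dist.areas) == [16 * 16]


@pytest.mark.parametrize("method", ["seam", "tiled"])
def test_small_specks_excluded(method):
    mask = np.ones((16, 16), dtype=int)
    mask[3, 4:6] = 0                      # area-2 lacuna: dropped
    mask[10:13, 10:14] = 0                # area-12 lacuna: kept
    dist = lacunae_areas(mask, method=method)
    assert list(dist.areas) == [12]


@pytest.mark.parametrize("method", ["seam", "tiled"])
def test_wrap_straddling_lacuna_counted_once(method):
    """A hole crossing both periodic seams reports its full wrapped area."""
    mask = np.ones((16, 16), dtype=int)
    mask[14:, 14:] = 0
    mask[:2, 14:] = 0
    mask[14:, :2] = 0
    mask[:2, :2] = 0                      # one 4x4 torus hole at the corner
    dist = lacunae_areas(mask, method=method)
    assert list(dist.areas) == [16]


def test_lacunae_match_torus_oracle(rng):
    """Area multisets equal the flood-fill oracle on 100+ random masks."""
    for trial in range(110):
        p = rng.uniform(0.3, 0.8)
        mask = (rng.random((16, 16)) < p).astype(int)
        got = sorted(lacunae_areas(mask, min_area=1).areas)
        expected = torus_region_areas_oracle(mask == 0)
        assert got == expected, f"trial {trial}"


def test_lacunae_shift_invariant(rng):
    mask = (rng.random((24, 24)) < 0.6).astype(int)
    base = sorted(lacunae_areas(mask).areas)
    for shift in [(1, 0), (0, 7), (13, 5)]:
        rolled = np.roll(mask, shift, axis=(0, 1))
        assert sorted(lacunae_areas(rolled).areas) == base


def test_tiled_method_agrees_on_network_like_masks(rng):
    """The tiling + inertia-eigenvalue procedure reproduces the exact
    periodic labeling on blob-like masks."""
    from scipy.ndimage import gaussian_filter
    for seed in range(5):
        r = np.random.default_rng(seed)
        mask = (gaussian_filter(r.random((32, 32)), 2, mode="wrap") < 0.5).astype(int)
        a = sorted(lacunae_areas(mask, method="seam").areas)
        b = sorted(lacunae_areas(mask, method="tiled").areas)
        assert a == b


def test_lacunae_rejects_non_binary():
    with pytest.raises(ContractViolation):
        lacunae_areas(np.full((4, 4), 2))


# -- emd --------------------------------------------------------------------

def _sorted_coupling(a, b):
    """Independent oracle for equal-size multisets: optimal 1-D transport
    pairs sorted samples."""
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


def test_emd_examples():
    mk = lambda xs: np.asarray(xs, dtype=float)
    assert emd(mk([4, 9, 9]), mk([9, 4, 9])) == 0.0
    assert emd(mk([0]), mk([5])) == 5.0
    assert emd(mk([1, 3]), mk([2, 4])) == pytest.approx(
        _sorted_coupling([1, 3], [2, 4])) == pytest.approx(1.0)


def test_emd_symmetry_and_triangle(rng):
    for _ in range(20):
        a, b, c = (rng.integers(1, 60, size=rng.integers(2, 9)).astype(float)
                   for _ in range(3))
        dab, dba = emd(a, b), emd(b, a)
        assert dab == pytest.approx(dba)
        assert emd(a, c) <= dab + emd(b, c) + 1e-9


def test_emd_empty_handling():
    with pytest.raises(PottsNetError):
        emd(np.asarray([]), np.asarray([]))
    assert np.isnan(emd(np.asarray([]), np.asarray([3.0])))


# -- summaries --------------------------------------------------------------

def test_summarize_state(rng):
    empty = EncodedFrame(cell=np.zeros((8, 8), dtype=np.uint8),
                         field=np.zeros((8, 8), dtype=np.float32))
    s = summarize_state(empty)
    assert s.vessel_area == 0 and s.field_mass == 0.0

    full = EncodedFrame(cell=np.ones((256, 256), dtype=np.uint8),
                        field=np.zeros((256, 256), dtype=np.float32))
    assert summarize_state(full).vessel_area == 65536

    cell = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    field = rng.random((8, 8)).astype(np.float32)
    s = summarize_state(EncodedFrame(cell=cell, field=field))
    assert s.vessel_area == int(cell.sum())
    assert s.field_mass == pytest.approx(float(field.sum()), rel=1e-6)
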