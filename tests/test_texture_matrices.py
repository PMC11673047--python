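"""Texture-matrix correctness against independent brute-force enumeration.

The oracles below recount pairs, runs, zones, dependencies and neighbour
differences with plain python loops, sharing no code with the vectorized
builders under test.
"""

import numpy as np
import pytest

from ctharmony import radiomics as rx

OFFSETS = rx.DEFAULT_OFFSETS
NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_glcm(binned, mask, offset, symmetric):
    ng = int(binned[mask].max())
    p = np.zeros((ng, ng))
    h, w = mask.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if mask[r, c] and 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                p[binned[r, c] - 1, binned[rr, cc] - 1] += 1
    if symmetric:
        p = p + p.T
    return p / p.sum() if p.sum() else p


def oracle_glrlm(binned, mask, direction):
    ng = int(binned[mask].max())
    h, w = mask.shape
    dr, dc = direction
    runs = {}
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            # run starts where the predecessor is absent or different
            if 0 <= pr < h and 0 <= pc < w and mask[pr, pc] and \
                    binned[pr, pc] == binned[r, c]:
                continue
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and \
                    binned[rr, cc] == binned[r, c]:
                length += 1
                rr += dr
                cc += dc
            runs[(binned[r, c], length)] = runs.get((binned[r, c], length), 0) + 1
    maxlen = max((l for _, l in runs), default=1)
    p = np.zeros((ng, maxlen))
    for (g, l), n in runs.items():
        p[g - 1, l - 1] = n
    return p


def oracle_glszm(binned, mask):
    ng = int(binned[mask].max())
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = binned[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGH8:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and \
                            not seen[nr, nc] and binned[nr, nc] == level:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((level, size))
    maxs = max(s for _, s in zones)
    p = np.zeros((ng, maxs))
    for g, s in zones:
        p[g - 1, s - 1] += 1
    return p


def oracle_gldm(binned, mask, alpha=0):
    ng = int(binned[mask].max())
    h, w = mask.shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 1
            for dr, dc in NEIGH8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and \
                        abs(int(binned[nr, nc]) - int(binned[r, c])) <= alpha:
                    dep += 1
            entries.append((binned[r, c], dep))
    maxd = max(d for _, d in entries)
    p = np.zeros((ng, maxd))
    for g, d in entries:
        p[g - 1, d - 1] += 1
    return p


def oracle_ngtdm(binned, mask):
    ng = int(binned[mask].max())
    h, w = mask.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            i = binned[r, c]
            n_i[i - 1] += 1
            neigh = [
                binned[r + dr, c + dc]
                for dr, dc in NEIGH8
                if 0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
            ]
            if neigh:
                s_i[i - 1] += abs(i - sum(neigh) / len(neigh))
    return n_i, s_i


def _pad_to_match(a, b):
    rows = max(a.shape[0], b.shape[0])
    cols = max(a.shape[1], b.shape[1])
    out = []
    for m in (a, b):
        p = np.zeros((rows, cols))
        p[: m.shape[0], : m.shape[1]] = m
        out.append(p)
    return out


def random_roi(rng):
    h, w = rng.integers(4, 9), rng.integers(4, 9)
    binned = rng.integers(1, 5, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if mask.sum() < 4:
        mask[:2, :2] = True
    # relabel so levels start at 1 inside the mask
    binned = binned - binned[mask].min() + 1
    binned[~mask] = 0
    return binned.astype(np.int64), mask


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------


def test_glcm_two_by_two_hand_example():
    binned = np.array([[1, 1], [1, 2]])
    mask = np.ones((2, 2), bool)
    (p,) = rx.glcm_matrix(binned, mask, [(0, 1)], symmetric=True)
    assert p[0, 0] == pytest.approx(0.5)
    assert p[0, 1] == pytest.approx(0.25)
    assert p[1, 0] == pytest.approx(0.25)
    assert p[1, 1] == 0.0
    feats = rx.glcm_features_from_matrix(p)
    assert feats["JointEnergy"] == pytest.approx(0.375)


def test_glcm_uniform_image_single_entry():
    binned = np.ones((4, 4), dtype=np.int64)
    mask = np.ones((4, 4), bool)
    (p,) = rx.glcm_matrix(binned, mask, [(0, 1)], symmetric=True)
    assert p.shape == (1, 1) and p[0, 0] == 1.0
    assert rx.glcm_features_from_matrix(p)["JointEntropy"] == 0.0


def test_glrlm_single_row_hand_example():
    binned = np.array([[1, 1, 2, 2, 2]])
    mask = np.ones((1, 5), bool)
    (p,) = rx.glrlm_matrix(binned, mask, [(0, 1)])
    expected = np.zeros((2, 3))
    expected[0, 1] = 1  # one run of level 1, length 2
    expected[1, 2] = 1  # one run of level 2, length 3
    assert np.array_equal(p, expected)
    feats = rx.glrlm_features([p], 5)
    # run-length non-uniformity: (1^2 + 1^2) / 2 runs = 1
    assert feats["RunLengthNonUniformity"] == pytest.approx(1.0)


def test_glszm_uniform_image_single_zone():
    binned = np.ones((3, 3), dtype=np.int64)
    mask = np.ones((3, 3), bool)
    p = rx.glszm_matrix(binned, mask)
    assert p.shape == (1, 9)
    assert p[0, 8] == 1 and p.sum() == 1


def test_ngtdm_uniform_image_zero_differences():
    binned = np.full((4, 4), 2, dtype=np.int64)
    mask = np.ones((4, 4), bool)
    n_i, s_i = rx.ngtdm_table(binned, mask)
    assert n_i[1] == 16
    assert np.all(s_i == 0)


# ---------------------------------------------------------------------------
# oracle equivalence on random ROIs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("case", range(24))
def test_matrices_equal_brute_force_enumeration(case):
    rng = np.random.default_rng(5000 + case)
    binned, mask = random_roi(rng)

    for off in OFFSETS:
        got = rx.glcm_matrix(binned, mask, [off], symmetric=True)[0]
        want = oracle_glcm(binned, mask, off, symmetric=True)
        assert np.array_equal(*_pad_to_match(got, want)), f"glcm {off}"

        got = rx.glrlm_matrix(binned, mask, [off])[0]
        want = oracle_glrlm(binned, mask, off)
        assert np.array_equal(*_pad_to_match(got, want)), f"glrlm {off}"

    assert np.array_equal(
        *_pad_to_match(rx.glszm_matrix(binned, mask), oracle_glszm(binned, mask))
    )
    assert np.array_equal(
        *_pad_to_match(rx.gldm_matrix(binned, mask), oracle_gldm(binned, mask))
    )
    n_got, s_got = rx.ngtdm_table(binned, mask)
    n_want, s_want = oracle_ngtdm(binned, mask)
    assert np.array_equal(n_got, n_want)
    assert np.allclose(s_got, s_want, rtol=0, atol=1e-12)


def test_direction_averaged_features_rotation_invariant(rng):
    binned = rng.integers(1, 6, size=(9, 9)).astype(np.int64)
    mask = np.ones((9, 9), bool)
    params = rx.ExtractionParams()
    a = rx._texture_features(binned, mask, params)
    b = rx._texture_features(np.rot90(binned).copy(), np.rot90(mask).copy(), params)
    for cls in a:
        for k in a[cls]:
            assert a[cls][k] == pytest.approx(b[cls][k], rel=1e-9), (cls, k)
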