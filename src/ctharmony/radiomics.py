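"""Radiomics feature extraction: 91-feature core on the original image and
four stationary-wavelet subbands, giving 455 features in 30 groups.

Feature definitions follow the Image Biomarker Standardisation Initiative
(IBSI) reference set, restricted to 2D single-slice ROIs.  The class
rosters are frozen here as the single source of truth:

==========  =====  ===============================================
class       count  note
==========  =====  ===============================================
firstorder   18    intensity statistics on raw HU (entropy and
                   uniformity use the discretized values)
glcm         22    grey-level co-occurrence, 4 in-plane offsets,
                   symmetric, features averaged over offsets
glrlm        16    run lengths, 4 directions averaged
glszm        16    size zones, 8-connectivity
gldm         14    dependence counts over the 8-neighbourhood
ngtdm         5    neighbouring grey-tone difference
==========  =====  ===============================================

Feature ids are ``{imagetype}_{class}_{FeatureName}``, with image types
``original, wavelet-LL, wavelet-LH, wavelet-HL, wavelet-HH``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .phantom import ProtocolStack, ROISet

IMAGE_TYPES = ["original", "wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH"]

FIRSTORDER_FEATURES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10", "Percentile90",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
]

GLCM_FEATURES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
]

GLRLM_FEATURES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_FEATURES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

GLDM_FEATURES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
]

NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

MATRIX_CLASSES: Dict[str, List[str]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

# 4 in-plane offsets: 0, 45, 90, 135 degrees, (row, col) convention
DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EPS = np.spacing(1.0)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SchemaEntry:
    image_type: str
    matrix_class: str
    feature_name: str

    @property
    def group(self) -> str:
        return f"{self.image_type}_{self.matrix_class}"

    @property
    def feature_id(self) -> str:
        return f"{self.image_type}_{self.matrix_class}_{self.feature_name}"


@dataclass(frozen=True)
class FeatureSchema:
    entries: Tuple[SchemaEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> List[str]:
        return [e.feature_id for e in self.entries]

    @property
    def groups(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group, None)
        return list(seen)

    def group_members(self, group: str) -> List[str]:
        return [e.feature_id for e in self.entries if e.group == group]

    def to_json_dict(self) -> dict:
        return {
            "image_types": IMAGE_TYPES,
            "classes": {k: list(v) for k, v in MATRIX_CLASSES.items()},
            "feature_ids": self.feature_ids,
        }


def build_schema() -> FeatureSchema:
    """The fixed 455-entry feature schema (91 core features x 5 image types)."""
    entries = [
        SchemaEntry(itype, mclass, name)
        for itype in IMAGE_TYPES
        for mclass, names in MATRIX_CLASSES.items()
        for name in names
    ]
    return FeatureSchema(tuple(entries))


# Schema arithmetic is structural; fail loudly at import if the rosters drift.
_core = sum(len(v) for v in MATRIX_CLASSES.values())
assert _core == 91, _core
assert len(build_schema()) == 455
assert len(build_schema().groups) == 30


@dataclass(frozen=True)
class ExtractionParams:
    bin_width_hu: float = 25.0
    offsets: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric_glcm: bool = True
    wavelet_name: str = "coif1"
    min_roi_pixels: int = 9

    def __post_init__(self) -> None:
        if self.bin_width_hu <= 0:
            raise ParameterError("bin_width_hu must be positive")
        if self.min_roi_pixels < 9:
            raise ParameterError("min_roi_pixels must be >= 9")


# ---------------------------------------------------------------------------
# discretization and wavelet decomposition
# ---------------------------------------------------------------------------


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization: ``floor(x/w) - floor(min/w) + 1``.

    Labels start at 1; the number of grey levels is the maximum label.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be nonempty and finite")
    return (np.floor(v / bin_width) - math.floor(v.min() / bin_width) + 1).astype(np.int64)


def wavelet_subbands(image: np.ndarray, wavelet: str = "coif1") -> Dict[str, np.ndarray]:
    """Single-level stationary (undecimated) 2D wavelet decomposition.

    Returns LL/LH/HL/HH subbands, each the same shape as the input so ROI
    masks apply unchanged.  Odd dimensions are symmetrically padded on the
    trailing edge to the next even size and cropped back afterwards.

    Naming uses the (row-filter, column-filter) convention: ``LH`` is
    low-pass along rows and high-pass along columns, so it responds to
    intensity changes across columns (vertical edges), and ``HL`` to
    changes across rows.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    h, w = img.shape
    ph_, pw = h % 2, w % 2
    if ph_ or pw:
        img = np.pad(img, ((0, ph_), (0, pw)), mode="symmetric")
    (ll, (lh, hl, hh)), = pywt.swt2(img, wavelet, level=1, norm=False)
    # pywt's cH is high-pass along rows; relabel to (row, col) filter order
    out = {"LL": ll, "LH": hl, "HL": lh, "HH": hh}
    return {k: v[:h, :w] for k, v in out.items()}


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------


def glcm_matrix(
    binned: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> List[np.ndarray]:
    """Normalized co-occurrence matrix per offset.

    Counts in-mask neighbour pairs; if symmetric, the transpose is added
    before normalizing each offset's matrix to sum 1.  Offsets with no
    valid pair yield a None-free empty matrix and are skipped by callers.
    """
    if not offsets:
        raise ParameterError("offsets must be nonempty")
    ng = int(binned[mask].max())
    mats = []
    for dr, dc in offsets:
        p = np.zeros((ng, ng), dtype=np.float64)
        rows, cols = np.nonzero(mask)
        nr, nc = rows + dr, cols + dc
        ok = (nr >= 0) & (nr < mask.shape[0]) & (nc >= 0) & (nc < mask.shape[1])
        ok[ok] &= mask[nr[ok], nc[ok]]
        a = binned[rows[ok], cols[ok]] - 1
        b = binned[nr[ok], nc[ok]] - 1
        np.add.at(p, (a, b), 1.0)
        if symmetric:
            p = p + p.T
        total = p.sum()
        if total > 0:
            p /= total
        mats.append(p)
    return mats


def glrlm_matrix(
    binned: np.ndarray,
    mask: np.ndarray,
    directions: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
) -> List[np.ndarray]:
    """Run-length matrix per direction; out-of-mask pixels break runs."""
    ng = int(binned[mask].max())
    h, w = mask.shape
    maxlen = max(h, w)
    out = []
    for dr, dc in directions:
        counts = np.zeros((ng, maxlen), dtype=np.float64)
        seen = np.zeros_like(mask, dtype=bool)
        for r0 in range(h):
            for c0 in range(w):
                # start of a line in direction (dr, dc)
                pr, pc = r0 - dr, c0 - dc
                if 0 <= pr < h and 0 <= pc < w:
                    continue
                r, c = r0, c0
                run_val, run_len = None, 0
                while 0 <= r < h and 0 <= c < w:
                    if mask[r, c]:
                        v = binned[r, c]
                        if v == run_val:
                            run_len += 1
                        else:
                            if run_val is not None:
                                counts[run_val - 1, run_len - 1] += 1
                            run_val, run_len = v, 1
                    else:
                        if run_val is not None:
                            counts[run_val - 1, run_len - 1] += 1
                        run_val, run_len = None, 0
                    r += dr
                    c += dc
                if run_val is not None:
                    counts[run_val - 1, run_len - 1] += 1
        # trim trailing all-zero run-length columns
        nz = np.nonzero(counts.sum(axis=0))[0]
        counts = counts[:, : nz.max() + 1] if nz.size else counts[:, :1]
        out.append(counts)
    return out


def glszm_matrix(binned: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size-zone matrix: 8-connected zones of equal grey level inside the mask."""
    ng = int(binned[mask].max())
    structure = np.ones((3, 3), dtype=int)
    sizes: List[Tuple[int, int]] = []
    for level in range(1, ng + 1):
        lab, n = ndimage.label((binned == level) & mask, structure=structure)
        if n:
            zs = np.bincount(lab.ravel())[1:]
            sizes.extend((level, int(s)) for s in zs)
    max_s = max(s for _, s in sizes)
    p = np.zeros((ng, max_s), dtype=np.float64)
    for level, s in sizes:
        p[level - 1, s - 1] += 1
    return p


_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def gldm_matrix(binned: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence matrix over the 8-neighbourhood.

    The dependence size of a pixel is 1 (the centre) plus the number of
    in-mask neighbours whose grey level differs from the centre by at most
    ``alpha``.
    """
    ng = int(binned[mask].max())
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    dep = np.ones(rows.size, dtype=np.int64)
    for dr, dc in _NEIGH8:
        nr, nc = rows + dr, cols + dc
        ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        ok[ok] &= mask[nr[ok], nc[ok]]
        diff = np.abs(binned[rows[ok], cols[ok]] - binned[nr[ok], nc[ok]])
        dep[ok] += (diff <= alpha).astype(np.int64)
    p = np.zeros((ng, int(dep.max())), dtype=np.float64)
    np.add.at(p, (binned[rows, cols] - 1, dep - 1), 1.0)
    return p


def ngtdm_table(binned: np.ndarray, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Counts n_i and summed absolute differences s_i per grey level.

    s_i sums |i - mean(in-mask 8-neighbours)| over in-mask pixels of level
    i that have at least one in-mask neighbour.
    """
    ng = int(binned[mask].max())
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    nsum = np.zeros(rows.size)
    ncnt = np.zeros(rows.size)
    for dr, dc in _NEIGH8:
        nr, nc = rows + dr, cols + dc
        ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        ok[ok] &= mask[nr[ok], nc[ok]]
        nsum[ok] += binned[nr[ok], nc[ok]]
        ncnt[ok] += 1
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = binned[rows, cols]
    for idx in range(rows.size):
        i = lv[idx]
        n_i[i - 1] += 1
        if ncnt[idx] > 0:
            s_i[i - 1] += abs(i - nsum[idx] / ncnt[idx])
    return n_i, s_i


# ---------------------------------------------------------------------------
# feature computations
# ---------------------------------------------------------------------------


def firstorder_features(
    values: np.ndarray, binned: np.ndarray, pixel_area_mm2: float
) -> Dict[str, float]:
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    mean = x.mean()
    var = x.var()
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    m3 = np.mean((x - mean) ** 3)
    m4 = np.mean((x - mean) ** 4)
    counts = np.bincount(binned)[1:]
    p = counts[counts > 0] / n
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(pixel_area_mm2 * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


def glcm_features_from_matrix(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(ii * p))
    muy = float(np.sum(jj * p))
    sigx = math.sqrt(max(float(np.sum((ii - mux) ** 2 * p)), 0.0))
    sigy = math.sqrt(max(float(np.sum((jj - muy) ** 2 * p)), 0.0))
    # diagonal / cross-diagonal distributions
    k_diff = np.arange(0, ng)  # |i-j|
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    da = float(np.sum(k_diff * p_diff))

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q))) if q.size else 0.0

    hx, hy = ent(px), ent(py)
    hxy = ent(p.ravel())
    pxy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-np.sum(p[nz] * np.log2(pxy[nz] + _EPS)))
    nz2 = pxy > 0
    hxy2 = float(-np.sum(pxy[nz2] * np.log2(pxy[nz2])))
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    if sigx > 0 and sigy > 0:
        corr = (float(np.sum(ii * jj * p)) - mux * muy) / (sigx * sigy)
    else:
        corr = 1.0
    off = ii != jj
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mux,
        "ClusterProminence": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(np.sum((ii - mux) ** 2 * p)),
    }


def _rl_style_features(
    p: np.ndarray, n_pixels: int, names: Dict[str, str]
) -> Dict[str, float]:
    """Shared grey-level x size feature family (GLRLM / GLSZM / GLDM).

    ``names`` maps the generic feature key (e.g. 'SE' short emphasis) to the
    class-specific feature name.
    """
    ng, ns = p.shape
    nz = p.sum()
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ns + 1)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    pn = p / nz
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))
    ent_p = pn[pn > 0]
    out = {
        "SE": float(np.sum(ps / np.arange(1, ns + 1) ** 2) / nz),
        "LE": float(np.sum(ps * np.arange(1, ns + 1) ** 2) / nz),
        "GLN": float(np.sum(pg**2) / nz),
        "GLNN": float(np.sum(pg**2) / nz**2),
        "SN": float(np.sum(ps**2) / nz),
        "SNN": float(np.sum(ps**2) / nz**2),
        "PCT": float(nz / n_pixels),
        "GLV": float(np.sum(pn * (i - mu_i) ** 2)),
        "SV": float(np.sum(pn * (j - mu_j) ** 2)),
        "ENT": float(-np.sum(ent_p * np.log2(ent_p))),
        "LGLE": float(np.sum(pg / np.arange(1, ng + 1) ** 2) / nz),
        "HGLE": float(np.sum(pg * np.arange(1, ng + 1) ** 2) / nz),
        "SLGLE": float(np.sum(p / (i**2 * j**2)) / nz),
        "SHGLE": float(np.sum(p * i**2 / j**2) / nz),
        "LLGLE": float(np.sum(p * j**2 / i**2) / nz),
        "LHGLE": float(np.sum(p * i**2 * j**2) / nz),
    }
    return {v: out[k] for k, v in names.items()}


_GLRLM_KEYMAP = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "RunLengthNonUniformity", "SNN": "RunLengthNonUniformityNormalized",
    "PCT": "RunPercentage", "GLV": "GrayLevelVariance", "SV": "RunVariance",
    "ENT": "RunEntropy", "LGLE": "LowGrayLevelRunEmphasis",
    "HGLE": "HighGrayLevelRunEmphasis", "SLGLE": "ShortRunLowGrayLevelEmphasis",
    "SHGLE": "ShortRunHighGrayLevelEmphasis", "LLGLE": "LongRunLowGrayLevelEmphasis",
    "LHGLE": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_KEYMAP = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "SizeZoneNonUniformity", "SNN": "SizeZoneNonUniformityNormalized",
    "PCT": "ZonePercentage", "GLV": "GrayLevelVariance", "SV": "ZoneVariance",
    "ENT": "ZoneEntropy", "LGLE": "LowGrayLevelZoneEmphasis",
    "HGLE": "HighGrayLevelZoneEmphasis", "SLGLE": "SmallAreaLowGrayLevelEmphasis",
    "SHGLE": "SmallAreaHighGrayLevelEmphasis", "LLGLE": "LargeAreaLowGrayLevelEmphasis",
    "LHGLE": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_KEYMAP = {
    "SE": "SmallDependenceEmphasis", "LE": "LargeDependenceEmphasis",
    "GLN": "GrayLevelNonUniformity", "SN": "DependenceNonUniformity",
    "SNN": "DependenceNonUniformityNormalized", "GLV": "GrayLevelVariance",
    "SV": "DependenceVariance", "ENT": "DependenceEntropy",
    "LGLE": "LowGrayLevelEmphasis", "HGLE": "HighGrayLevelEmphasis",
    "SLGLE": "SmallDependenceLowGrayLevelEmphasis",
    "SHGLE": "SmallDependenceHighGrayLevelEmphasis",
    "LLGLE": "LargeDependenceLowGrayLevelEmphasis",
    "LHGLE": "LargeDependenceHighGrayLevelEmphasis",
}


def glrlm_features(mats: List[np.ndarray], n_pixels: int) -> Dict[str, float]:
    per = [_rl_style_features(m, n_pixels, _GLRLM_KEYMAP) for m in mats if m.sum() > 0]
    return {k: float(np.mean([d[k] for d in per])) for k in GLRLM_FEATURES}


def glszm_features(p: np.ndarray, n_pixels: int) -> Dict[str, float]:
    return _rl_style_features(p, n_pixels, _GLSZM_KEYMAP)


def gldm_features(p: np.ndarray, n_pixels: int) -> Dict[str, float]:
    return _rl_style_features(p, n_pixels, _GLDM_KEYMAP)


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> Dict[str, float]:
    n = n_i.sum()
    p_i = n_i / n
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_i.size + 1, dtype=np.float64)
    coarseness_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarseness_den if coarseness_den > 0 else 1e6
    if ngp > 1:
        pi_, ii_ = p_i[present], i[present]
        dif2 = (ii_[:, None] - ii_[None, :]) ** 2
        contrast = float(
            np.sum(pi_[:, None] * pi_[None, :] * dif2) / (ngp * (ngp - 1))
        ) * float(s_i.sum() / n)
        busy_den = float(np.sum(np.abs((ii_ * pi_)[:, None] - (ii_ * pi_)[None, :])))
        busyness = coarseness_den / busy_den if busy_den > 0 else 0.0
        psum = pi_[:, None] + pi_[None, :]
        pspart = (pi_ * s_i[present])[:, None] + (pi_ * s_i[present])[None, :]
        complexity = float(np.sum(np.abs(ii_[:, None] - ii_[None, :]) * pspart / psum)) / n
        s_total = float(s_i.sum())
        strength = (
            float(np.sum(psum * dif2)) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------------


def _texture_features(
    binned: np.ndarray, mask: np.ndarray, params: ExtractionParams
) -> Dict[str, Dict[str, float]]:
    n_px = int(mask.sum())
    glcms = glcm_matrix(binned, mask, params.offsets, params.symmetric_glcm)
    valid = [m for m in glcms if m.sum() > 0]
    if not valid:
        raise ValueError("no valid neighbour pair for GLCM")
    per_off = [glcm_features_from_matrix(m) for m in valid]
    glcm_f = {k: float(np.mean([d[k] for d in per_off])) for k in GLCM_FEATURES}
    return {
        "glcm": glcm_f,
        "glrlm": glrlm_features(glrlm_matrix(binned, mask, params.offsets), n_px),
        "glszm": glszm_features(glszm_matrix(binned, mask), n_px),
        "gldm": gldm_features(gldm_matrix(binned, mask), n_px),
        "ngtdm": ngtdm_features(*ngtdm_table(binned, mask)),
    }


def compute_core_features(
    values: np.ndarray,
    binned_image: np.ndarray,
    mask: np.ndarray,
    params: ExtractionParams,
    pixel_area_mm2: float,
) -> Dict[str, Dict[str, float]]:
    """All 91 core features of one image type for one ROI."""
    out = _texture_features(binned_image, mask, params)
    out["firstorder"] = firstorder_features(values, binned_image[mask], pixel_area_mm2)
    return out


def extract_features(
    stack: ProtocolStack,
    rois: ROISet,
    schema: Optional[FeatureSchema] = None,
    params: Optional[ExtractionParams] = None,
) -> pd.DataFrame:
    """Extract the full 455-feature schema from every (ROI, protocol) pair.

    Returns a long-format table with columns
    ``subject, roi, protocol, feature, value`` (NaN value plus a ``reason``
    for ROIs below the minimum pixel count or with degenerate texture).
    """
    schema = schema or build_schema()
    params = params or ExtractionParams()
    area = rois.pixel_spacing_mm**2
    rows: List[tuple] = []
    for label, image in stack.images.items():
        subbands = wavelet_subbands(image, params.wavelet_name)
        typed_images = {"original": image, **{f"wavelet-{k}": v for k, v in subbands.items()}}
        for roi in rois:
            mask = roi.mask(image.shape, rois.pixel_spacing_mm)
            reason = None
            if int(mask.sum()) < params.min_roi_pixels:
                reason = f"ROI below minimum pixel count ({int(mask.sum())} < {params.min_roi_pixels})"
            values_by_type: Dict[str, Dict[str, Dict[str, float]]] = {}
            if reason is None:
                # crop to the ROI bounding box: out-of-mask pixels break
                # pairs/runs/zones, so the crop changes nothing but cost
                rr, cc = np.nonzero(mask)
                sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
                cmask = mask[sl]
                try:
                    for itype, timg in typed_images.items():
                        crop = timg[sl]
                        binned = np.zeros(crop.shape, dtype=np.int64)
                        binned[cmask] = discretize(crop[cmask], params.bin_width_hu)
                        values_by_type[itype] = compute_core_features(
                            crop[cmask], binned, cmask, params, area
                        )
                except ValueError as exc:
                    reason = str(exc)
            for entry in schema.entries:
                if reason is None:
                    val = values_by_type[entry.image_type][entry.matrix_class][
                        entry.feature_name
                    ]
                else:
                    val = np.nan
                rows.append(
                    (stack.subject_id, roi.roi_id, label, entry.feature_id, val, reason)
                )
    df = pd.DataFrame(
        rows, columns=["subject", "roi", "protocol", "feature", "value", "reason"]
    )
    df.attrs["bin_width_hu"] = params.bin_width_hu
    df.attrs["wavelet"] = params.wavelet_name
    return df


def extract_cohort_features(
    cohort: Iterable[Tuple[ProtocolStack, ROISet]],
    schema: Optional[FeatureSchema] = None,
    params: Optional[ExtractionParams] = None,
) -> pd.DataFrame:
    """Concatenate per-subject feature tables for a cohort."""
    parts = [extract_features(s, r, schema, params) for s, r in cohort]
    return pd.concat(parts, ignore_index=True)


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to (subject, roi, protocol) rows x feature columns."""
    return table.pivot_table(
        index=["subject", "roi", "protocol"], columns="feature", values="value",
        aggfunc="first", observed=True,
    )
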