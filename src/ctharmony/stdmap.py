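"""Per-pixel standard-deviation maps over pairwise protocol differences.

Because all reconstructions of one DECT acquisition are voxel-aligned, the
per-pixel spread of the C(k,2) pairwise difference images visualizes where
protocols disagree; harmonization should lower the map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .phantom import ProtocolStack

DEFAULT_WINDOW_WIDTH = 300.0
DEFAULT_WINDOW_LEVEL = 40.0


@dataclass
class StdMapResult:
    pairs: List[Tuple[str, str]]
    std_image: np.ndarray
    window: Tuple[float, float] = (DEFAULT_WINDOW_WIDTH, DEFAULT_WINDOW_LEVEL)


def pairwise_differences(stack: ProtocolStack) -> Dict[Tuple[str, str], np.ndarray]:
    """Signed difference image per unordered protocol pair, lexicographic order.

    Four protocols give the six combinations; each entry is image_i - image_j
    with i < j lexicographically.
    """
    labels = sorted(stack.images)
    if len(labels) < 2:
        raise ValueError("need at least 2 protocols")
    shapes = {stack.images[l].shape for l in labels}
    if len(shapes) > 1:
        raise ValueError(f"misaligned stack: shapes {shapes}")
    return {
        (a, b): stack.images[a] - stack.images[b]
        for a, b in itertools.combinations(labels, 2)
    }


def std_map(stack: ProtocolStack, population: bool = True) -> StdMapResult:
    """Per-pixel standard deviation over all pairwise protocol differences.

    The population convention (divide by the number of pairs) is the
    default: the pairs are a complete enumeration, not a sample.
    """
    diffs = pairwise_differences(stack)
    if len(diffs) < 3:
        warnings.warn(
            "fewer than 3 protocol pairs: std map is degenerate", stacklevel=2
        )
    arr = np.stack(list(diffs.values()))
    ddof = 0 if population else 1
    if not population and arr.shape[0] < 2:
        raise ValueError("sample std needs at least 2 pairs")
    return StdMapResult(pairs=list(diffs), std_image=arr.std(axis=0, ddof=ddof))


def render_display(
    image: np.ndarray,
    window_width: float = DEFAULT_WINDOW_WIDTH,
    window_level: float = DEFAULT_WINDOW_LEVEL,
) -> np.ndarray:
    """Linear HU-to-grey windowing to an 8-bit display image.

    Values at or below level - width/2 map to 0, at or above level + width/2
    to 255; the level itself maps to mid-grey.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    lo = window_level - window_width / 2.0
    frac = np.clip((np.asarray(image, dtype=np.float64) - lo) / window_width, 0.0, 1.0)
    return np.round(frac * 255.0).astype(np.uint8)
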