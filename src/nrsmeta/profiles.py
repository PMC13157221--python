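"""Local similarity profiles, smoothing, segmentation and SVG rendering.

A profile maps each position i of a target to the similarity
s_i = clamp(1 - bits_i / 2, 0, 1), where bits_i is the per-position code
length under a reference-trained bundle: positions the reference explains
well approach 1, unexplained positions approach 0.  Profiles are smoothed
with a centered moving average and segmented into maximal runs of high
similarity; both plots (profile lines, matrix heat maps) are rendered as
deterministic SVG text so outputs can be compared byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compressor import ModelBundle, relative_code_length
from .seqio import SequenceRecord, format_float

__all__ = [
    "SimilarityProfile",
    "Segment",
    "local_profile",
    "smooth_profile",
    "segment_profile",
    "render_profile_svg",
    "render_heatmap_svg",
]

DEFAULT_SMOOTH_WINDOW = 21
DEFAULT_SEGMENT_THRESHOLD = 0.5
DEFAULT_SEGMENT_MIN_LENGTH = 10


@dataclass
class SimilarityProfile:
    target_id: str
    values: np.ndarray      # raw per-position similarity in [0, 1]
    smoothed: np.ndarray    # same length, after the moving average

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.smoothed = np.asarray(self.smoothed, dtype=np.float64)
        if self.values.shape != self.smoothed.shape:
            raise ValueError("values and smoothed must have the same length")


@dataclass(frozen=True)
class Segment:
    """Half-open [start, end) run of high similarity along a target."""

    target_id: str
    start: int
    end: int
    mean_similarity: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")


def local_profile(
    target: SequenceRecord,
    bundle: ModelBundle,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> SimilarityProfile:
    """Per-position similarity of the target under the bundle."""
    res = relative_code_length(target, bundle, keep_profile=True)
    values = np.clip(1.0 - res.per_symbol_bits / 2.0, 0.0, 1.0)
    return SimilarityProfile(target.id, values, smooth_profile(values, smooth_window))


def smooth_profile(values: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with edge truncation.

    Near the boundaries the effective window shrinks to the available
    positions, so the smoothed values stay within [min, max] of the raw
    ones.  ``window`` must be odd; window = 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    values = np.asarray(values, dtype=np.float64)
    if window == 1 or values.size == 0:
        return values.copy()
    n = values.size
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (cum[hi] - cum[lo]) / (hi - lo)


def segment_profile(
    smoothed: np.ndarray,
    threshold: float = DEFAULT_SEGMENT_THRESHOLD,
    min_length: int = DEFAULT_SEGMENT_MIN_LENGTH,
    target_id: str = "",
) -> list[Segment]:
    """Maximal runs of positions with smoothed value >= threshold.

    Runs shorter than ``min_length`` are discarded; coordinates are 0-based
    half-open.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    smoothed = np.asarray(smoothed, dtype=np.float64)
    segments: list[Segment] = []
    start = None
    for i, v in enumerate(smoothed):
        if v >= threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_length:
                segments.append(
                    Segment(target_id, start, i, float(np.mean(smoothed[start:i])))
                )
            start = None
    if start is not None and smoothed.size - start >= min_length:
        segments.append(
            Segment(target_id, start, int(smoothed.size),
                    float(np.mean(smoothed[start:])))
        )
    return segments


# --- SVG rendering ---------------------------------------------------------
# All coordinates are written with the fixed 6-decimal format; identical
# inputs therefore produce byte-identical files.

_SVG_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<!-- deterministic SVG: fixed canvas, 6-decimal coordinates, linear\n'
    '     colormap white (value 0) to #08519c (value 1) -->\n'
)


def _f(x: float) -> str:
    return format_float(x)


def render_profile_svg(
    profile: SimilarityProfile,
    segments: Sequence[Segment],
    path: str,
    width: float = 1000.0,
    height: float = 220.0,
) -> None:
    """Similarity profile as an SVG line plot with segment overlays."""
    n = profile.values.size
    margin = 10.0
    plot_w = width - 2 * margin
    plot_h = height - 2 * margin
    step = plot_w / max(1, n - 1)

    def xy(i: int, v: float) -> str:
        return f"{_f(margin + i * step)},{_f(margin + plot_h * (1.0 - v))}"

    parts = [_SVG_HEADER]
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">\n'
    )
    parts.append(
        f'<rect x="0" y="0" width="{_f(width)}" height="{_f(height)}" fill="#ffffff"/>\n'
    )
    for seg in segments:
        x0 = margin + seg.start * step
        x1 = margin + (seg.end - 1) * step
        parts.append(
            f'<rect class="segment" x="{_f(x0)}" y="{_f(margin)}" '
            f'width="{_f(max(x1 - x0, step))}" height="{_f(plot_h)}" '
            f'fill="#fdd0a2" fill-opacity="0.6"/>\n'
        )
    if n:
        raw_pts = " ".join(xy(i, float(v)) for i, v in enumerate(profile.values))
        sm_pts = " ".join(xy(i, float(v)) for i, v in enumerate(profile.smoothed))
        parts.append(
            f'<polyline class="raw" points="{raw_pts}" fill="none" '
            f'stroke="#bdbdbd" stroke-width="0.5"/>\n'
        )
        parts.append(
            f'<polyline class="smoothed" points="{sm_pts}" fill="none" '
            f'stroke="#08519c" stroke-width="1.5"/>\n'
        )
    parts.append("</svg>\n")
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("".join(parts))


def _heat_color(value: float) -> str:
    """Linear white -> #08519c colormap, clamped to [0, 1]."""
    v = max(0.0, min(1.0, value))
    r = round(255 + (0x08 - 255) * v)
    g = round(255 + (0x51 - 255) * v)
    b = round(255 + (0x9C - 255) * v)
    return f"#{r:02x}{g:02x}{b:02x}"


def render_heatmap_svg(
    matrix: np.ndarray,
    labels: Sequence[str],
    path: str,
    cell: float = 40.0,
) -> None:
    """Square similarity matrix as an SVG heat map (one rect per cell)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with one label per row")
    margin = 110.0
    width = margin + n * cell + 10.0
    height = margin + n * cell + 10.0
    parts = [_SVG_HEADER]
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">\n'
    )
    parts.append(
        f'<rect x="0" y="0" width="{_f(width)}" height="{_f(height)}" fill="#ffffff"/>\n'
    )
    for i in range(n):
        for j in range(n):
            x = margin + j * cell
            y = margin + i * cell
            parts.append(
                f'<rect class="cell" x="{_f(x)}" y="{_f(y)}" width="{_f(cell)}" '
                f'height="{_f(cell)}" fill="{_heat_color(float(matrix[i, j]))}">'
                f"<title>{labels[i]} vs {labels[j]}: "
                f"{format_float(float(matrix[i, j]))}</title></rect>\n"
            )
    for i, label in enumerate(labels):
        y = margin + (i + 0.5) * cell
        parts.append(
            f'<text x="{_f(margin - 6.0)}" y="{_f(y)}" text-anchor="end" '
            f'dominant-baseline="middle" font-size="11">{label}</text>\n'
        )
        x = margin + (i + 0.5) * cell
        parts.append(
            f'<text x="{_f(x)}" y="{_f(margin - 6.0)}" text-anchor="start" '
            f'font-size="11" transform="rotate(-60 {_f(x)} {_f(margin - 6.0)})">'
            f"{label}</text>\n"
        )
    parts.append("</svg>\n")
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("".join(parts))
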