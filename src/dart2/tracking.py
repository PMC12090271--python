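"""Per-frame tracking statistics for two-choice tube assays.

The assay records a glass tube, odorant cap at one end and solvent cap at
the other, as a grayscale image stack.  Flies are segmented from the
background by a brightness threshold, and two per-frame summary statistics
are computed from the resulting pixel mask:

* the **normalized center of mass** (CoM) of all above-threshold pixels
  along the tube axis, 0 at the odorant end and 1 at the opposite
  (solvent) end, so 0.5 indicates indifference and values above 0.5
  indicate aversion;
* the **avoidance index** (AI), the signed difference between pixel
  counts in the odorant and solvent halves of the tube divided by the
  total count.

Normalization note: with 0-based column offsets ``x`` from the odorant
end the CoM is computed as ``sum(x) / (M * (L - 1))`` where ``M`` is the
number of flagged pixels and ``L`` the tube span in pixels.  The
``L - 1`` denominator makes the canonical anchors exact: all mass in the
farthest column gives 1.0, all mass at the odorant end gives 0.0, and a
homogeneous occupancy of every column gives exactly 0.5.  A denominator
of ``L`` would differ by O(1/L) and could not attain those anchors.

The AI counts above-threshold pixels as a proxy for fly counts; with an
odd tube width the single middle column belongs to neither half (it still
counts in the denominator).  As printed, the index is +1 when all mass
sits in the odorant half, so *aversion is negative*; pass
``aversion_positive=True`` to flip the sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TubeGeometry:
    """Location and orientation of the tube within the frame.

    Parameters
    ----------
    c0, c1:
        Inclusive column-index range of the tube span within the frame.
    odorant_end:
        ``"low"`` if the odorant cap sits at column ``c0``, ``"high"`` if
        it sits at column ``c1``.  All lengthwise coordinates are
        measured from the odorant end regardless of image orientation.
    """

    c0: int
    c1: int
    odorant_end: Literal["low", "high"] = "low"

    def __post_init__(self) -> None:
        if not (isinstance(self.c0, (int, np.integer)) and isinstance(self.c1, (int, np.integer))):
            raise TypeError("tube span must be given as integer column indices")
        if self.c1 <= self.c0:
            raise ValueError(f"need c1 > c0, got c0={self.c0}, c1={self.c1}")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.odorant_end not in ("low", "high"):
            raise ValueError(f"odorant_end must be 'low' or 'high', got {self.odorant_end!r}")

    @property
    def length_px(self) -> int:
        """Tube span L in pixels (inclusive column count)."""
        return self.c1 - self.c0 + 1

    def flipped(self) -> "TubeGeometry":
        """Same span with the odorant end on the other side."""
        other = "high" if self.odorant_end == "low" else "low"
        return TubeGeometry(self.c0, self.c1, other)


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize a frame.

    ``fixed`` mode applies a preset brightness level (the default
    behavior; the level comes from the run configuration).  ``otsu`` mode
    derives the level from the tube region of each frame and is offered
    as a convenience only.  ``polarity`` states whether flies are
    brighter or darker than the background; pixels strictly beyond the
    level on the fly side are flagged.
    """

    mode: Literal["fixed", "otsu"] = "fixed"
    level: Optional[float] = None
    polarity: Literal["bright_flies", "dark_flies"] = "bright_flies"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "otsu"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed":
            if self.level is None or not math.isfinite(float(self.level)):
                raise ValueError("fixed threshold mode requires a finite level")
        if self.polarity not in ("bright_flies", "dark_flies"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class PixelMask:
    """Boolean above-threshold mask bound to its tube geometry.

    ``flags`` has the shape of the source frame; pixels outside the tube
    span are never flagged.  ``offsets`` are the 0-based lengthwise
    coordinates of flagged pixels measured from the odorant end.
    """

    flags: np.ndarray
    geometry: TubeGeometry

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 2:
            raise ValueError("mask flags must be a 2-D grid")
        object.__setattr__(self, "flags", flags)

    @property
    def count(self) -> int:
        """M, the total number of flagged pixels."""
        return int(self.flags.sum())

    @property
    def offsets(self) -> np.ndarray:
        """x_n per flagged pixel: column offset from the odorant end."""
        cols = np.nonzero(self.flags)[1]
        g = self.geometry
        if g.odorant_end == "low":
            off = cols - g.c0
        else:
            off = g.c1 - cols
        return off.astype(np.int64)


def threshold_frame(frame: np.ndarray, spec: ThresholdSpec, geometry: TubeGeometry) -> PixelMask:
    """Binarize one frame into a :class:`PixelMask`.

    Pixels outside ``geometry``'s column span are never flagged.  The
    comparison direction follows ``spec.polarity``: with ``bright_flies``
    a pixel is flagged when its intensity is strictly above the level.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")
    if frame.shape[1] < 2:
        raise ValueError("frame must have at least 2 columns")
    if not np.all(np.isfinite(frame.astype(np.float64))):
        raise ValueError("frame intensities must be finite")
    if geometry.c1 >= frame.shape[1]:
        raise ValueError(
            f"tube span [{geometry.c0}, {geometry.c1}] exceeds frame width {frame.shape[1]}"
        )
    tube = frame[:, geometry.c0 : geometry.c1 + 1]
    if spec.mode == "fixed":
        level = float(spec.level)  # type: ignore[arg-type]
    else:
        from skimage.filters import threshold_otsu

        level = float(threshold_otsu(tube))
    if spec.polarity == "bright_flies":
        inside = tube > level
    else:
        inside = tube < level
    flags = np.zeros(frame.shape, dtype=bool)
    flags[:, geometry.c0 : geometry.c1 + 1] = inside
    return PixelMask(flags=flags, geometry=geometry)


def compute_com(mask: PixelMask, geometry: Optional[TubeGeometry] = None) -> float:
    """Normalized center of mass of the flagged pixels.

    Returns ``sum(x_n) / (M * (L - 1))`` with ``x_n`` the 0-based column
    offsets from the odorant end; 0 means all mass at the odorant end, 1
    all mass at the opposite end, and values above 0.5 indicate aversion.
    An empty mask (M = 0) yields NaN — a missing value, never silently 0.
    """
    g = geometry if geometry is not None else mask.geometry
    if geometry is not None and geometry != mask.geometry:
        mask = PixelMask(mask.flags, geometry)
    m = mask.count
    if m == 0:
        return math.nan
    L = g.length_px
    return float(mask.offsets.sum() / (m * (L - 1)))


def compute_ai(
    mask: PixelMask,
    geometry: Optional[TubeGeometry] = None,
    aversion_positive: bool = False,
) -> float:
    """Avoidance index of the flagged pixels.

    The tube is bisected at its midpoint; the index is
    ``(count in odorant half - count in solvent half) / M``.  With an odd
    span the middle column belongs to neither half but still counts in
    ``M``.  As written the index is positive for attraction; set
    ``aversion_positive=True`` to report aversion as positive instead.
    Empty masks give NaN.
    """
    g = geometry if geometry is not None else mask.geometry
    if geometry is not None and geometry != mask.geometry:
        mask = PixelMask(mask.flags, geometry)
    m = mask.count
    if m == 0:
        return math.nan
    L = g.length_px
    off = mask.offsets
    n_odor = int((off < L // 2).sum())
    n_solv = int((off >= L - L // 2).sum())
    ai = (n_odor - n_solv) / m
    return float(-ai if aversion_positive else ai)


def mask_from_positions(
    positions: Sequence[float], geometry: TubeGeometry, normalized: bool = True, tube_length_mm: float = 150.0
) -> PixelMask:
    """Point-mass mask from lengthwise fly positions.

    Each position (normalized to [0, 1] from the odorant end, or in mm
    when ``normalized=False``) is mapped to its nearest tube column; each
    fly occupies its own mask row so coincident flies keep their
    multiplicity in the pixel statistics.
    """
    u = np.asarray(positions, dtype=np.float64)
    if u.ndim != 1:
        raise ValueError("positions must be 1-D")
    if not normalized:
        u = u / float(tube_length_mm)
    if u.size and (u.min() < -1e-9 or u.max() > 1 + 1e-9):
        raise ValueError("normalized positions must lie in [0, 1]")
    L = geometry.length_px
    off = np.rint(np.clip(u, 0.0, 1.0) * (L - 1)).astype(np.int64)
    if geometry.odorant_end == "low":
        cols = geometry.c0 + off
    else:
        cols = geometry.c1 - off
    flags = np.zeros((max(u.size, 1), geometry.c1 + 1), dtype=bool)
    flags[np.arange(u.size), cols] = True
    return PixelMask(flags=flags, geometry=geometry)


def track_stack(
    frames: Iterable[np.ndarray],
    spec: ThresholdSpec,
    geometry: TubeGeometry,
    fps: float = 1.0,
    aversion_positive: bool = False,
) -> pd.DataFrame:
    """Apply the per-frame statistics to an image stack.

    Returns a data frame with one row per frame and columns ``frame``,
    ``time_s``, ``com``, ``ai`` and ``n_pixels``.  Frames in which no
    pixel crosses the threshold are carried as missing (NaN) statistics.
    """
    if fps <= 0 or not math.isfinite(fps):
        raise ValueError("fps must be positive and finite")
    rows = []
    for i, frame in enumerate(frames):
        mask = threshold_frame(frame, spec, geometry)
        rows.append(
            {
                "frame": i,
                "time_s": i / fps,
                "com": compute_com(mask),
                "ai": compute_ai(mask, aversion_positive=aversion_positive),
                "n_pixels": mask.count,
            }
        )
    if not rows:
        raise ValueError("empty frame stack")
    return pd.DataFrame(rows)
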