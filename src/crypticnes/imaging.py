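"""Per-cell nuclear/total (N/T) fluorescence quantification.

The N/T ratio — summed nuclear signal over summed whole-cell signal —
tracks nuclear retention versus export of a fluorescently tagged
protein: export-competent cargo drains from the nucleus and the ratio
falls.  Cells are segmented by global Otsu thresholding plus connected
components on each channel; nuclei are assigned to the enclosing cell;
cells touching the image border are discarded.  N and T are integrated
(summed) background-subtracted intensities, with the background taken
as the median intensity outside all cell masks and negative
post-subtraction pixels clamped to zero.

Time courses are normalized per group so the t = 0 mean ratio equals 1
exactly; the SEM is scaled by the same factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border


class NormalizationError(ValueError):
    """Raised when a group lacks a usable t = 0 sample."""


@dataclass
class CellImage:
    """A two-channel field of view: protein signal plus nuclear marker."""

    signal: np.ndarray
    nuclei: np.ndarray
    group: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        if self.signal.shape != self.nuclei.shape:
            raise ValueError(
                f"channel shapes differ: {self.signal.shape} vs {self.nuclei.shape}"
            )
        if self.signal.ndim != 2:
            raise ValueError("channels must be 2-D")
        if not (np.all(np.isfinite(self.signal)) and np.all(np.isfinite(self.nuclei))):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class CellMasks:
    """Boolean masks for one segmented cell; nucleus is a subset of cell."""

    cell: np.ndarray
    nucleus: np.ndarray


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    N: float
    T: float
    ratio: float
    group: str = ""
    time_min: float = 0.0


@dataclass(frozen=True)
class TimeCourse:
    """Per-group N/T trajectory, normalized to the group's t = 0 mean."""

    group: str
    times: tuple[float, ...]
    mean_ratio: tuple[float, ...]
    sem: tuple[float, ...]
    n: tuple[int, ...]
    normalized_mean: tuple[float, ...]
    normalized_sem: tuple[float, ...]


def _threshold_components(channel: np.ndarray, min_area: int) -> np.ndarray:
    """Label connected components above a global Otsu threshold.

    The threshold is the background median plus five robust standard
    deviations (1.4826 * MAD): with background the dominant pixel class
    this lands between background and foreground regardless of how
    bright or dim nuclei are relative to cytoplasm, where a plain Otsu
    split can land between the two foreground classes instead.  For
    noise-free images (MAD = 0) Otsu is the fallback.  Holes are filled
    so a cell whose nucleus falls below threshold still yields one
    solid mask.
    """
    if np.ptp(channel) == 0:
        return np.zeros(channel.shape, dtype=int)
    background = np.median(channel)
    sigma = 1.4826 * np.median(np.abs(channel - background))
    th = background + 5.0 * sigma if sigma > 0 else threshold_otsu(channel)
    lab = label(binary_fill_holes(channel > th))
    if min_area > 1:
        keep = np.zeros(lab.max() + 1, dtype=bool)
        for p in regionprops(lab):
            keep[p.label] = p.area >= min_area
        lab = np.where(keep[lab], lab, 0)
    return lab


def segment_cells(image: CellImage, min_area: int = 20) -> list[CellMasks]:
    """Segment cells and their nuclei.

    Cells come from the signal channel, nuclei from the nuclear-marker
    channel; each nucleus is assigned to the cell containing its
    centroid, and cells touching the image border are discarded.  An
    image with no component above threshold yields an empty list with a
    warning, not an error.
    """
    cell_lab = clear_border(_threshold_components(image.signal, min_area))
    nuc_lab = _threshold_components(image.nuclei, min_area)
    if cell_lab.max() == 0:
        warnings.warn("no cells found above threshold", stacklevel=2)
        return []
    nucleus_of_cell: dict[int, np.ndarray] = {}
    for p in regionprops(nuc_lab):
        r, c = (int(round(v)) for v in p.centroid)
        cell_id = int(cell_lab[r, c])
        if cell_id > 0:
            mask = nuc_lab == p.label
            if cell_id in nucleus_of_cell:
                nucleus_of_cell[cell_id] |= mask
            else:
                nucleus_of_cell[cell_id] = mask
    out: list[CellMasks] = []
    for cell_id in range(1, cell_lab.max() + 1):
        cell_mask = cell_lab == cell_id
        if not cell_mask.any():
            continue
        nuc_mask = nucleus_of_cell.get(cell_id)
        if nuc_mask is None:
            continue  # no nuclear marker inside: cannot measure N
        out.append(CellMasks(cell_mask, nuc_mask & cell_mask))
    return out


def measure_nt(image: CellImage, masks: list[CellMasks]) -> list[CellMeasurement]:
    """Background-subtracted N and T sums and the N/T ratio per cell.

    Background is the median intensity outside all cell masks; pixels
    negative after subtraction are clamped to zero, so 0 <= ratio <= 1.
    Cells with T = 0 are skipped with a warning.
    """
    if not masks:
        return []
    outside = ~np.any([m.cell for m in masks], axis=0)
    background = float(np.median(image.signal[outside])) if outside.any() else 0.0
    corrected = np.clip(image.signal - background, 0.0, None)
    out: list[CellMeasurement] = []
    for i, m in enumerate(masks, start=1):
        T = float(corrected[m.cell].sum())
        if T == 0:
            warnings.warn(f"cell {i}: total intensity is zero, skipped", stacklevel=2)
            continue
        N = float(corrected[m.nucleus].sum())
        out.append(CellMeasurement(i, N, T, N / T, image.group, image.time_min))
    return out


def measurements_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "group": m.group,
                "time_min": m.time_min,
                "N": m.N,
                "T": m.T,
                "ratio": m.ratio,
            }
            for m in measurements
        ],
        columns=["cell_id", "group", "time_min", "N", "T", "ratio"],
    )


def normalize_timecourse(frame: pd.DataFrame) -> list[TimeCourse]:
    """Group-wise mean +/- SEM trajectories with the t = 0 mean set to 1.

    *frame* needs columns ``group``, ``time_min``, ``ratio``.  Each
    group's means (and SEMs, by the same factor) are divided by that
    group's own mean ratio at its t = 0 time point.
    """
    required = {"group", "time_min", "ratio"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    out: list[TimeCourse] = []
    for group, gdf in frame.groupby("group", sort=True):
        stats = (
            gdf.groupby("time_min")["ratio"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
            .sort_values("time_min")
        )
        if 0.0 not in set(stats["time_min"]):
            raise NormalizationError(f"group {group!r} has no t=0 time point")
        t0_mean = float(stats.loc[stats["time_min"] == 0.0, "mean"].iloc[0])
        if not t0_mean > 0:
            raise NormalizationError(f"group {group!r} t=0 mean ratio is not positive")
        sem = (stats["sd"] / np.sqrt(stats["n"])).fillna(0.0)
        out.append(
            TimeCourse(
                group=str(group),
                times=tuple(stats["time_min"]),
                mean_ratio=tuple(stats["mean"]),
                sem=tuple(sem),
                n=tuple(int(v) for v in stats["n"]),
                normalized_mean=tuple(stats["mean"] / t0_mean),
                normalized_sem=tuple(sem / t0_mean),
            )
        )
    return out


def timecourse_frame(courses: list[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in courses:
        for t, m, s, n, nm, ns in zip(
            tc.times, tc.mean_ratio, tc.sem, tc.n, tc.normalized_mean, tc.normalized_sem
        ):
            rows.append(
                {
                    "group": tc.group,
                    "time_min": t,
                    "mean_ratio": m,
                    "sem": s,
                    "n": n,
                    "normalized_mean": nm,
                    "normalized_sem": ns,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "time_min", "mean_ratio", "sem", "n", "normalized_mean", "normalized_sem"],
    )
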