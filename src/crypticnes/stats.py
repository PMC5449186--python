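"""Phenotype and densitometry summary statistics.

Covers the organismal readouts of a transgenic *C. elegans* toxicity
study — bagging rates (eggs hatching inside the mother), eggs laid,
body-bend locomotion rates, uncensored survival — plus relative
immunoprecipitation (IP) efficiency from band densitometry, and the
paired/unpaired two-tailed Student's t-tests used for all pairwise
group comparisons.

Survival is summarized as the exact empirical curve (no Kaplan-Meier
machinery): animals were followed until every one died, so there is no
censoring and S(d) is simply the fraction of animals with death day
strictly greater than d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    """A two-tailed Student's t-test result."""

    test: str  # "paired" or "unpaired"
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnimalRecord:
    """One animal of one transgenic line; absent assays stay None."""

    line: str
    bends_per_min: int | None = None
    death_day: int | None = None
    bagged: bool | None = None
    hatched_eggs: int | None = None
    eggs_48h: int | None = None

    def __post_init__(self) -> None:
        if self.hatched_eggs is not None and self.bagged is not True:
            raise ValueError("hatched_eggs present requires bagged=True")
        for name in ("bends_per_min", "death_day", "hatched_eggs", "eggs_48h"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.death_day is not None and self.death_day < 1:
            raise ValueError("death_day must be >= 1")


@dataclass(frozen=True)
class DensitometryPair:
    """IP and whole-cell-lysate band densities for one sample."""

    label: str
    ip_density: float
    wcl_density: float

    def __post_init__(self) -> None:
        if self.ip_density <= 0 or self.wcl_density <= 0:
            raise ValueError("band densities must be > 0")


@dataclass(frozen=True)
class SurvivalSummary:
    """Empirical survival curve S(d) on days 0..max and mean survival."""

    days: tuple[int, ...]
    surviving_fraction: tuple[float, ...]
    mean_days: float

    def s(self, day: int) -> float:
        """Fraction of animals alive strictly after *day*."""
        if day < 0:
            raise ValueError("day must be >= 0")
        if day >= self.days[-1]:
            return self.surviving_fraction[-1]
        return self.surviving_fraction[day]


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> GroupComparison:
    """Two-tailed Student's t-test (pooled variance if unpaired).

    By convention, two samples with zero variance and equal means give
    t = 0, p = 1 instead of the 0/0 indeterminate form.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        df = len(d) - 1
        if np.all(d == d[0]) and d[0] == 0:
            return GroupComparison("paired", 0.0, df, 1.0)
        res = sps.ttest_rel(x, y)
        return GroupComparison("paired", float(res.statistic), df, float(res.pvalue))
    df = len(x) + len(y) - 2
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return GroupComparison("unpaired", 0.0, df, 1.0)
        return GroupComparison(
            "unpaired", math.copysign(math.inf, x.mean() - y.mean()), df, 0.0
        )
    res = sps.ttest_ind(x, y, equal_var=True)
    return GroupComparison("unpaired", float(res.statistic), df, float(res.pvalue))


def bagging_rate(n_bagged: int, n_total: int) -> float:
    """Percentage of animals that bagged, exact before the final float."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_bagged <= n_total:
        raise ValueError("need 0 <= n_bagged <= n_total")
    return float(Fraction(100 * n_bagged, n_total))


def group_mean_sem(values: Sequence[float]) -> tuple[float, float | None, int]:
    """(mean, SEM, n); SEM is None for a single observation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.size == 1:
        return float(v[0]), None, 1
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size)), int(v.size)


def survival_summary(death_days: Sequence[int]) -> SurvivalSummary:
    """Exact uncensored survival curve and mean survival time.

    ``S(d)`` is the fraction of animals whose death day exceeds ``d``;
    the curve starts at S(0) = 1 and reaches 0 at the last death day.
    """
    days = np.asarray(death_days, dtype=int)
    if days.size == 0:
        raise ValueError("empty input")
    if np.any(days < 1):
        raise ValueError("death days must be >= 1")
    horizon = int(days.max())
    grid = tuple(range(horizon + 1))
    surviving = tuple(float(np.mean(days > d)) for d in grid)
    return SurvivalSummary(grid, surviving, float(days.mean()))


def ip_efficiency(
    pairs: Sequence[DensitometryPair], reference_label: str
) -> dict[str, float]:
    """Relative IP efficiency: per-sample IP/WCL ratio as fold over reference.

    Scale-invariant: multiplying all densities of a blot by a constant
    leaves the folds unchanged, and the reference maps to exactly 1.
    """
    by_label = {p.label: p for p in pairs}
    if reference_label not in by_label:
        raise ValueError(f"reference label {reference_label!r} not among samples")
    ref = by_label[reference_label]
    ref_ratio = ref.ip_density / ref.wcl_density
    return {
        p.label: (p.ip_density / p.wcl_density) / ref_ratio for p in pairs
    }


def compare_lines(
    records: Sequence[AnimalRecord], metric: str, line_a: str, line_b: str
) -> GroupComparison:
    """Unpaired two-tailed t-test on one metric between two lines."""
    valid = {"bends_per_min", "death_day", "hatched_eggs", "eggs_48h"}
    if metric not in valid:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(valid)}")

    def pull(line: str) -> list[float]:
        vals = [
            float(getattr(r, metric))
            for r in records
            if r.line == line and getattr(r, metric) is not None
        ]
        if len(vals) < 2:
            raise ValueError(f"line {line!r} has fewer than 2 values for {metric!r}")
        return vals

    return two_sample_ttest(pull(line_a), pull(line_b), paired=False)


# ---------------------------------------------------------------------------
# CSV round-trip for animal records

ANIMAL_COLUMNS = ["line", "bends_per_min", "death_day", "bagged", "hatched_eggs", "eggs_48h"]


def records_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line": r.line,
                "bends_per_min": r.bends_per_min,
                "death_day": r.death_day,
                "bagged": r.bagged,
                "hatched_eggs": r.hatched_eggs,
                "eggs_48h": r.eggs_48h,
            }
            for r in records
        ],
        columns=ANIMAL_COLUMNS,
    )


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value)


def frame_to_records(frame: pd.DataFrame) -> list[AnimalRecord]:
    missing = set(ANIMAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    return [
        AnimalRecord(
            line=str(row["line"]),
            bends_per_min=_opt_int(row["bends_per_min"]),
            death_day=_opt_int(row["death_day"]),
            bagged=_opt_bool(row["bagged"]),
            hatched_eggs=_opt_int(row["hatched_eggs"]),
            eggs_48h=_opt_int(row["eggs_48h"]),
        )
        for _, row in frame.iterrows()
    ]


def read_records_csv(path) -> list[AnimalRecord]:
    return frame_to_records(pd.read_csv(path))


def write_records_csv(records: Sequence[AnimalRecord], path) -> None:
    records_frame(records).to_csv(path, index=False)
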