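"""Concentration-panel data model, I/O, QC validation and descriptive statistics.

A *panel* is an ordered collection of lip-cosmetic products (lipsticks,
lip glosses, lip balms) each carrying a measured Pb concentration in
mg/kg (numerically identical to μg/g) together with retail metadata.
Non-detects — samples whose concentration fell below the analytical
detection limit — are recorded as 0 with ``detected=False`` and are
*included* in means and standard deviations, the convention under which
a panel with ~41% non-detects can still report an overall mean of
~0.058 mg/kg. An optional half-detection-limit substitution is available
for sensitivity analyses via :meth:`SamplePanel.with_substitution`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ParameterError,
    SchemaError,
    UndefinedCorrelationError,
    UndefinedRpdError,
    ValidationError,
)

__all__ = [
    "Category",
    "SampleRecord",
    "SamplePanel",
    "GroupSummary",
    "SummaryTable",
    "LimitCheck",
    "QcRun",
    "QcReport",
    "read_panel",
    "write_panel",
    "summarize_panel",
    "check_limit",
    "correlate",
    "qc_validate",
    "DEFAULT_CATEGORY_CODES",
]

PANEL_COLUMNS = (
    "sample_id",
    "category",
    "brand",
    "production_country",
    "color",
    "price_rmb",
    "pb_mg_per_kg",
)


class Category(str, Enum):
    """Product category; ordinal coding for correlation follows this order."""

    LIPSTICK = "lipstick"
    LIP_GLOSS = "lip_gloss"
    LIP_BALM = "lip_balm"

    @classmethod
    def parse(cls, text: str) -> "Category":
        key = str(text).strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown category {text!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


#: Ordinal category coding used by :func:`correlate`; overridable per call.
DEFAULT_CATEGORY_CODES: Mapping[Category, int] = {
    Category.LIPSTICK: 1,
    Category.LIP_GLOSS: 2,
    Category.LIP_BALM: 3,
}


@dataclass(frozen=True)
class SampleRecord:
    """One product with its measured Pb concentration.

    ``detected=False`` records a non-detect, stored with concentration 0.
    """

    sample_id: str
    category: Category
    brand: str
    production_country: str
    color: str
    price_rmb: float
    pb_mg_per_kg: float
    detected: bool = True

    def __post_init__(self) -> None:
        if self.pb_mg_per_kg < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative concentration "
                f"{self.pb_mg_per_kg}"
            )
        if self.price_rmb < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative price {self.price_rmb}"
            )
        if not self.detected and self.pb_mg_per_kg != 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: non-detect must be recorded as 0, "
                f"got {self.pb_mg_per_kg}"
            )


@dataclass(frozen=True)
class SamplePanel:
    """Ordered, unit-fixed (mg/kg) collection of :class:`SampleRecord`."""

    records: tuple[SampleRecord, ...]
    unit: str = "mg/kg"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def values(self) -> np.ndarray:
        """Concentrations in panel order, non-detects as 0."""
        return np.array([r.pb_mg_per_kg for r in self.records], dtype=float)

    def with_substitution(self, detection_limit: float) -> "SamplePanel":
        """Return a panel with non-detects replaced by half the detection limit.

        Off by default everywhere; provided for sensitivity analyses of the
        zeros-as-zero convention.
        """
        if detection_limit <= 0:
            raise ParameterError("detection_limit must be positive")
        half = detection_limit / 2.0
        recs = tuple(
            replace(r, pb_mg_per_kg=half, detected=True) if not r.detected else r
            for r in self.records
        )
        return SamplePanel(recs, unit=self.unit)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "category": [r.category.value for r in self.records],
                "brand": [r.brand for r in self.records],
                "production_country": [r.production_country for r in self.records],
                "color": [r.color for r in self.records],
                "price_rmb": [r.price_rmb for r in self.records],
                "pb_mg_per_kg": [r.pb_mg_per_kg for r in self.records],
                "detected": [r.detected for r in self.records],
            }
        )


def read_panel(source: str | TextIO, *, detect_column: bool | None = None) -> SamplePanel:
    """Read a panel from CSV.

    Schema: ``sample_id,category,brand,production_country,color,price_rmb,
    pb_mg_per_kg[,detected]``; UTF-8 with header. Category parses
    case-insensitively. Without a ``detected`` column, rows with
    concentration 0 become non-detects.

    Parameters
    ----------
    source
        Path or open text stream.
    detect_column
        Force interpretation of the optional ``detected`` column; by default
        it is used iff present.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_detect = "detected" in df.columns if detect_column is None else detect_column
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            conc = float(getattr(row, "pb_mg_per_kg"))
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {idx}: unparseable concentration {getattr(row, 'pb_mg_per_kg')!r}"
            ) from None
        if conc < 0:
            raise ValidationError(f"row {idx}: negative concentration {conc}")
        if has_detect:
            detected = str(getattr(row, "detected")).strip().lower() in (
                "true", "1", "yes", "t",
            )
        else:
            detected = conc > 0
        records.append(
            SampleRecord(
                sample_id=str(getattr(row, "sample_id")),
                category=Category.parse(getattr(row, "category")),
                brand=str(getattr(row, "brand")),
                production_country=str(getattr(row, "production_country")),
                color=str(getattr(row, "color")),
                price_rmb=float(getattr(row, "price_rmb")),
                pb_mg_per_kg=conc,
                detected=detected,
            )
        )
    return SamplePanel(tuple(records))


def write_panel(panel: SamplePanel, dest: str | TextIO) -> None:
    """Write a panel to CSV in the documented schema (includes ``detected``)."""
    panel.to_dataframe().to_csv(dest, index=False)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one category (or the overall panel).

    ``sd`` is the sample standard deviation (n−1 denominator), ``None`` when
    the group has a single member. Zeros (non-detects) are included.
    """

    n: int
    mean: float
    sd: float | None
    min: float
    max: float
    nondetect_fraction: float


@dataclass(frozen=True)
class SummaryTable:
    """Per-category + overall descriptive statistics of a panel."""

    groups: Mapping[str, GroupSummary]
    unit: str = "mg/kg"

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            name: {
                "n": g.n,
                "mean": g.mean,
                "sd": g.sd if g.sd is not None else float("nan"),
                "min": g.min,
                "max": g.max,
                "nondetect_fraction": g.nondetect_fraction,
            }
            for name, g in self.groups.items()
        }
        return pd.DataFrame(rows).T.rename_axis("group")

    def to_csv(self, dest: str | TextIO) -> None:
        self.to_dataframe().to_csv(dest)

    def __str__(self) -> str:
        return self.to_dataframe().to_string(float_format=lambda v: f"{v:.5f}")


def _group_stats(records: Sequence[SampleRecord]) -> GroupSummary:
    vals = np.array([r.pb_mg_per_kg for r in records], dtype=float)
    n = len(vals)
    sd = float(np.std(vals, ddof=1)) if n >= 2 else None
    n_nd = sum(1 for r in records if not r.detected)
    return GroupSummary(
        n=n,
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        nondetect_fraction=n_nd / n,
    )


def summarize_panel(panel: SamplePanel) -> SummaryTable:
    """Descriptive statistics per category plus an overall row.

    Means, minima and maxima are taken over *all* values including the zeros
    that encode non-detects; the standard deviation uses the n−1 denominator.
    """
    if len(panel) == 0:
        raise ValidationError("cannot summarize an empty panel")
    groups: dict[str, GroupSummary] = {}
    for cat in Category:
        members = [r for r in panel if r.category is cat]
        if members:
            groups[cat.value] = _group_stats(members)
    groups["total"] = _group_stats(panel.records)
    return SummaryTable(groups=groups, unit=panel.unit)


@dataclass(frozen=True)
class LimitCheck:
    """Per-sample regulatory-limit exceedance flags and overall verdict."""

    limit: float
    flags: Mapping[str, bool]
    verdict: str  # "compliant" | "non-compliant"

    @property
    def n_exceedances(self) -> int:
        return sum(self.flags.values())


def check_limit(panel: SamplePanel, limit: float = 10.0) -> LimitCheck:
    """Flag samples whose concentration strictly exceeds the regulatory limit.

    The 10 mg/kg default is the Pb-in-cosmetics limit shared by China, the
    United States and Canada. A value exactly at the limit is compliant.
    """
    if limit <= 0:
        raise ParameterError(f"limit must be positive, got {limit}")
    flags = {r.sample_id: r.pb_mg_per_kg > limit for r in panel}
    verdict = "compliant" if not any(flags.values()) else "non-compliant"
    return LimitCheck(limit=limit, flags=flags, verdict=verdict)


def correlate(
    panel: SamplePanel,
    x: str = "category_code",
    method: str = "spearman",
    *,
    category_codes: Mapping[Category, int] | None = None,
) -> tuple[float, float]:
    """Correlate Pb concentration against category coding or price.

    Returns ``(coefficient, two-sided p-value)``. Category is ordinal-coded
    lipstick=1, lip gloss=2, lip balm=3 by default (override with
    ``category_codes``); Spearman is the default method because the coding is
    ordinal, with Pearson available for sensitivity.
    """
    if len(panel) < 3:
        raise ValidationError("correlation needs at least 3 samples")
    codes = DEFAULT_CATEGORY_CODES if category_codes is None else category_codes
    if x == "category_code":
        xs = np.array([codes[r.category] for r in panel], dtype=float)
    elif x == "price":
        xs = np.array([r.price_rmb for r in panel], dtype=float)
    else:
        raise ParameterError(f"x must be 'category_code' or 'price', got {x!r}")
    ys = panel.values
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: one of the variables is constant"
        )
    if method == "spearman":
        res = stats.spearmanr(xs, ys)
    elif method == "pearson":
        res = stats.pearsonr(xs, ys)
    else:
        raise ParameterError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class QcRun:
    """Quality-control measurements for one analytical run.

    ``parallel_pairs`` holds replicate concentration pairs; ``calibration_r``
    is the correlation coefficient of the instrument standard curve;
    ``blank_values`` are blank-sample readings compared against
    ``detection_limit``.
    """

    parallel_pairs: tuple[tuple[float, float], ...]
    calibration_r: float
    blank_values: tuple[float, ...] = ()
    detection_limit: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "parallel_pairs", tuple(tuple(p) for p in self.parallel_pairs)
        )
        object.__setattr__(self, "blank_values", tuple(self.blank_values))
        if not -1.0 <= self.calibration_r <= 1.0:
            raise ValidationError(
                f"calibration_r must be in [-1, 1], got {self.calibration_r}"
            )


@dataclass(frozen=True)
class QcReport:
    """Pass/fail outcome per QC rule with the items that failed."""

    pair_rpds: tuple[float, ...]
    pair_passes: tuple[bool, ...]
    calibration_pass: bool
    blanks_pass: bool
    failed_items: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failed_items

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rpd": self.pair_rpds, "pass": self.pair_passes}
        ).rename_axis("pair")


def qc_validate(run: QcRun, max_rpd: float = 0.10, min_r: float = 0.995) -> QcReport:
    """Validate a QC run against replicate, calibration and blank rules.

    A replicate pair passes iff its relative deviation |a−b|/mean(a,b) is at
    most ``max_rpd`` (10% default); calibration passes iff the standard-curve
    correlation is at least ``min_r`` (0.995 default, inclusive); blanks pass
    iff all readings fall strictly below the detection limit.
    """
    rpds: list[float] = []
    pair_passes: list[bool] = []
    failed: list[str] = []
    for i, (a, b) in enumerate(run.parallel_pairs):
        m = (a + b) / 2.0
        if m == 0:
            raise UndefinedRpdError(f"pair {i}: mean is zero, RPD undefined")
        rpd = abs(a - b) / m
        ok = rpd <= max_rpd
        rpds.append(rpd)
        pair_passes.append(ok)
        if not ok:
            failed.append(f"parallel_pair[{i}]: RPD {rpd:.4f} > {max_rpd}")
    calibration_pass = run.calibration_r >= min_r
    if not calibration_pass:
        failed.append(
            f"calibration: r {run.calibration_r:.4f} < {min_r}"
        )
    blanks_pass = all(v < run.detection_limit for v in run.blank_values)
    if run.blank_values and not blanks_pass:
        failed.append("blanks: reading at or above detection limit")
    if not run.blank_values:
        blanks_pass = True
    return QcReport(
        pair_rpds=tuple(rpds),
        pair_passes=tuple(pair_passes),
        calibration_pass=calibration_pass,
        blanks_pass=blanks_pass,
        failed_items=tuple(failed),
    )
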