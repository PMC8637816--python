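"""Synthetic concentration panels and QC runs.

Generates product panels with the statistical structure the analysis
assumes: three categories (12 lipsticks, 13 lip glosses, 9 lip balms by
default), a ~41% non-detect mass at zero, positive concentrations drawn
from the lognormal moment-matched to the study's overall mean 0.05791 and
sd 0.10146 mg/kg (μ = −3.5507, σ = 1.1848), and retail prices drawn
uniformly within one of the market terciles (edges 95 and 266 RMB).
Brand/colour/country vocabularies are neutral placeholder strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .panel import Category, QcRun, SamplePanel, SampleRecord

__all__ = ["PanelSpec", "QcSpec", "generate_panel", "generate_qc_run"]

_BRANDS = ("Brand A", "Brand B", "Brand C", "Brand D", "Brand E",
           "Brand F", "Brand G", "Brand H")
_COUNTRIES = ("Country 1", "Country 2", "Country 3", "Country 4")
_COLORS = ("red", "orange red", "brick red", "pink", "brown", "colorless")

_PREFIX = {Category.LIPSTICK: "LS", Category.LIP_GLOSS: "LG", Category.LIP_BALM: "LB"}


@dataclass(frozen=True)
class PanelSpec:
    """Generator settings for a synthetic concentration panel.

    ``n_per_category`` orders counts as (lipstick, lip gloss, lip balm);
    ``p_zero`` is the non-detect probability; (``mu``, ``sigma``) the
    log-scale parameters of positive concentrations; ``price_bins`` the
    tercile edges in RMB.
    """

    n_per_category: tuple[int, int, int] = (12, 13, 9)
    p_zero: float = 0.41
    mu: float = -3.5507
    sigma: float = 1.1848
    price_bins: tuple[float, float] = (95.0, 266.0)
    price_max: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_category", tuple(self.n_per_category))
        object.__setattr__(self, "price_bins", tuple(self.price_bins))
        if any(n < 1 for n in self.n_per_category):
            raise ParameterError("category counts must be at least 1")
        if not 0.0 <= self.p_zero < 1.0:
            raise ParameterError(f"p_zero must lie in [0, 1), got {self.p_zero}")
        if self.sigma <= 0:
            raise ParameterError("sigma must be strictly positive")
        lo, hi = self.price_bins
        if not 0 < lo < hi < self.price_max:
            raise ParameterError("price_bins must satisfy 0 < lo < hi < price_max")


@dataclass(frozen=True)
class QcSpec:
    """Generator settings for a synthetic QC run.

    ``replicate_cv`` is the coefficient of variation of the multiplicative
    replicate noise; ``calibration_r_true`` the standard-curve correlation
    to report.
    """

    replicate_cv: float = 0.02
    calibration_r_true: float = 0.999
    detection_limit: float = 0.001
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ParameterError("replicate_cv must be non-negative")
        if not -1.0 <= self.calibration_r_true <= 1.0:
            raise ParameterError("calibration_r_true must lie in [-1, 1]")
        if self.detection_limit <= 0:
            raise ParameterError("detection_limit must be strictly positive")


def generate_panel(spec: PanelSpec = PanelSpec()) -> SamplePanel:
    """Draw a synthetic panel: per record, a non-detect (0) with probability
    ``p_zero``, otherwise a lognormal concentration; prices uniform within a
    randomly chosen tercile. Identical seed ⇒ identical panel."""
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    edges = (0.0, *spec.price_bins, spec.price_max)
    for cat, n in zip(Category, spec.n_per_category):
        for i in range(n):
            nondetect = rng.random() < spec.p_zero
            conc = 0.0 if nondetect else float(
                rng.lognormal(mean=spec.mu, sigma=spec.sigma)
            )
            tercile = int(rng.integers(0, 3))
            price = float(
                np.round(rng.uniform(edges[tercile], edges[tercile + 1]), 2)
            )
            records.append(
                SampleRecord(
                    sample_id=f"{_PREFIX[cat]}{i + 1}",
                    category=cat,
                    brand=str(rng.choice(_BRANDS)),
                    production_country=str(rng.choice(_COUNTRIES)),
                    color=str(rng.choice(_COLORS)),
                    price_rmb=price,
                    pb_mg_per_kg=conc,
                    detected=not nondetect,
                )
            )
    return SamplePanel(tuple(records))


def generate_qc_run(panel: SamplePanel, spec: QcSpec = QcSpec()) -> QcRun:
    """Build a QC run for a panel: each detected sample gets a replicate pair
    with multiplicative lognormal noise of the given CV, the calibration
    correlation is set to the target, and blanks fall below the detection
    limit."""
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.replicate_cv**2)))
    pairs: list[tuple[float, float]] = []
    for rec in panel:
        if not rec.detected:
            continue
        if sigma == 0:
            pairs.append((rec.pb_mg_per_kg, rec.pb_mg_per_kg))
        else:
            noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=2)
            pairs.append(
                (rec.pb_mg_per_kg * float(noise[0]), rec.pb_mg_per_kg * float(noise[1]))
            )
    blanks = tuple(
        float(v) for v in rng.uniform(0.0, spec.detection_limit * 0.5, spec.n_blanks)
    )
    return QcRun(
        parallel_pairs=tuple(pairs),
        calibration_r=spec.calibration_r_true,
        blank_values=blanks,
        detection_limit=spec.detection_limit,
    )
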