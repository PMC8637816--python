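"""Adult Lead Model (ALM) and the child multi-media Pb intake layer.

The ALM maps medium Pb exposure linearly onto adult blood lead (μg/dl):

    PbB = Pbs·BKSF·IR_SD·AF_SD·EF_S/AT           (soil + dust term)
        + PbL·BKSF·IR_L·AF_L·EF_L/AT             (lip-cosmetic term)
        + PbB0                                   (baseline)

with BKSF the biokinetic slope factor (μg/dl blood per μg/d uptake, here
0.4 d/dl), IR intakes in g/d, AF absorption fractions, and EF/AT contact
days per averaged year. Two background scenarios are modelled: *low*
(baseline only — soil is computed but excluded from the total) and *high*
(baseline plus the soil term, ≈2.03 μg/dl with the defaults). Maternal
blood lead transfers to the fetus at a fixed fraction: 0.85 under the ALM
convention, 0.9 under the IEUBK convention.

Two rounding modes are provided. ``full_precision`` (default) carries
floats through. ``paper_emulation`` reproduces spreadsheet-style report
tables digit-for-digit: the lip term is rounded half-up to 4 decimals and
the background to 2 decimals before summing, and fetal products are
truncated toward zero at 4 decimals.

The child side stops deliberately at the intake/uptake input layer of the
IEUBK model — absorbed μg/d per medium (air, water, diet, soil+dust, lip
balm) — and does not attempt the biokinetic compartment solver that turns
uptake into a blood-lead prediction; a user-supplied response function may
be applied to the totals instead.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from decimal import ROUND_DOWN, Decimal
from typing import Callable, Mapping, Sequence, TextIO

import pandas as pd

from ._rounding import round_half_up
from .errors import ParameterError, ValidationError

__all__ = [
    "ALMParams",
    "BLLBreakdown",
    "ScenarioGrid",
    "ChildExposureParams",
    "MediaUptake",
    "adult_bll",
    "maternal_transfer",
    "scenario_table",
    "maternal_input_mean",
    "maternal_inputs",
    "child_lip_intake",
    "child_media_uptake",
    "AGE_BANDS",
    "USER_LIP_INTAKES",
    "TRANSFER_RATES",
]

#: Lip-cosmetic intake (g/d) per user class in the blood-lead model.
USER_LIP_INTAKES: Mapping[str, float] = {"average": 0.0258, "high": 0.1490}

#: Maternal-fetal transfer conventions: ALM 0.85, IEUBK 0.9.
TRANSFER_RATES: tuple[float, ...] = (0.85, 0.9)


@dataclass(frozen=True)
class ALMParams:
    """Adult Lead Model inputs with the study defaults.

    Units: concentrations μg/g, intakes g/d, exposure/averaging d/year,
    BKSF d/dl, blood lead μg/dl. The soil concentration 282 μg/g is a
    Chinese soil Pb reference value; 1.62 μg/dl the reference baseline
    blood lead; lip absorption is conservatively complete (AF_L = 1).
    """

    Pbs: float = 282.0  # soil Pb, μg/g
    PbL: float = 0.05791  # lip-cosmetic Pb, μg/g (panel mean)
    PbB0: float = 1.62  # baseline blood lead, μg/dl
    BKSF: float = 0.4  # biokinetic slope factor, d/dl
    IR_SD: float = 0.05  # soil + dust intake, g/d
    IR_L: float = 0.0258  # lip-cosmetic intake, g/d (average user)
    AF_SD: float = 0.12  # soil absorption fraction
    AF_L: float = 1.0  # lip absorption fraction
    EF_S: float = 220.0  # soil exposure, d/year
    EF_L: float = 365.0  # lip exposure, d/year
    AT: float = 365.0  # averaging time, d/year
    transfer_rate: float = 0.85  # maternal-fetal fraction

    def __post_init__(self) -> None:
        for f in ("Pbs", "PbL", "PbB0", "BKSF", "IR_SD", "IR_L", "EF_S", "EF_L", "AT"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be non-negative")
        for f in ("AF_SD", "AF_L", "transfer_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{f} must lie in [0, 1], got {v}")
        if self.AT <= 0:
            raise ValidationError("AT must be strictly positive")
        if self.EF_S > self.AT or self.EF_L > self.AT:
            raise ValidationError("exposure frequency cannot exceed averaging time")

    def for_user(self, user: str) -> "ALMParams":
        """Return a copy with the lip intake of the named user class."""
        try:
            return replace(self, IR_L=USER_LIP_INTAKES[user])
        except KeyError:
            raise ParameterError(
                f"unknown user class {user!r}; expected {sorted(USER_LIP_INTAKES)}"
            ) from None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BLLBreakdown:
    """Additive decomposition of adult blood lead (all μg/dl).

    ``total = background + lip_term``; in the low-background scenario the
    soil term is reported but excluded from the total, in the high-background
    scenario ``background = baseline + soil_term``. ``fetal`` is
    ``transfer_rate × total``.
    """

    soil_term: float
    lip_term: float
    baseline: float
    background: float
    total: float
    fetal: float
    scenario: str
    rounding: str
    transfer_rate: float


def _terms(p: ALMParams) -> tuple[float, float]:
    soil = p.Pbs * p.BKSF * p.IR_SD * p.AF_SD * p.EF_S / p.AT
    lip = p.PbL * p.BKSF * p.IR_L * p.AF_L * p.EF_L / p.AT
    return soil, lip


def _check_mode(rounding: str) -> None:
    if rounding not in ("full_precision", "paper_emulation"):
        raise ParameterError(
            f"rounding must be 'full_precision' or 'paper_emulation', got {rounding!r}"
        )


def adult_bll(
    p: ALMParams,
    scenario: str = "low_background",
    rounding: str = "full_precision",
) -> BLLBreakdown:
    """Evaluate the ALM for one parameter set and background scenario."""
    _check_mode(rounding)
    if scenario not in ("low_background", "high_background"):
        raise ParameterError(
            f"scenario must be 'low_background' or 'high_background', got {scenario!r}"
        )
    soil, lip = _terms(p)
    if scenario == "low_background":
        background = p.PbB0
    else:
        background = p.PbB0 + soil
    if rounding == "paper_emulation":
        lip = round_half_up(lip, 4)
        background = round_half_up(background, 2)
        total = float(Decimal(repr(background)) + Decimal(repr(lip)))
    else:
        total = background + lip
    fetal = maternal_transfer(total, p.transfer_rate, rounding)
    return BLLBreakdown(
        soil_term=soil,
        lip_term=lip,
        baseline=p.PbB0,
        background=background,
        total=total,
        fetal=fetal,
        scenario=scenario,
        rounding=rounding,
        transfer_rate=p.transfer_rate,
    )


def maternal_transfer(
    PbB: float, rate: float, rounding: str = "full_precision"
) -> float:
    """Fetal blood lead as a fixed fraction of maternal blood lead.

    ``paper_emulation`` truncates the product toward zero at 4 decimals
    (spreadsheet display convention; truncation, not rounding, is what
    report tables built this way show).
    """
    _check_mode(rounding)
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"transfer rate must lie in [0, 1], got {rate}")
    if rounding == "paper_emulation":
        product = Decimal(repr(PbB)) * Decimal(repr(rate))
        return float(product.quantize(Decimal("0.0001"), rounding=ROUND_DOWN))
    return rate * PbB


@dataclass(frozen=True)
class ScenarioGrid:
    """Blood-lead totals over backgrounds × users, and fetal values × rates."""

    totals: Mapping[tuple[str, str], float]  # (background, user) -> μg/dl
    fetal: Mapping[tuple[str, str, float], float]  # (background, user, rate)
    breakdowns: Mapping[tuple[str, str], BLLBreakdown]
    rounding: str

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (background, user, rate)."""
        rows = []
        for (bg, user, rate), fetal in self.fetal.items():
            bd = self.breakdowns[(bg, user)]
            rows.append(
                {
                    "background": bg,
                    "user": user,
                    "transfer_rate": rate,
                    "background_bll": bd.background,
                    "lip_term": bd.lip_term,
                    "total_bll": self.totals[(bg, user)],
                    "fetal_bll": fetal,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, dest: str | TextIO) -> None:
        self.to_dataframe().to_csv(dest, index=False)


def scenario_table(
    p: ALMParams = ALMParams(),
    backgrounds: Sequence[str] = ("low_background", "high_background"),
    users: Sequence[str] = ("average", "high"),
    rates: Sequence[float] = TRANSFER_RATES,
    rounding: str = "full_precision",
) -> ScenarioGrid:
    """Evaluate the ALM over the background × user × transfer-rate grid."""
    _check_mode(rounding)
    totals: dict[tuple[str, str], float] = {}
    fetal: dict[tuple[str, str, float], float] = {}
    breakdowns: dict[tuple[str, str], BLLBreakdown] = {}
    for bg in backgrounds:
        for user in users:
            bd = adult_bll(p.for_user(user), bg, rounding)
            totals[(bg, user)] = bd.total
            breakdowns[(bg, user)] = bd
            for rate in rates:
                fetal[(bg, user, rate)] = maternal_transfer(bd.total, rate, rounding)
    return ScenarioGrid(totals=totals, fetal=fetal, breakdowns=breakdowns,
                        rounding=rounding)


def maternal_input_mean(fetal_values: Sequence[float]) -> float:
    """Maternal blood-lead input for the child model: mean of the four fetal
    values (2 user classes × 2 transfer rates) of one background scenario."""
    if len(fetal_values) != 4:
        raise ValidationError(
            f"expected exactly 4 fetal values (2 users × 2 rates), "
            f"got {len(fetal_values)}"
        )
    return sum(fetal_values) / 4.0


def maternal_inputs(grid: ScenarioGrid) -> dict[str, float]:
    """Per-background maternal inputs from a 2-user × 2-rate scenario grid."""
    out: dict[str, float] = {}
    backgrounds = {bg for bg, _, _ in grid.fetal}
    for bg in sorted(backgrounds):
        vals = [v for (b, _, _), v in grid.fetal.items() if b == bg]
        out[bg] = maternal_input_mean(vals)
    return out


def child_lip_intake(conc: float, ir: float) -> float:
    """Daily Pb intake (μg/d) of a child from lip balm: concentration (μg/g)
    times intake rate (g/d). Children are assumed to contact lip balm only;
    other product categories reach them via maternal transfer."""
    if conc < 0 or ir < 0:
        raise ValidationError("concentration and intake rate must be non-negative")
    return conc * ir


#: Child age bands (years) and their banded intake defaults.
AGE_BANDS: tuple[str, ...] = ("0.5-1", "1-2", "2-3", "3-4", "4-5", "5-6", "6-7")

#: Drinking-water intake L/d per age band (national standard values).
_WATER_INTAKE = dict(zip(AGE_BANDS, (0.2, 0.5, 0.52, 0.53, 0.55, 0.58, 0.59)))
#: Dietary Pb background μg/d: 8 under age 3, 20 for ages 3-7.
_DIET_BACKGROUND = dict(zip(AGE_BANDS, (8.0, 8.0, 8.0, 20.0, 20.0, 20.0, 20.0)))
#: Ventilation m³/d and soil+dust ingestion g/d: standard child exposure
#: defaults by age band, shipped as editable configuration.
_VENTILATION = dict(zip(AGE_BANDS, (2.0, 3.0, 5.0, 5.0, 5.0, 7.0, 7.0)))
_SOIL_INTAKE = dict(zip(AGE_BANDS, (0.085, 0.135, 0.135, 0.135, 0.100, 0.090, 0.085)))


@dataclass(frozen=True)
class ChildExposureParams:
    """Per-medium background concentrations, intake rates and absorption
    fractions for one child age band.

    Defaults: air 0.5 μg/m³ (annual ambient limit) absorbed at 30%; drinking
    water 0.01 μg/L with age-banded intake; dietary background 8 μg/d under
    age 3 and 20 μg/d for 3-7; soil 282 μg/g absorbed at 45%. Water and diet
    absorption default to 0.5; ventilation and soil ingestion are age-banded
    editable defaults.
    """

    age_band: str
    air_conc: float = 0.5  # μg/m³
    air_absorption: float = 0.30
    ventilation: float = 5.0  # m³/d
    water_conc: float = 0.01  # μg/L
    water_intake: float = 0.5  # L/d
    water_absorption: float = 0.5
    diet_background: float = 8.0  # μg/d
    diet_absorption: float = 0.5
    soil_conc: float = 282.0  # μg/g
    soil_intake: float = 0.1  # g/d
    soil_absorption: float = 0.45
    lipbalm_conc: float = 0.0738  # μg/g (panel lip-balm mean)
    lip_ir: float = 0.02578  # g/d
    lip_absorption: float = 1.0

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ParameterError(
                f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}"
            )
        for f in ("air_absorption", "water_absorption", "diet_absorption",
                  "soil_absorption", "lip_absorption"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{f} must lie in [0, 1], got {v}")
        for f in ("air_conc", "ventilation", "water_conc", "water_intake",
                  "diet_background", "soil_conc", "soil_intake",
                  "lipbalm_conc", "lip_ir"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be non-negative")

    @classmethod
    def for_age_band(cls, age_band: str, **overrides) -> "ChildExposureParams":
        """Build parameters with the banded intake defaults for ``age_band``."""
        if age_band not in AGE_BANDS:
            raise ParameterError(
                f"unknown age band {age_band!r}; expected one of {AGE_BANDS}"
            )
        base = dict(
            age_band=age_band,
            water_intake=_WATER_INTAKE[age_band],
            diet_background=_DIET_BACKGROUND[age_band],
            ventilation=_VENTILATION[age_band],
            soil_intake=_SOIL_INTAKE[age_band],
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class MediaUptake:
    """Absorbed Pb μg/d per medium for one age band, and the total."""

    age_band: str
    air: float
    water: float
    diet: float
    soil: float
    lip_cosmetic: float

    @property
    def total(self) -> float:
        return self.air + self.water + self.diet + self.soil + self.lip_cosmetic

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


def child_media_uptake(
    p: ChildExposureParams,
    response: Callable[[float], float] | None = None,
) -> MediaUptake | tuple[MediaUptake, float]:
    """Absorbed Pb per medium: concentration × intake rate × absorption.

    Air uses ventilation volume as the intake rate. This is the intake/uptake
    input layer of the child blood-lead model, not a blood-lead prediction;
    to map the total onto a blood-lead level, pass an explicit ``response``
    function (uptake μg/d → BLL μg/dl) and the pair (uptake, BLL) is returned.
    """
    uptake = MediaUptake(
        age_band=p.age_band,
        air=p.air_conc * p.ventilation * p.air_absorption,
        water=p.water_conc * p.water_intake * p.water_absorption,
        diet=p.diet_background * p.diet_absorption,
        soil=p.soil_conc * p.soil_intake * p.soil_absorption,
        lip_cosmetic=p.lipbalm_conc * p.lip_ir * p.lip_absorption,
    )
    if response is not None:
        return uptake, response(uptake.total)
    return uptake
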