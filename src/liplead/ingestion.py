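"""Deterministic USEPA oral-ingestion risk for Pb in lip cosmetics.

The average daily dose of an ingested contaminant is

    ADD = C · IR · EF · ED · CF / (BW · AT)        [mg/(kg·d)]

with C the product concentration (mg/kg), IR the product intake rate (g/d),
EF exposure frequency (d/a), ED exposure duration (a), CF the g→kg unit
conversion (0.001), BW body weight (kg) and AT averaging time (d). The
non-carcinogenic hazard quotient is HQ = ADD/RfD and the incremental
lifetime cancer risk LCR = ADD·SF. With the default lifetime parameters
EF·ED = 365·70 = 25550 = AT, so ADD reduces to C·IR·CF/BW.

Unit note: IR is in grams of product per day and C in mg of Pb per kg of
product; CF = 0.001 kg/g bridges them so ADD lands in mg/(kg·d). Dropping
CF is the classic 1000× slip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping, TextIO

import yaml

from .errors import ParameterError, ValidationError

__all__ = [
    "ExposureParams",
    "RiskResult",
    "average_daily_dose",
    "hazard_quotient",
    "cancer_risk",
    "assess",
    "HQ_THRESHOLD",
    "LCR_THRESHOLD",
]

#: Risk is flagged "elevated" strictly above these reference values.
HQ_THRESHOLD = 1.0
LCR_THRESHOLD = 1e-6


@dataclass(frozen=True)
class ExposureParams:
    """Exposure-factor set for the oral-ingestion dose equation.

    Defaults are lifetime lip-cosmetic exposure factors for a 60 kg adult:
    daily use over 70 years with averaging time equal to the exposure
    period. Two presets differ only in intake rate: ``average_user``
    (IR = 0.02578 g/d) and ``high_user`` (IR = 0.14902 g/d). RfD and SF are
    USEPA IRIS oral toxicity values for Pb.
    """

    IR: float  # product intake rate, g/d
    EF: float = 365.0  # exposure frequency, d/a
    ED: float = 70.0  # exposure duration, a
    CF: float = 0.001  # g -> kg unit conversion
    BW: float = 60.0  # body weight, kg
    AT: float = 25550.0  # averaging time, d
    RfD: float = 0.0004  # reference dose, mg/(kg·d)
    SF: float = 0.0085  # cancer slope factor, (kg·d)/mg
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in ("IR", "EF", "ED", "CF", "BW", "AT", "RfD", "SF"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"{f} must be strictly positive")

    @classmethod
    def average_user(cls, **overrides) -> "ExposureParams":
        return cls(IR=0.02578, name="average_user").override(**overrides)

    @classmethod
    def high_user(cls, **overrides) -> "ExposureParams":
        return cls(IR=0.14902, name="high_user").override(**overrides)

    def override(self, **overrides) -> "ExposureParams":
        return replace(self, **overrides) if overrides else self

    @classmethod
    def from_mapping(cls, data: Mapping[str, float]) -> "ExposureParams":
        return cls(**data)

    @classmethod
    def from_yaml(cls, stream: str | TextIO) -> "ExposureParams":
        if isinstance(stream, str):
            with open(stream, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(stream)
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RiskResult:
    """Dose and risk metrics for one concentration under one exposure preset."""

    C: float  # concentration, mg/kg
    ADD: float  # average daily dose, mg/(kg·d)
    HQ: float  # hazard quotient, dimensionless
    LCR: float  # lifetime cancer risk, dimensionless
    hq_classification: str  # "acceptable" | "elevated"
    lcr_classification: str
    preset: str = "custom"
    hq_threshold: float = HQ_THRESHOLD
    lcr_threshold: float = LCR_THRESHOLD

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def average_daily_dose(C: float, p: ExposureParams) -> float:
    """ADD = C·IR·EF·ED·CF/(BW·AT), mg per kg body weight per day."""
    if C < 0:
        raise ValidationError(f"concentration must be non-negative, got {C}")
    return C * p.IR * p.EF * p.ED * p.CF / (p.BW * p.AT)


def hazard_quotient(ADD: float, RfD: float) -> float:
    """Non-carcinogenic hazard quotient ADD/RfD; >1 flags concern."""
    if RfD <= 0:
        raise ParameterError(f"RfD must be strictly positive, got {RfD}")
    return ADD / RfD


def cancer_risk(ADD: float, SF: float) -> float:
    """Incremental lifetime cancer risk ADD·SF; >1e−6 flags concern."""
    if SF <= 0:
        raise ParameterError(f"SF must be strictly positive, got {SF}")
    return ADD * SF


def _classify(value: float, threshold: float) -> str:
    # strict: a value exactly at the reference level is still acceptable
    return "elevated" if value > threshold else "acceptable"


def assess(C: float, p: ExposureParams) -> RiskResult:
    """Compose dose, hazard quotient and cancer risk for one concentration."""
    add = average_daily_dose(C, p)
    hq = hazard_quotient(add, p.RfD)
    lcr = cancer_risk(add, p.SF)
    return RiskResult(
        C=C,
        ADD=add,
        HQ=hq,
        LCR=lcr,
        hq_classification=_classify(hq, HQ_THRESHOLD),
        lcr_classification=_classify(lcr, LCR_THRESHOLD),
        preset=p.name,
    )
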