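"""Stoichiometric metabolic-hydrogen ([2H]) balance of rumen fermentation.

Fermentation of hexose to short-chain fatty acids (SCFA) either releases or
consumes pairs of reducing equivalents ("metabolic hydrogen", written [2H]).
Acetate and butyrate formation release 2 mol [2H] per mol of acid; propionate
and valerate formation each consume 1 mol; methanogenesis consumes 4 mol [2H]
per mol CH4.  Caproate is ambiguous: condensation of two propionyl-CoA
consumes 4 mol [2H]/mol (pathway 1), condensation of two acetyl-CoA releases
2 mol [2H]/mol (pathway 2).  Both scenarios are carried through every
calculation in this module.

The balance is pure bookkeeping over daily production rates (mmol/d of each
acid, mL/d of CH4).  CH4 volume is converted to moles with the ideal gas law;
the temperature and pressure to use are explicit arguments because gas-volume
measurements are rarely reported with their reference conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

__all__ = [
    "R_GAS",
    "STANDARD_PRESSURE_KPA",
    "INCUBATION_TEMPERATURE_K",
    "CaproatePathway",
    "StoichiometricTable",
    "FermentationProfile",
    "H2Balance",
    "StoichiometryConfigError",
    "ch4_volume_to_mmol",
    "h2_components",
    "h2_production",
    "h2_utilization",
    "balance_from_components",
    "compute_balance",
    "compute_balance_frame",
    "round_half_away",
]

#: Molar gas constant, J mol^-1 K^-1.  With pressure in kPa and volume in mL,
#: P*V/(R*T) comes out directly in mmol.
R_GAS = 8.3145

#: One standard atmosphere in kPa.
STANDARD_PRESSURE_KPA = 101.325

#: Incubation temperatures of the two thermal conditions, in kelvin.
INCUBATION_TEMPERATURE_K = {39.5: 312.65, 42.0: 315.15}


class StoichiometryConfigError(KeyError):
    """A fermentation product has no coefficient in the stoichiometric table."""


class CaproatePathway(Enum):
    """Biochemical route assumed for caproate formation.

    PROPANYL_COA ("pathway 1"): condensation of 2 propionyl-CoA, incorporating
    4 mol [2H] per mol caproate (a hydrogen sink).
    ACETYL_COA ("pathway 2"): condensation of 2 acetyl-CoA, releasing 2 mol
    [2H] per mol caproate (a hydrogen source).
    """

    PROPANYL_COA = "pathway_1"
    ACETYL_COA = "pathway_2"


# Signed mol [2H] per mol of end product: positive = produced, negative = used.
_DEFAULT_COEFFICIENTS: dict[str, float] = {
    "acetate": +2.0,
    "propionate": -1.0,
    "butyrate": +2.0,
    "valerate": -1.0,
    "methane": -4.0,
}
_CAPROATE_COEFFICIENTS: dict[CaproatePathway, float] = {
    CaproatePathway.PROPANYL_COA: -4.0,
    CaproatePathway.ACETYL_COA: +2.0,
}
# Iso-acids are measured in Rusitec work but excluded from the balance by
# default; when enabled they take the coefficients of their straight-chain
# analogues (branching does not change the redox bookkeeping).
_ISO_COEFFICIENTS: dict[str, float] = {
    "isobutyrate": +2.0,
    "isovalerate": -1.0,
}


@dataclass(frozen=True)
class StoichiometricTable:
    """Signed [2H] coefficients per mole of each fermentation end product.

    ``coefficients`` covers every product except caproate, whose coefficient
    depends on the assumed pathway and lives in ``caproate``.  Extra minor
    products (formate, heptanoate, ...) may be added by the caller; they are
    excluded by default.
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS)
    )
    caproate: Mapping[CaproatePathway, float] = field(
        default_factory=lambda: dict(_CAPROATE_COEFFICIENTS)
    )
    include_iso_acids: bool = False

    def __post_init__(self) -> None:
        for name, value in {**dict(self.coefficients), **dict(self.caproate)}.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite [2H] coefficient for {name!r}: {value}")

    def coefficient(self, product: str, pathway: CaproatePathway) -> float:
        if product == "caproate":
            return self.caproate[pathway]
        if product in self.coefficients:
            return self.coefficients[product]
        if self.include_iso_acids and product in _ISO_COEFFICIENTS:
            return _ISO_COEFFICIENTS[product]
        raise StoichiometryConfigError(
            f"no [2H] coefficient configured for product {product!r}"
        )


DEFAULT_TABLE = StoichiometricTable()


@dataclass(frozen=True)
class FermentationProfile:
    """One fermenter-day of end-product output.

    SCFA rates are mmol/d; ``ch4_volume`` is mL/d at the stated
    ``temperature`` (K) and ``pressure`` (kPa).  ``extras`` holds optional
    minor products (mmol/d) such as iso-acids; they enter the balance only if
    the stoichiometric table carries a coefficient for them.
    """

    acetate: float = 0.0
    propionate: float = 0.0
    butyrate: float = 0.0
    valerate: float = 0.0
    caproate: float = 0.0
    ch4_volume: float = 0.0
    temperature: float = INCUBATION_TEMPERATURE_K[39.5]
    pressure: float = STANDARD_PRESSURE_KPA
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("acetate", "propionate", "butyrate", "valerate", "caproate",
                     "ch4_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name, value in dict(self.extras).items():
            if value < 0:
                raise ValueError(f"extra product {name!r} must be >= 0, got {value}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.pressure <= 0:
            raise ValueError(f"pressure must be > 0 kPa, got {self.pressure}")

    def acid_mmol(self) -> dict[str, float]:
        """Daily mmol of every acid, including extras."""
        base = {
            "acetate": self.acetate,
            "propionate": self.propionate,
            "butyrate": self.butyrate,
            "valerate": self.valerate,
            "caproate": self.caproate,
        }
        base.update(self.extras)
        return base


@dataclass(frozen=True)
class H2Balance:
    """[2H] budget of one profile under one caproate pathway.

    production and utilization are both non-negative mmol [2H]/d;
    gain = production − utilization; recovery = 100 × utilization/production
    (``nan`` when production is zero).  ``components`` keeps the signed
    per-product terms for reporting.
    """

    pathway: CaproatePathway
    production: float
    utilization: float
    gain: float
    recovery: float
    components: Mapping[str, float]


def ch4_volume_to_mmol(volume: float, temperature: float, pressure: float) -> float:
    """Convert a gas volume (mL) to mmol via PV = nRT.

    Parameters are volume in mL, temperature in K, pressure in kPa; with
    R = 8.3145 J mol^-1 K^-1 the result is mmol because
    kPa·mL = 10^-3 J.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    if pressure <= 0:
        raise ValueError(f"pressure must be > 0 kPa, got {pressure}")
    if volume < 0:
        raise ValueError(f"volume must be >= 0 mL, got {volume}")
    return pressure * volume / (R_GAS * temperature)


def h2_components(
    profile: FermentationProfile,
    pathway: CaproatePathway,
    table: StoichiometricTable = DEFAULT_TABLE,
) -> dict[str, float]:
    """Signed [2H] term (mmol/d) for every end product of a profile.

    Each term is coefficient × daily mmol of the product; the methane term
    converts the measured volume with the profile's own T and P.
    """
    components: dict[str, float] = {}
    for product, mmol in profile.acid_mmol().items():
        components[product] = table.coefficient(product, pathway) * mmol
    ch4_mmol = ch4_volume_to_mmol(profile.ch4_volume, profile.temperature,
                                  profile.pressure)
    components["methane"] = table.coefficient("methane", pathway) * ch4_mmol
    return components


def h2_production(
    profile: FermentationProfile,
    pathway: CaproatePathway,
    table: StoichiometricTable = DEFAULT_TABLE,
) -> float:
    """Total [2H] released (mmol/d): the sum of the positive components."""
    return sum(c for c in h2_components(profile, pathway, table).values() if c > 0)


def h2_utilization(
    profile: FermentationProfile,
    pathway: CaproatePathway,
    table: StoichiometricTable = DEFAULT_TABLE,
) -> float:
    """Total [2H] consumed (mmol/d): the sum of |negative components|."""
    return sum(-c for c in h2_components(profile, pathway, table).values() if c < 0)


def balance_from_components(
    components: Mapping[str, float], pathway: CaproatePathway
) -> H2Balance:
    """Aggregate signed per-product [2H] terms into a balance.

    Useful when the per-product [2H] rates are known directly (e.g. from a
    published treatment-mean table) rather than via a raw profile.
    """
    production = sum(c for c in components.values() if c > 0)
    utilization = sum(-c for c in components.values() if c < 0)
    gain = production - utilization
    recovery = 100.0 * utilization / production if production > 0 else math.nan
    return H2Balance(
        pathway=pathway,
        production=production,
        utilization=utilization,
        gain=gain,
        recovery=recovery,
        components=dict(components),
    )


def compute_balance(
    profile: FermentationProfile,
    table: StoichiometricTable = DEFAULT_TABLE,
) -> dict[CaproatePathway, H2Balance]:
    """Full [2H] balance of one profile under both caproate pathways."""
    return {
        pathway: balance_from_components(h2_components(profile, pathway, table), pathway)
        for pathway in CaproatePathway
    }


_PROFILE_COLUMNS = ("acetate", "propionate", "butyrate", "valerate", "caproate")


def compute_balance_frame(
    records: pd.DataFrame,
    table: StoichiometricTable = DEFAULT_TABLE,
    temperature: float | None = None,
    pressure: float = STANDARD_PRESSURE_KPA,
) -> pd.DataFrame:
    """Vectorised balance over a table of fermenter-day records.

    ``records`` needs columns acetate..caproate (mmol/d) and ``ch4_ml``
    (mL/d).  A ``temperature_k`` column takes precedence over the
    ``temperature`` argument; if neither is given, rows are assumed measured
    at the normal incubation temperature (312.65 K).  Returns one row per
    input row with per-pathway production/utilization/gain/recovery and all
    signed components, keyed ``<quantity>_pathway1`` / ``_pathway2``.
    """
    missing = [c for c in (*_PROFILE_COLUMNS, "ch4_ml") if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    out_rows = []
    for _, row in records.iterrows():
        if "temperature_k" in records.columns:
            temp = float(row["temperature_k"])
        elif temperature is not None:
            temp = temperature
        else:
            temp = INCUBATION_TEMPERATURE_K[39.5]
        profile = FermentationProfile(
            **{c: float(row[c]) for c in _PROFILE_COLUMNS},
            ch4_volume=float(row["ch4_ml"]),
            temperature=temp,
            pressure=pressure,
        )
        balances = compute_balance(profile, table)
        rec: dict[str, float] = {}
        for i, pathway in enumerate(
            (CaproatePathway.PROPANYL_COA, CaproatePathway.ACETYL_COA), start=1
        ):
            b = balances[pathway]
            rec[f"h2_production_pathway{i}"] = b.production
            rec[f"h2_utilization_pathway{i}"] = b.utilization
            rec[f"h2_gain_pathway{i}"] = b.gain
            rec[f"h2_recovery_pathway{i}"] = b.recovery
            for product, value in b.components.items():
                rec[f"h2_{product}_pathway{i}"] = value
        out_rows.append(rec)
    return pd.DataFrame(out_rows, index=records.index)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero, as fermentation tables are printed."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)
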