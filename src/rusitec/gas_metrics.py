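"""Fermentation-gas summaries and methane yield metrics.

Total fermentation gas is the sum of the three measured components
(CH4 + CO2 + O2).  CH4 output is additionally expressed per gram of
apparently degraded dry matter (DM) or organic matter (OM) — the difference
between nutrient mass fed and mass recovered in the residue bag — and as the
methane conversion rate (MCR), the fraction of gross-energy (GE) intake lost
as CH4 energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GasRecord",
    "NutrientFlow",
    "EnergyConfig",
    "CH4_ENERGY_DENSITY_KJ_PER_L",
    "total_fermentation_gas",
    "gas_fraction",
    "apparent_disappearance",
    "normalize_ch4",
    "methane_conversion_rate",
    "gas_metrics_frame",
]

#: Default energy density of methane, kJ per litre of gas.  The MCR is
#: uncomputable without it; it is configurable via EnergyConfig.
CH4_ENERGY_DENSITY_KJ_PER_L = 39.54


@dataclass(frozen=True)
class GasRecord:
    """Daily gas volumes (mL/d).  O2 defaults to 0 when not measured."""

    ch4: float
    co2: float
    o2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ch4", "co2", "o2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 mL/d, got {getattr(self, name)}")


@dataclass(frozen=True)
class NutrientFlow:
    """Daily nutrient mass in feed (in) and residue (out), g/d."""

    dm_in: float
    dm_out: float
    om_in: float
    om_out: float

    def __post_init__(self) -> None:
        for nutrient in ("dm", "om"):
            inflow = getattr(self, f"{nutrient}_in")
            outflow = getattr(self, f"{nutrient}_out")
            if not 0 <= outflow <= inflow:
                raise ValueError(
                    f"{nutrient}: need 0 <= out <= in, got out={outflow}, in={inflow}"
                    " (check units)"
                )


@dataclass(frozen=True)
class EnergyConfig:
    """Gross-energy intake (kJ/d) and CH4 energy density (kJ/L)."""

    ge_intake: float
    ch4_energy_density: float = CH4_ENERGY_DENSITY_KJ_PER_L

    def __post_init__(self) -> None:
        if self.ge_intake <= 0:
            raise ValueError(f"ge_intake must be > 0 kJ/d, got {self.ge_intake}")
        if self.ch4_energy_density <= 0:
            raise ValueError(
                f"ch4_energy_density must be > 0 kJ/L, got {self.ch4_energy_density}"
            )


def total_fermentation_gas(gas: GasRecord) -> float:
    """CH4 + CO2 + O2, mL/d."""
    return gas.ch4 + gas.co2 + gas.o2


def gas_fraction(gas: GasRecord, component: str) -> float:
    """Percentage of total gas contributed by one component.

    Returns ``nan`` when the total is zero (empty gas bag).
    """
    if component not in ("ch4", "co2", "o2"):
        raise ValueError(f"unknown gas component {component!r}")
    total = total_fermentation_gas(gas)
    if total <= 0:
        return math.nan
    return 100.0 * getattr(gas, component) / total


def apparent_disappearance(flow: NutrientFlow) -> tuple[float, float]:
    """(DM degraded, OM degraded) in g/d: mass in minus mass out."""
    return flow.dm_in - flow.dm_out, flow.om_in - flow.om_out


def normalize_ch4(ch4: float, degraded: float) -> float:
    """CH4 yield per gram of degraded nutrient, mL/g; nan if nothing degraded."""
    if ch4 < 0:
        raise ValueError(f"ch4 must be >= 0 mL/d, got {ch4}")
    if degraded <= 0:
        return math.nan
    return ch4 / degraded


def methane_conversion_rate(ch4: float, energy: EnergyConfig) -> float:
    """CH4 energy as % of gross-energy intake.

    ch4 is mL/d; CH4 energy = (ch4/1000 L/d) × energy density (kJ/L).
    """
    if ch4 < 0:
        raise ValueError(f"ch4 must be >= 0 mL/d, got {ch4}")
    return 100.0 * (ch4 / 1000.0 * energy.ch4_energy_density) / energy.ge_intake


def gas_metrics_frame(records: pd.DataFrame,
                      ch4_energy_density: float = CH4_ENERGY_DENSITY_KJ_PER_L
                      ) -> pd.DataFrame:
    """Per-record gas metrics over a table of fermenter-days.

    Expects columns ch4_ml, co2_ml, dm_in, dm_out, om_in, om_out and
    ge_intake_kj; o2_ml is optional and defaults to 0 (with a warning, since
    total gas then understates the true total).
    """
    required = ["ch4_ml", "co2_ml", "dm_in", "dm_out", "om_in", "om_out",
                "ge_intake_kj"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    if "o2_ml" not in records.columns:
        warnings.warn("no o2_ml column; assuming O2 = 0 so total gas = CH4 + CO2",
                      stacklevel=2)
    rows = []
    for _, row in records.iterrows():
        gas = GasRecord(ch4=float(row["ch4_ml"]), co2=float(row["co2_ml"]),
                        o2=float(row.get("o2_ml", 0.0)))
        flow = NutrientFlow(dm_in=float(row["dm_in"]), dm_out=float(row["dm_out"]),
                            om_in=float(row["om_in"]), om_out=float(row["om_out"]))
        energy = EnergyConfig(ge_intake=float(row["ge_intake_kj"]),
                              ch4_energy_density=ch4_energy_density)
        dm_deg, om_deg = apparent_disappearance(flow)
        rows.append({
            "total_gas_ml": total_fermentation_gas(gas),
            "ch4_pct_total_gas": gas_fraction(gas, "ch4"),
            "co2_pct_total_gas": gas_fraction(gas, "co2"),
            "dm_degraded_g": dm_deg,
            "om_degraded_g": om_deg,
            "ch4_per_g_dm": normalize_ch4(gas.ch4, dm_deg),
            "ch4_per_g_om": normalize_ch4(gas.ch4, om_deg),
            "mcr_pct_ge": methane_conversion_rate(gas.ch4, energy),
        })
    return pd.DataFrame(rows, index=records.index)
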