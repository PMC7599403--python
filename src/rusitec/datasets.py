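"""Treatment-level reference values of the betaine heat/osmotic-stress
Rusitec experiment that this package's simulator emulates.

These are least-squares means per factor level (osmolality: normal vs
hyperosmotic ~295 vs ~420 mOsmol/kg; temperature 39.5 vs 42 degC; betaine
0/51/286 ppm) of the fermentation-gas and metabolic-hydrogen variables, and
mean genus-level relative abundances of the archaeal community in the liquid
and solid digesta phases.  They serve three purposes: default baselines and
effect sizes for the synthetic generator, the worked example in the README,
and the inputs for the stoichiometric identity checks (the per-product [2H]
rates are inputs; the sums, gains and recoveries are recomputed).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "h2_component_means",
    "h2_totals",
    "gas_parameter_means",
    "genus_means",
    "READS_PER_SAMPLE",
    "N_OTUS",
    "RAREFACTION_DEPTH",
    "OTU_MIN_READS",
]

#: Mean quality-filtered reads per sample in the sequencing dataset.
READS_PER_SAMPLE = 66139
#: Unique OTUs after the <10-read filter.
N_OTUS = 3016
#: Rarefaction depth (lowest single-sample read count).
RAREFACTION_DEPTH = 41921
#: Minimum total reads for an OTU to be retained.
OTU_MIN_READS = 10

# Per-product [2H] rates (mmol [2H]/d), LS means by osmolality level.
# Signed by role: producers positive, sinks negative.
_H2_COMPONENTS = {
    # product: (normal, hyper)
    "acetate": (59.9, 50.3),
    "butyrate": (20.8, 21.3),
    "caproate_produced": (3.76, 2.99),     # pathway 2 source term (+2/mol)
    "propionate": (-16.4, -16.7),
    "valerate": (-3.23, -2.75),
    "caproate_utilized": (-7.5, -6.0),     # pathway 1 sink term (-4/mol)
    "methane": (-13.8, -7.8),
}

# Aggregate [2H] production/utilization (mmol/d), LS means by osmolality.
# These are LS means of the per-sample sums, so they differ in the last
# digit from re-summing the rounded component means above.
_H2_TOTALS = {
    "production_pathway1": (80.6, 71.6),
    "utilization_pathway1": (40.9, 33.2),
    "production_pathway2": (84.4, 74.6),
    "utilization_pathway2": (33.4, 27.2),
}

# Gas and energy variables, LS means by factor level.
_GAS_PARAMETERS = {
    # variable: {level: mean}
    "ch4_ml": {"normal": 87.3, "hyper": 49.3, "39.5": 66.7, "42": 69.9,
               "control": 50.6, "low": 60.1, "high": 94.2},
    "co2_ml": {"normal": 423.8, "hyper": 277.7, "39.5": 346.3, "42": 355.3,
               "control": 328.0, "low": 341.3, "high": 383.0},
    "total_gas_ml": {"normal": 550.3, "hyper": 365.5, "39.5": 450.6,
                     "42": 465.2, "control": 418.6, "low": 438.2,
                     "high": 516.9},
    "ch4_pct_total_gas": {"normal": 15.6, "hyper": 12.8, "39.5": 14.1,
                          "42": 14.3, "control": 11.6, "low": 13.2,
                          "high": 17.8},
    "ch4_per_g_om": {"normal": 13.5, "hyper": 7.9, "39.5": 10.7, "42": 10.7,
                     "control": 7.8, "low": 9.5, "high": 14.8},
    "ch4_per_g_dm": {"normal": 12.2, "hyper": 7.1, "39.5": 9.7, "42": 9.7,
                     "control": 7.0, "low": 8.6, "high": 13.4},
    "mcr_pct_ge": {"normal": 1.63, "hyper": 0.92, "39.5": 1.24, "42": 1.30,
                   "control": 0.94, "low": 1.12, "high": 1.75},
}

# Mean genus relative abundances per digesta phase.  The strictly
# aceticlastic Methanosaeta occurs only in the liquid phase.  Remainder up
# to 1 is unclassified Euryarchaeota; Crenarchaeota are a trace phylum.
_GENUS_MEANS = {
    "liquid": {
        "Methanobrevibacter": 0.49,
        "VadinCA11": 0.303,
        "Methanosphaera": 0.043,
        "Methanimicrococcus": 0.032,
        "Methanobacterium": 1e-5,
        "Methanosarcina": 7e-7,
        "Methanosaeta": 3e-7,
    },
    "solid": {
        "Methanobrevibacter": 0.45,
        "VadinCA11": 0.27,
        "Methanosphaera": 0.13,
        "Methanimicrococcus": 0.01,
        "Methanobacterium": 3e-5,
        "Methanosarcina": 2e-5,
    },
}


def h2_component_means() -> pd.DataFrame:
    """Signed per-product [2H] LS means (mmol/d) by osmolality level.

    Index: product; columns: normal, hyper.  Caproate appears twice, once as
    the pathway-2 source term and once as the pathway-1 sink term.
    """
    return pd.DataFrame(_H2_COMPONENTS, index=["normal", "hyper"]).T


def h2_totals() -> pd.DataFrame:
    """Aggregate [2H] production/utilization LS means by osmolality level."""
    return pd.DataFrame(_H2_TOTALS, index=["normal", "hyper"]).T


def gas_parameter_means() -> pd.DataFrame:
    """Gas/energy LS means by factor level (columns) per variable (rows)."""
    return pd.DataFrame(_GAS_PARAMETERS).T


def genus_means(phase: str) -> dict[str, float]:
    """Mean genus relative abundances for one digesta phase."""
    if phase not in _GENUS_MEANS:
        raise ValueError(f"unknown phase {phase!r}; expected 'liquid' or 'solid'")
    return dict(_GENUS_MEANS[phase])
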