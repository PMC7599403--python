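"""Synthetic Rusitec dataset generator.

Produces complete, internally consistent datasets with the study's
2 x 2 x 3 factorial structure (osmolality x temperature x betaine dose,
6 runs, 12 fermenters per run): daily fermentation records (SCFA mmol/d,
gas mL/d, nutrient flows, gross-energy intake), and per-phase (liquid /
solid) archaeal OTU tables with a taxonomy map and a rooted branch-length
tree.  Every number flows from a single integer seed.

The generative model is deliberately simple — the generator exists to
exercise and validate the analysis pipeline by parameter recovery, not to
model rumen biology:

* fermentation variables: value = baseline + additive treatment shifts
  + run effect N(0, sigma_run) + residual N(0, sigma), truncated at 0;
  baselines and shifts default to the treatment-level means of the study
  being emulated, so that e.g. hyperosmolality lowers CH4 by 38 mL/d and
  stoichiometric [2H] recovery lands in the observed 35-55 % band;
* community: per-sample genus proportions are Dirichlet-distributed around
  phase-specific means, with treatment effects applied as logit-scale
  shifts; reads are allocated multinomially to OTUs whose within-genus
  base weights follow a geometric series (so singleton OTUs occur at
  realistic frequency); read depth is Gaussian around 66,139;
* tree: random coalescent-style joining within genus-level clades, then
  across clades, with exponential branch lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets
from .diversity import OtuTable, PhyloTree
from .factorial import DesignTable, make_design
from .stoichiometry import INCUBATION_TEMPERATURE_K

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_fermentation",
    "simulate_community",
    "simulate_dataset",
    "PHASES",
]

logger = logging.getLogger(__name__)

PHASES = ("liquid", "solid")

# Baseline fermentation values at normal osmolality / 39.5 degC / no betaine.
# SCFA mmol/d are back-computed from the [2H] component means (acetate and
# butyrate carry 2 [2H]/mol, caproate's sink term 4 [2H]/mol).
_BASELINES: dict[str, float] = {
    "acetate": 29.95,      # 59.9 mmol [2H]/d / 2
    "propionate": 16.4,
    "butyrate": 10.4,      # 20.8 / 2
    "valerate": 3.23,
    "caproate": 1.875,     # 7.5 / 4
    "ch4_ml": 87.3,
    "co2_ml": 423.8,
    "o2_ml": 39.2,         # closes total gas at 550.3 mL/d
    "dm_in": 12.0,         # daily feed bag, g DM
    "dm_out": 4.84,        # 7.16 g DM degraded -> CH4/g DM 12.2
    "om_in": 11.0,
    "om_out": 4.53,        # 6.47 g OM degraded -> CH4/g OM 13.5
    "ge_intake_kj": 211.8,
}

# Additive treatment shifts relative to baseline, keyed by the non-reference
# factor levels (hyper osmolality, 42 degC, low/high betaine).  Derived from
# LS-mean differences of the emulated study.
_EFFECTS: dict[str, dict[str, float]] = {
    "ch4_ml": {"hyper": -38.0, "42": 3.2, "low": 9.5, "high": 43.6},
    "co2_ml": {"hyper": -146.1, "42": 9.0, "low": 13.3, "high": 55.0},
    "acetate": {"hyper": -4.8, "42": 1.2, "low": 1.75, "high": 2.9},
    "butyrate": {"hyper": 0.25, "42": -0.1, "low": 0.3, "high": 0.5},
    "propionate": {"hyper": 0.3, "42": -2.1, "low": 1.1, "high": 1.3},
    "valerate": {"hyper": -0.48, "42": 0.43, "low": 0.0, "high": -0.07},
    "caproate": {"hyper": -0.385, "42": 0.36, "low": -0.115, "high": -0.215},
    "dm_out": {"hyper": 0.22},
    "om_out": {"hyper": 0.23},
}

# Residual (within-fermenter, day-to-day) standard deviations.  CH4 is 5
# mL/d; other variables default to 5 % of their baseline magnitude.
_RESIDUAL_SIGMA_OVERRIDES = {"ch4_ml": 5.0}
_RESIDUAL_CV = 0.05
# Between-run standard deviations default to 3 % of baseline.
_RUN_CV = 0.03

_NONNEGATIVE_FIXED = ("dm_in", "om_in", "ge_intake_kj")  # no noise applied


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# Logit-scale community treatment shifts, per phase and genus, derived from
# the study's per-level genus means.
def _default_community_effects() -> dict[str, dict[str, dict[str, float]]]:
    return {
        "liquid": {
            "Methanosphaera": {"hyper": _logit(0.069) - _logit(0.043)},
            "Methanimicrococcus": {"42": _logit(0.033) - _logit(0.019)},
            "VadinCA11": {"42": _logit(0.287) - _logit(0.320)},
        },
        "solid": {
            "Methanobrevibacter": {"hyper": _logit(0.50) - _logit(0.45)},
            "Methanimicrococcus": {"hyper": _logit(0.003) - _logit(0.01),
                                   "42": _logit(0.011) - _logit(0.0045)},
            "VadinCA11": {"42": _logit(0.2426) - _logit(0.293)},
        },
    }


# Trace Crenarchaeota mass per phase (single unclassified genus).
_CRENARCHAEOTA_MASS = {"liquid": 3e-5, "solid": 1e-3}


@dataclass
class SimulationConfig:
    """All knobs of the generator.  ``seed`` is mandatory; every random
    stream is derived from it."""

    seed: int
    n_runs: int = 6
    n_days: int = 5
    baselines: dict[str, float] = field(default_factory=lambda: dict(_BASELINES))
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _EFFECTS.items()})
    residual_sigma: dict[str, float] = field(default_factory=dict)
    run_sigma: dict[str, float] = field(default_factory=dict)
    community_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: datasets.genus_means(p) for p in PHASES})
    community_effects: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_community_effects)
    n_otus: int = datasets.N_OTUS
    otu_geometric_ratio: float = 0.985
    read_depth_mean: float = float(datasets.READS_PER_SAMPLE)
    read_depth_sd: float = 6000.0
    read_depth_min: int = 42000
    dirichlet_concentration: float | None = 150.0
    rarefaction_depth: int = datasets.RAREFACTION_DEPTH

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.seed = int(self.seed)
        if self.n_runs < 1 or self.n_days < 1:
            raise ValueError("n_runs and n_days must be >= 1")
        for var, base in self.baselines.items():
            self.residual_sigma.setdefault(
                var, 0.0 if var in _NONNEGATIVE_FIXED
                else _RESIDUAL_SIGMA_OVERRIDES.get(var, _RESIDUAL_CV * abs(base)))
            self.run_sigma.setdefault(
                var, 0.0 if var in _NONNEGATIVE_FIXED else _RUN_CV * abs(base))
        for sigmas in (self.residual_sigma, self.run_sigma):
            for var, s in sigmas.items():
                if s < 0:
                    raise ValueError(f"sigma for {var!r} must be >= 0, got {s}")
        for phase, means in self.community_means.items():
            total = sum(means.values())
            if total > 1.0 + 1e-9 or any(m < 0 for m in means.values()):
                raise ValueError(
                    f"{phase} genus proportions must be >= 0 and sum to <= 1 "
                    f"(got sum {total})")
        if not 0 < self.otu_geometric_ratio < 1:
            raise ValueError("otu_geometric_ratio must be in (0, 1)")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticDataset:
    """One complete simulated experiment plus the ground truth that made it."""

    design: DesignTable
    fermentation: pd.DataFrame
    otu_tables: dict[str, OtuTable]
    tree: PhyloTree
    ground_truth: dict


def _treatment_shift(effects: Mapping[str, float], osmo: str, temp: str,
                     betaine: str) -> float:
    shift = 0.0
    if osmo == "hyper":
        shift += effects.get("hyper", 0.0)
    if temp == "42":
        shift += effects.get("42", 0.0)
    if betaine in ("low", "high"):
        shift += effects.get(betaine, 0.0)
    return shift


def simulate_fermentation(config: SimulationConfig,
                          design: DesignTable | None = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Daily fermentation records for every fermenter of every run.

    Returns (records, ground_truth).  Records carry one row per
    fermenter-day with identifiers, factor levels, temperature_k, SCFA
    production, gas volumes, nutrient flows and GE intake.  Negative draws
    are truncated at zero and counted in the ground truth.
    """
    if design is None:
        design = make_design(config.n_runs)
    rng = config._rng(1)
    variables = list(config.baselines)
    run_effects = {
        int(run): {v: rng.normal(0.0, config.run_sigma[v]) for v in variables}
        for run in sorted(design.frame["run"].unique())
    }
    rows = []
    n_truncated = 0
    for _, unit in design.frame.iterrows():
        shifts = {
            v: _treatment_shift(config.effects.get(v, {}), unit["osmolality"],
                                unit["temperature"], unit["betaine"])
            for v in variables
        }
        for day in range(6, 6 + config.n_days):
            row = {
                "run": unit["run"], "fermenter": unit["fermenter"], "day": day,
                "osmolality": unit["osmolality"],
                "temperature": unit["temperature"],
                "betaine": unit["betaine"],
                "temperature_k": INCUBATION_TEMPERATURE_K[float(unit["temperature"])],
            }
            for v in variables:
                value = (config.baselines[v] + shifts[v]
                         + run_effects[int(unit["run"])][v]
                         + rng.normal(0.0, config.residual_sigma[v]))
                if value < 0:
                    value = 0.0
                    n_truncated += 1
                row[v] = value
            rows.append(row)
    if n_truncated:
        logger.info("truncated %d negative draws at 0", n_truncated)
    records = pd.DataFrame(rows)
    ground_truth = {
        "baselines": dict(config.baselines),
        "effects": {k: dict(v) for k, v in config.effects.items()},
        "residual_sigma": dict(config.residual_sigma),
        "run_sigma": dict(config.run_sigma),
        "run_effects": {r: dict(e) for r, e in run_effects.items()},
        "n_truncated": n_truncated,
    }
    return records, ground_truth


# ---------------------------------------------------------------------------
# community


def _genus_universe(config: SimulationConfig) -> list[tuple[str, str]]:
    """(genus, phylum) across all phases, plus trace/unclassified bins."""
    genera: dict[str, str] = {}
    for phase in PHASES:
        for genus in config.community_means[phase]:
            genera[genus] = "Euryarchaeota"
    genera["unclassified_Crenarchaeota"] = "Crenarchaeota"
    genera["unclassified"] = "Euryarchaeota"
    return sorted(genera.items())


def _allocate_otus(config: SimulationConfig) -> dict[str, int]:
    """Number of OTUs per genus, proportional to (mean abundance)^0.25.

    The dampened exponent keeps rare genera represented by several OTUs
    while the dominant genera still hold most of the richness.
    """
    mean_over_phases: dict[str, float] = {}
    for genus, _ in _genus_universe(config):
        if genus == "unclassified_Crenarchaeota":
            mean_over_phases[genus] = float(np.mean(list(_CRENARCHAEOTA_MASS.values())))
        elif genus == "unclassified":
            rem = [max(1.0 - sum(config.community_means[p].values())
                       - _CRENARCHAEOTA_MASS[p], 1e-6) for p in PHASES]
            mean_over_phases[genus] = float(np.mean(rem))
        else:
            mean_over_phases[genus] = float(np.mean(
                [config.community_means[p].get(genus, 0.0) for p in PHASES]))
    weights = {g: max(m, 1e-8) ** 0.25 for g, m in mean_over_phases.items()}
    total_w = sum(weights.values())
    alloc = {g: max(3, int(round(config.n_otus * w / total_w)))
             for g, w in weights.items()}
    # adjust the largest genus so the total matches exactly
    delta = config.n_otus - sum(alloc.values())
    largest = max(alloc, key=alloc.get)
    alloc[largest] = max(3, alloc[largest] + delta)
    return alloc


def _coalescent_newick(labels: list[str], rng: np.random.Generator,
                       scale: float) -> str:
    """Random topology by sequential pairwise joining, exp branch lengths."""
    nodes = [f"{lab}:{rng.exponential(scale):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(scale):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


class _OtuUniverse:
    """Shared OTU space: ids, taxonomy, within-genus weights, tree."""

    def __init__(self, config: SimulationConfig):
        rng = config._rng(0)
        alloc = _allocate_otus(config)
        phylum_of = dict(_genus_universe(config))
        self.otu_ids: list[str] = []
        self.taxonomy: dict[str, tuple[str, str]] = {}
        self.genus_otu_slices: dict[str, slice] = {}
        self.genus_weights: dict[str, np.ndarray] = {}
        pos = 0
        clades = []
        for genus in sorted(alloc):
            n = alloc[genus]
            ids = [f"OTU{pos + k + 1:05d}" for k in range(n)]
            self.otu_ids.extend(ids)
            for otu in ids:
                self.taxonomy[otu] = (phylum_of[genus], genus)
            self.genus_otu_slices[genus] = slice(pos, pos + n)
            w = config.otu_geometric_ratio ** np.arange(n)
            self.genus_weights[genus] = w / w.sum()
            pos += n
            clades.append(_coalescent_newick(ids, rng, scale=0.05))
        backbone = _coalescent_newick(clades, rng, scale=0.2)
        # the clade strings are already subtrees; joining them nests newick
        self.newick = backbone + ";"
        self.tree = PhyloTree.from_newick(self.newick)
        self.n_otus = pos

    def probabilities(self, genus_props: Mapping[str, float]) -> np.ndarray:
        p = np.zeros(self.n_otus)
        for genus, prop in genus_props.items():
            if prop <= 0:
                continue
            sl = self.genus_otu_slices[genus]
            p[sl] = prop * self.genus_weights[genus]
        total = p.sum()
        if total <= 0:
            raise ValueError("all genus proportions are zero")
        return p / total


def _phase_genus_means(config: SimulationConfig, phase: str) -> dict[str, float]:
    means = dict(config.community_means[phase])
    means["unclassified_Crenarchaeota"] = _CRENARCHAEOTA_MASS[phase]
    means["unclassified"] = max(1.0 - sum(means.values()), 0.0)
    return means


def expected_genus_proportions(config: SimulationConfig, phase: str,
                               osmolality: str = "normal",
                               temperature: str = "39.5",
                               betaine: str = "control") -> dict[str, float]:
    """Noise-free genus proportions of one treatment cell.

    Phase means with the logit-scale treatment shifts applied and
    renormalised — the Dirichlet mean around which samples scatter, and the
    exact proportions in the infinite-concentration limit.
    """
    means = _phase_genus_means(config, phase)
    for genus, eff in config.community_effects.get(phase, {}).items():
        shift = _treatment_shift(eff, osmolality, temperature, betaine)
        if shift != 0.0 and 0.0 < means.get(genus, 0.0) < 1.0:
            means[genus] = _expit(_logit(means[genus]) + shift)
    total = sum(means.values())
    return {g: m / total for g, m in means.items()}


def simulate_community(config: SimulationConfig, phase: str,
                       design: DesignTable | None = None,
                       universe: _OtuUniverse | None = None
                       ) -> tuple[OtuTable, PhyloTree, dict[str, tuple[str, str]]]:
    """One phase's OTU table plus the (phase-shared) tree and taxonomy.

    Genus proportions per sample are Dirichlet around the phase means with
    logit-scale treatment shifts; ``dirichlet_concentration = None`` is the
    infinite-concentration limit (proportions exactly at their means).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if design is None:
        design = make_design(config.n_runs)
    if universe is None:
        universe = _OtuUniverse(config)
    rng = config._rng(2 if phase == "liquid" else 3)

    sample_ids: list[str] = []
    counts = np.zeros((len(design.frame), universe.n_otus), dtype=np.int64)
    for i, (_, unit) in enumerate(design.frame.iterrows()):
        means = expected_genus_proportions(
            config, phase, unit["osmolality"], unit["temperature"],
            unit["betaine"])
        if config.dirichlet_concentration is not None:
            alpha = np.array([max(m * config.dirichlet_concentration, 1e-12)
                              for m in means.values()])
            draw = rng.dirichlet(alpha)
            props = dict(zip(means.keys(), draw))
        else:
            props = means
        p = universe.probabilities(props)
        depth = int(max(rng.normal(config.read_depth_mean, config.read_depth_sd),
                        config.read_depth_min))
        counts[i] = rng.multinomial(depth, p)
        sample_ids.append(f"{unit['fermenter']}_{phase}")

    table = OtuTable(counts=counts, sample_ids=sample_ids,
                     otu_ids=list(universe.otu_ids),
                     taxonomy=dict(universe.taxonomy))
    return table, universe.tree, dict(universe.taxonomy)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full experiment: design, fermentation records, both phase OTU tables,
    tree and ground truth."""
    design = make_design(config.n_runs)
    fermentation, truth = simulate_fermentation(config, design)
    universe = _OtuUniverse(config)
    otu_tables: dict[str, OtuTable] = {}
    for phase in PHASES:
        table, tree, _ = simulate_community(config, phase, design, universe)
        otu_tables[phase] = table
    truth["community_means"] = {p: _phase_genus_means(config, p) for p in PHASES}
    truth["community_effects"] = {
        p: {g: dict(e) for g, e in config.community_effects.get(p, {}).items()}
        for p in PHASES
    }
    truth["seed"] = config.seed
    return SyntheticDataset(
        design=design, fermentation=fermentation, otu_tables=otu_tables,
        tree=universe.tree, ground_truth=truth,
    )
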