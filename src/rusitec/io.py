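"""Readers, writers and the end-to-end pipeline.

Formats are deliberately plain: delimited tables (TSV/CSV by extension) for
fermentation records, design and results; the classic OTU-table layout
(first column the OTU id, one column per sample, optional trailing
``taxonomy`` column with a semicolon-delimited lineage); newick with branch
lengths for the tree; a square TSV for distance matrices.  All writers are
locale-independent.  Every pipeline output directory carries a JSON manifest
with input checksums, the configuration used and collected warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (OtuTable, PhyloTree, DistanceMatrix, aggregate_taxa,
                        alpha_frame, filter_low_count_otus, pcoa, rarefy,
                        weighted_unifrac)
from .factorial import DesignTable, fit_factorial, pearson_matrix
from .gas_metrics import gas_metrics_frame
from .stoichiometry import compute_balance_frame

__all__ = [
    "read_table", "write_table",
    "read_design", "write_design",
    "read_otu_table", "write_otu_table",
    "read_taxonomy", "write_taxonomy",
    "read_newick", "write_newick",
    "read_distance_matrix", "write_distance_matrix",
    "RunConfig", "run_pipeline", "write_dataset",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path), index=index, lineterminator="\n")


def read_design(path: str | Path) -> DesignTable:
    return DesignTable(read_table(path))


def write_design(design: DesignTable, path: str | Path) -> None:
    write_table(design.frame, path)


def read_otu_table(path: str | Path) -> OtuTable:
    """Classic tab-separated OTU table: rows OTUs, columns samples.

    A trailing ``taxonomy`` column (lineage ``phylum;genus``) is optional.
    Counts must be non-negative integers; the error for a bad cell names it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    otu_col = df.columns[0]
    otu_ids = df[otu_col].tolist()
    if len(set(otu_ids)) != len(otu_ids):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise ValueError(f"duplicate OTU id(s): {dupes}")
    taxonomy: dict[str, tuple[str, str]] = {}
    sample_cols = [c for c in df.columns[1:] if c.lower() != "taxonomy"]
    if "taxonomy" in [c.lower() for c in df.columns]:
        tax_col = next(c for c in df.columns if c.lower() == "taxonomy")
        for otu, lineage in zip(otu_ids, df[tax_col]):
            parts = [p.strip() for p in str(lineage).split(";")]
            phylum = parts[0] if parts and parts[0] else "unclassified"
            genus = parts[1] if len(parts) > 1 and parts[1] else "unclassified"
            taxonomy[otu] = (phylum, genus)
    counts = np.zeros((len(sample_cols), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                value = int(str(raw))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at OTU {otu_ids[i]!r}, "
                    f"sample {col!r}") from None
            if value < 0:
                raise ValueError(
                    f"negative count {value} at OTU {otu_ids[i]!r}, "
                    f"sample {col!r}")
            counts[j, i] = value
    return OtuTable(counts=counts, sample_ids=list(sample_cols),
                    otu_ids=otu_ids, taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path: str | Path,
                    with_taxonomy: bool = True) -> None:
    df = pd.DataFrame(table.counts.T, index=pd.Index(table.otu_ids, name="#OTU ID"),
                      columns=table.sample_ids)
    if with_taxonomy:
        df["taxonomy"] = [";".join(table.taxonomy[o]) for o in table.otu_ids]
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    """OTU id -> semicolon-delimited lineage, two tab-separated columns."""
    taxonomy: dict[str, tuple[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        otu, lineage = line.split("\t", 1)
        parts = [p.strip() for p in lineage.split(";")]
        phylum = parts[0] if parts and parts[0] else "unclassified"
        genus = parts[1] if len(parts) > 1 and parts[1] else "unclassified"
        taxonomy[otu] = (phylum, genus)
    return taxonomy


def write_taxonomy(taxonomy: dict[str, tuple[str, str]], path: str | Path) -> None:
    lines = [f"{otu}\t{phylum};{genus}"
             for otu, (phylum, genus) in taxonomy.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a rooted newick tree; missing branch lengths become 0 with a
    warning (via PhyloTree validation)."""
    text = Path(path).read_text()
    if text.count("(") != text.count(")"):
        offset = len(text.rstrip())
        raise ValueError(
            f"unbalanced parentheses in newick (by character {offset}): "
            f"{text.count('(')} '(' vs {text.count(')')} ')'")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(data=df.to_numpy(dtype=float),
                          ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline


_RUNCONFIG_FIELDS: dict[str, object] = {}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``rarefaction_seed`` is mandatory: the rarefaction subsample is random
    and must be reproducible.  Unknown keys in ``from_dict`` are rejected.
    """

    fermentation: str
    design: str
    otu_tables: dict[str, str]          # phase -> path
    tree: str
    out_dir: str
    rarefaction_seed: int = None  # type: ignore[assignment]
    rarefaction_depth: int = 41921
    min_otu_reads: int = 10
    shannon_base: float = 2.0
    unifrac_normalized: bool = False
    ace_rare_threshold: int = 10
    temperature_k: float | None = None
    pressure_kpa: float = 101.325
    ch4_energy_density: float = 39.54

    def __post_init__(self) -> None:
        if self.rarefaction_seed is None:
            raise ValueError("rarefaction_seed is required (explicit-seed policy)")
        self.rarefaction_seed = int(self.rarefaction_seed)
        for name in ("fermentation", "design", "tree"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for phase, path in self.otu_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"OTU table for {phase!r} missing: {path}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute stoichiometry -> gas metrics -> diversity -> factorial stats.

    Writes result tables plus a JSON manifest into ``config.out_dir``.  A
    failure in any stage removes partial outputs and re-raises with the
    stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    collected_warnings: list[str] = []
    stage = "setup"

    def _write(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        write_table(frame, path, index=index)
        written.append(path)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "load"
            fermentation = read_table(config.fermentation)
            design = read_design(config.design)
            tree = read_newick(config.tree)
            otu_tables = {p: read_otu_table(path)
                          for p, path in config.otu_tables.items()}

            stage = "stoichiometry"
            balance = compute_balance_frame(
                fermentation, temperature=config.temperature_k,
                pressure=config.pressure_kpa)
            id_cols = [c for c in ("run", "fermenter", "day")
                       if c in fermentation.columns]
            _write(pd.concat([fermentation[id_cols], balance], axis=1),
                   "h2_balance.tsv")

            stage = "gas_metrics"
            gas = gas_metrics_frame(fermentation,
                                    ch4_energy_density=config.ch4_energy_density)
            _write(pd.concat([fermentation[id_cols], gas], axis=1),
                   "gas_metrics.tsv")

            stage = "diversity"
            alpha_all = {}
            genus_rel = {}
            for phase, table in otu_tables.items():
                filtered = filter_low_count_otus(table, config.min_otu_reads)
                rare = rarefy(filtered, depth=config.rarefaction_depth,
                              seed=config.rarefaction_seed)
                alpha = alpha_frame(rare, shannon_base=config.shannon_base,
                                    ace_rare_threshold=config.ace_rare_threshold)
                _write(alpha, f"alpha_{phase}.tsv", index=True)
                alpha_all[phase] = alpha
                dm = weighted_unifrac(tree, rare,
                                      normalized=config.unifrac_normalized)
                path = out / f"unifrac_{phase}.tsv"
                write_distance_matrix(dm, path)
                written.append(path)
                ordination = pcoa(dm)
                _write(ordination.coordinates, f"pcoa_coords_{phase}.tsv",
                       index=True)
                _write(pd.DataFrame({
                    "axis": ordination.coordinates.columns,
                    "explained_pct": ordination.explained[
                        :ordination.coordinates.shape[1]],
                }), f"pcoa_explained_{phase}.tsv")
                genus_rel[phase] = aggregate_taxa(rare, "genus")
                _write(genus_rel[phase], f"genus_abundance_{phase}.tsv",
                       index=True)

            stage = "factorial_stats"
            fermen_stats = []
            response_cols = [c for c in ("ch4_ml", "co2_ml", "acetate",
                                         "propionate", "butyrate")
                             if c in fermentation.columns]
            for col in response_cols:
                res = fit_factorial(fermentation, design, response=col)
                eff = res.effects.reset_index()
                eff.insert(0, "response", col)
                fermen_stats.append(eff)
                lsm = res.ls_means.copy()
                lsm.insert(0, "response", col)
                fermen_stats.append(lsm.rename(columns={"lsmean": "estimate"}))
            if fermen_stats:
                _write(pd.concat(fermen_stats, ignore_index=True),
                       "factorial_effects.tsv")

            stage = "correlations"
            daily_mean = fermentation.groupby("fermenter")[response_cols].mean()
            for phase, rel in genus_rel.items():
                rel = rel.copy()
                rel.index = [s.rsplit("_", 1)[0] for s in rel.index]
                corr = pearson_matrix(rel, daily_mean)
                _write(corr["r"], f"correlation_r_{phase}.tsv", index=True)
                _write(corr["pvalue"], f"correlation_p_{phase}.tsv", index=True)

            collected_warnings = [str(w.message) for w in caught]

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": {k: (dict(v) if isinstance(v, dict) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "inputs": {
                "fermentation": _sha256(config.fermentation),
                "design": _sha256(config.design),
                "tree": _sha256(config.tree),
                **{f"otu_table_{p}": _sha256(path)
                   for p, path in config.otu_tables.items()},
            },
            "outputs": sorted(p.name for p in written),
            "warnings": collected_warnings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out


def write_dataset(dataset, out_dir: str | Path) -> Path:
    """Serialize a SyntheticDataset to a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(dataset.design, out / "design.tsv")
    write_table(dataset.fermentation, out / "fermentation.tsv")
    for phase, table in dataset.otu_tables.items():
        write_otu_table(table, out / f"otu_table_{phase}.tsv")
    write_newick(dataset.tree, out / "tree.nwk")
    first = next(iter(dataset.otu_tables.values()))
    write_taxonomy(first.taxonomy, out / "taxonomy.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth, indent=2, sort_keys=True, default=float)
        + "\n")
    return out
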