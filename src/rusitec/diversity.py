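"""Archaeal community analysis from the OTU table down.

Implements the post-clustering half of a 16S amplicon workflow: removal of
low-count OTUs, rarefaction to even depth, alpha diversity (observed
richness, singles, ACE, Shannon, Simpson), genus/phylum aggregation,
weighted UniFrac dissimilarity over a rooted branch-length tree, and
principal coordinate analysis of the resulting distance matrix.

Conventions (all configurable):

* Shannon is reported in bits (log base 2).
* Simpson is reported as 1 − D = 1 − Σ p_i², the probability that two reads
  drawn without replacement-ish are different OTUs; D and 1/D are available.
* Weighted UniFrac is the raw (unnormalised) variant:
  d(A, B) = Σ_b len(b) · |p_A(b) − p_B(b)| over all branches b, where
  p_X(b) is the fraction of sample X's reads on tips below b.
* ACE uses the conventional rare/abundant cutoff of 10 reads.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "PhyloTree",
    "AlphaRecord",
    "DistanceMatrix",
    "Ordination",
    "filter_low_count_otus",
    "rarefy",
    "ace",
    "chao1",
    "alpha_diversity",
    "alpha_frame",
    "weighted_unifrac",
    "pcoa",
    "aggregate_taxa",
]


@dataclass
class OtuTable:
    """Samples × OTUs count matrix with taxonomy labels.

    ``counts`` is a non-negative integer array of shape
    (len(sample_ids), len(otu_ids)).  ``taxonomy`` maps every OTU id to a
    (phylum, genus) pair; missing entries default to "unclassified" at both
    ranks.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        for otu in self.otu_ids:
            self.taxonomy.setdefault(otu, ("unclassified", "unclassified"))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            counts=self.counts[keep, :].copy(),
            sample_ids=[self.sample_ids[i] for i in keep],
            otu_ids=list(self.otu_ids),
            taxonomy=dict(self.taxonomy),
        )

    def select_otus(self, keep: Sequence[int]) -> "OtuTable":
        keep = list(keep)
        otus = [self.otu_ids[j] for j in keep]
        return OtuTable(
            counts=self.counts[:, keep].copy(),
            sample_ids=list(self.sample_ids),
            otu_ids=otus,
            taxonomy={o: self.taxonomy[o] for o in otus},
        )


class PhyloTree:
    """Rooted tree with non-negative branch lengths; tips are OTU ids."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif not math.isfinite(edge.length) or edge.length < 0:
                raise ValueError(f"invalid branch length {edge.length}")
        if n_missing:
            warnings.warn(
                f"{n_missing} branches had no length; set to 0", stacklevel=2
            )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True)

    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def filter_low_count_otus(table: OtuTable, min_reads: int = 10) -> OtuTable:
    """Drop OTUs whose total count across all samples is below ``min_reads``.

    An OTU with exactly ``min_reads`` reads is kept ("fewer than 10 reads"
    rule).  ``min_reads = 0`` is the identity.
    """
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads}")
    keep = np.flatnonzero(table.otu_sums() >= min_reads)
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int = 41921, seed: int | None = None,
           rng: np.random.Generator | None = None) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Either an integer ``seed`` or an explicit ``rng`` must be supplied — the
    subsampling is random and silent global state is not allowed.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if rng is None:
        if seed is None:
            raise ValueError("rarefy requires an explicit seed (or rng)")
        rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep = np.flatnonzero(totals >= depth)
    dropped = [table.sample_ids[i] for i in np.flatnonzero(totals < depth)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth "
            f"{depth}: {dropped}", stacklevel=2,
        )
    if keep.size == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        out[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    sub.counts = out
    return sub


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness estimate."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of OTU richness.

    S_ace = S_abund + S_rare/C_ace + (F1/C_ace)·γ² with rare OTUs those at
    1..rare_threshold reads, C_ace = 1 − F1/N_rare the sample coverage of the
    rare group, and γ² a (non-negative) coefficient of variation term.  When
    every rare read is a singleton C_ace = 0 and the estimator is undefined;
    we then fall back to bias-corrected Chao1 with a warning.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("ace needs at least one positive count")
    rare = counts[counts <= rare_threshold]
    s_abund = int((counts > rare_threshold).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund)
    freq = np.bincount(rare.astype(np.int64), minlength=rare_threshold + 1)
    f1 = int(freq[1])
    n_rare = int(rare.sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "all rare reads are singletons (C_ace = 0); "
            "falling back to bias-corrected Chao1", stacklevel=2,
        )
        return chao1(counts)
    i = np.arange(1, rare_threshold + 1)
    if n_rare > 1:
        cv = (s_rare / c_ace) * float((i * (i - 1) * freq[1:]).sum()) / (
            n_rare * (n_rare - 1.0)) - 1.0
    else:
        cv = 0.0
    gamma_sq = max(cv, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq


@dataclass(frozen=True)
class AlphaRecord:
    """Alpha diversity of one sample."""

    observed: int
    singles: int
    ace: float
    shannon: float
    simpson: float


def alpha_diversity(counts: np.ndarray, shannon_base: float = 2.0,
                    simpson_variant: str = "one_minus_d",
                    ace_rare_threshold: int = 10) -> AlphaRecord:
    """Observed richness, singles, ACE, Shannon and Simpson of one sample.

    shannon = −Σ p_i log_base p_i over p_i > 0; Simpson's D = Σ p_i², reported
    as 1 − D (``simpson_variant`` may also be ``"d"`` or ``"inverse"``);
    singles counts OTUs seen exactly once in the sample.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("alpha diversity of an all-zero sample is undefined")
    positive = counts[counts > 0]
    p = positive / total
    shannon = float(-(p * (np.log(p) / np.log(shannon_base))).sum())
    d = float((p ** 2).sum())
    if simpson_variant == "one_minus_d":
        simpson = 1.0 - d
    elif simpson_variant == "d":
        simpson = d
    elif simpson_variant == "inverse":
        simpson = 1.0 / d
    else:
        raise ValueError(f"unknown simpson_variant {simpson_variant!r}")
    return AlphaRecord(
        observed=int(positive.size),
        singles=int((counts == 1).sum()),
        ace=float(ace(counts, rare_threshold=ace_rare_threshold)),
        shannon=shannon,
        simpson=simpson,
    )


def alpha_frame(table: OtuTable, **kwargs) -> pd.DataFrame:
    """Alpha diversity of every sample of a table, one row per sample."""
    rows = [vars(alpha_diversity(table.counts[i], **kwargs))
            for i in range(table.n_samples)]
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative distances")
        self.data = np.maximum((self.data + self.data.T) / 2.0, 0.0)
        np.fill_diagonal(self.data, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def _branch_profile(tree: PhyloTree, table: OtuTable
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch relative-abundance mass for every sample.

    Returns (lengths, P) where P[k, s] is the fraction of sample s's reads on
    tips descending through branch k.
    """
    tip_index = {}
    for j, otu in enumerate(table.otu_ids):
        tip_index[otu] = j
    present = np.flatnonzero(table.otu_sums() > 0)
    present_ids = {table.otu_ids[j] for j in present}
    tips_in_tree = set(tree.tip_names())
    missing = sorted(present_ids - tips_in_tree)
    if missing:
        raise ValueError(
            f"{len(missing)} OTU(s) with nonzero counts are missing from the "
            f"tree: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    totals = table.sample_sums().astype(float)
    if (totals == 0).any():
        raise ValueError("weighted UniFrac is undefined for empty samples")
    rel = table.counts / totals[:, None]          # samples x otus

    lengths: list[float] = []
    masses: list[np.ndarray] = []
    node_mass: dict[int, np.ndarray] = {}
    n_samples = table.n_samples
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            j = tip_index.get(label)
            mass = rel[:, j].copy() if j is not None else np.zeros(n_samples)
        else:
            mass = np.zeros(n_samples)
            for child in node.child_nodes():
                mass += node_mass.pop(id(child))
        node_mass[id(node)] = mass
        if node is not tree.tree.seed_node:
            lengths.append(float(node.edge.length or 0.0))
            masses.append(mass)
    return np.asarray(lengths), np.asarray(masses)


def weighted_unifrac(tree: PhyloTree, table: OtuTable,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac dissimilarity between every pair of samples.

    Raw form: d(A,B) = Σ_b len(b)·|p_A(b) − p_B(b)|.  With
    ``normalized=True`` each distance is divided by Σ_b len(b)·(p_A(b) +
    p_B(b)), bounding it in [0, 1].
    """
    lengths, masses = _branch_profile(tree, table)
    n = table.n_samples
    d = np.zeros((n, n))
    for a in range(n):
        diff = np.abs(masses[:, a, None] - masses[:, a + 1:])
        d[a, a + 1:] = lengths @ diff
        if normalized:
            denom = lengths @ (masses[:, a, None] + masses[:, a + 1:])
            with np.errstate(invalid="ignore", divide="ignore"):
                d[a, a + 1:] = np.where(denom > 0, d[a, a + 1:] / denom, 0.0)
    d = d + d.T
    return DistanceMatrix(data=d, ids=list(table.sample_ids))


@dataclass
class Ordination:
    """PCoA result: sample coordinates and % variation explained per axis."""

    coordinates: pd.DataFrame
    explained: np.ndarray
    n_negative_eigenvalues: int = 0


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Principal coordinate analysis by Gower double-centering.

    B = −½·J·D²·J with J the centering matrix; coordinates are eigenvectors
    scaled by √λ for positive eigenvalues, ordered by decreasing λ; the
    explained percentages use the positive eigenvalues only.  Negative
    eigenvalues (non-Euclidean input) are dropped and counted.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {n}")
    d2 = d.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    n_negative = int((eigvals < -tol).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam_axes = lam[:n_axes]
    else:
        lam_axes = lam
    explained = 100.0 * lam_axes / lam.sum() if lam.size else np.array([])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        explained=explained,
        n_negative_eigenvalues=n_negative,
    )


_RANK_INDEX = {"phylum": 0, "genus": 1}


def aggregate_taxa(table: OtuTable, rank: str) -> pd.DataFrame:
    """Relative abundance per taxon at ``rank`` ("phylum" or "genus").

    Rows (samples) sum to 1; columns are ordered by decreasing mean
    abundance across samples.
    """
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected 'phylum' or 'genus'")
    idx = _RANK_INDEX[rank]
    labels = [table.taxonomy[o][idx] for o in table.otu_ids]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=labels)
    agg = df.T.groupby(level=0).sum().T
    totals = agg.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot compute relative abundance for empty samples")
    rel = agg.div(totals, axis=0)
    return rel[rel.mean(axis=0).sort_values(ascending=False).index]
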