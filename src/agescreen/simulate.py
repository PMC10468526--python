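"""Synthetic hepatocyte scRNA-seq data with a planted senescent subpopulation.

The generator emulates two groups of albumin-positive hepatocytes (young and
old animals). Every cell draws its counts from the same zero-inflated-looking
negative-binomial model:

* per-gene relative abundance is lognormal across genes and normalised to
  sum to one,
* per-cell sequencing depth (library size) is lognormal across cells,
* the count of gene *g* in cell *c* is negative binomial with mean
  ``depth_c * abundance_g`` and a common dispersion.

A configurable fraction of cells in each group is flagged *senescent*; in
those cells the relative abundance of a small set of marker genes is
multiplied by ``marker_fold`` and the abundance vector renormalised, so that
depth is independent of senescence status. Marker genes get a deliberately
low baseline abundance (a low quantile of the gene pool) so that, like true
senescence markers, they are close to silent in normal hepatocytes. One
gene — the *gate gene*, standing in for albumin — is pinned to a high
abundance in every cell, and a small block of genes is flagged mitochondrial
and scaled to a realistic share of reads so the QC rules have something to
measure.

Ground truth (which cells are senescent, which genes are markers) is
returned alongside the count matrix so downstream screening can be scored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import ConfigurationError

__all__ = ["SimulationConfig", "SimTruth", "generate_annotation", "simulate_counts"]


def default_gene_ids(n_genes: int) -> list[str]:
    """Gene identifiers of the simulated universe: ``g00001`` .. ``g<N>``."""
    return [f"g{i + 1:05d}" for i in range(n_genes)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group hepatocyte simulation.

    Defaults reproduce the screen's reference conditions: 255 young and 1251 old cells, three planted markers, a
    rare senescent subpopulation in the young group (2%) that is common in
    the old group (35%), and an eight-fold marker induction in senescent
    cells. ``senescent_fraction_young <= senescent_fraction_old`` is *not*
    enforced: the age trend is the hypothesis the screen recovers, not an
    input constraint.
    """

    n_cells_young: int = 255
    n_cells_old: int = 1251
    n_genes: int = 2000
    n_mito_genes: int = 13
    marker_gene_ids: tuple[str, ...] = ("g00002", "g00003", "g00004")
    senescent_fraction_young: float = 0.02
    senescent_fraction_old: float = 0.35
    marker_fold: float = 8.0
    baseline_mean_log_mu: float = 0.0
    baseline_mean_log_sigma: float = 1.0
    libsize_log_mu: float = 9.9  # exp(9.9 + 0.35^2/2) ~ 2.1e4 reads/cell
    libsize_log_sigma: float = 0.35
    nb_dispersion: float = 10.0
    gate_gene_id: str = "g00001"
    seed: int = 0
    # fraction of non-marker, non-gate genes left without a mouse ortholog,
    # so the ortholog filter of the screen is exercised
    ortholog_missing_fraction: float = 0.10
    # baseline abundance of marker genes, as a quantile of the gene pool:
    # markers are nearly silent outside senescent cells
    marker_baseline_quantile: float = 0.01
    # share of total abundance carried by the mitochondrial gene block
    mito_share: float = 0.08

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid SimulationConfig.{name}: {why}")

        for name in ("n_cells_young", "n_cells_old", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise bad(name, "must be a positive count")
        if not 0 <= self.n_mito_genes < self.n_genes:
            raise bad("n_mito_genes", "must satisfy 0 <= n_mito_genes < n_genes")
        for name in (
            "senescent_fraction_young",
            "senescent_fraction_old",
            "ortholog_missing_fraction",
        ):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise bad(name, f"{v} is not a proportion in [0, 1]")
        if not self.marker_fold > 0:
            raise bad("marker_fold", "must be > 0")
        if not self.nb_dispersion > 0:
            raise bad("nb_dispersion", "must be > 0")
        if not 0.0 < self.marker_baseline_quantile < 1.0:
            raise bad("marker_baseline_quantile", "must be in (0, 1)")
        if not 0.0 <= self.mito_share < 1.0:
            raise bad("mito_share", "must be in [0, 1)")
        for name in ("baseline_mean_log_sigma", "libsize_log_sigma"):
            if float(getattr(self, name)) < 0:
                raise bad(name, "must be >= 0")

        universe = set(self.gene_ids)
        markers = tuple(self.marker_gene_ids)
        if len(set(markers)) != len(markers):
            raise bad("marker_gene_ids", "contains duplicates")
        missing = sorted(set(markers) - universe)
        if missing:
            raise bad("marker_gene_ids", f"not in the simulated gene universe: {missing}")
        if self.gate_gene_id not in universe:
            raise bad("gate_gene_id", "not in the simulated gene universe")
        if self.gate_gene_id in markers:
            raise bad("gate_gene_id", "must not be a marker gene")
        mito = set(self.mito_gene_ids)
        if self.gate_gene_id in mito:
            raise bad("gate_gene_id", "falls inside the mitochondrial gene block")
        clash = sorted(set(markers) & mito)
        if clash:
            raise bad("marker_gene_ids", f"fall inside the mitochondrial block: {clash}")
        object.__setattr__(self, "marker_gene_ids", markers)

    @property
    def gene_ids(self) -> list[str]:
        return default_gene_ids(self.n_genes)

    @property
    def mito_gene_ids(self) -> list[str]:
        """The mitochondrial block occupies the last ``n_mito_genes`` ids."""
        return self.gene_ids[self.n_genes - self.n_mito_genes :]

    @property
    def n_cells(self) -> int:
        return self.n_cells_young + self.n_cells_old

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_gene_ids"] = list(self.marker_gene_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown SimulationConfig fields: {unknown}")
        d = dict(d)
        if "marker_gene_ids" in d:
            d["marker_gene_ids"] = tuple(d["marker_gene_ids"])
        return cls(**d)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulation: cell labels and planted markers."""

    cells: pd.DataFrame  # columns: cell_id, group, senescent
    marker_gene_ids: tuple[str, ...]
    marker_fold: float

    @property
    def senescent_cell_ids(self) -> list[str]:
        return self.cells.loc[self.cells["senescent"], "cell_id"].tolist()

    def n_senescent(self, group: str) -> int:
        sub = self.cells[self.cells["group"] == group]
        return int(sub["senescent"].sum())


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Build the gene annotation table for a simulated universe.

    Returns one row per gene with columns ``gene_id``, ``symbol``,
    ``length_bp`` (uniform in [300, 10000] bp), ``is_mitochondrial`` and
    ``ortholog_symbol``. The gate gene is given the symbol ``Alb``;
    mitochondrial genes get an ``mt-`` prefix. A configurable fraction of
    genes is left without an ortholog symbol, but the gate and marker genes
    always carry one (real senescence markers were selected for having mouse
    orthologs, and the gate gene must survive every filter).

    Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    gene_ids = config.gene_ids
    mito = set(config.mito_gene_ids)

    symbols = []
    for i, gid in enumerate(gene_ids):
        if gid == config.gate_gene_id:
            symbols.append("Alb")
        elif gid in mito:
            symbols.append(f"mt-G{i + 1}")
        else:
            symbols.append(f"G{i + 1}")

    lengths = rng.integers(300, 10001, size=config.n_genes)
    no_orth = rng.random(config.n_genes) < config.ortholog_missing_fraction
    protected = set(config.marker_gene_ids) | {config.gate_gene_id}
    ortholog = [
        None if (no_orth[i] and gid not in protected) else symbols[i]
        for i, gid in enumerate(gene_ids)
    ]

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "length_bp": lengths.astype(np.int64),
            "is_mitochondrial": [gid in mito for gid in gene_ids],
            "ortholog_symbol": pd.array(ortholog, dtype="string"),
        }
    )


def _check_annotation(config: SimulationConfig, annotation: pd.DataFrame) -> None:
    if list(annotation["gene_id"]) != config.gene_ids:
        raise ConfigurationError(
            "annotation is inconsistent with the configuration: gene_id column "
            "does not match the simulated gene universe"
        )
    missing = [g for g in config.marker_gene_ids if g not in set(annotation["gene_id"])]
    if missing:
        raise ConfigurationError(f"marker gene ids absent from annotation: {missing}")


def simulate_counts(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[AnnData, SimTruth]:
    """Draw the two-group count matrix and its ground truth.

    A single pseudo-random stream is seeded once per call; gene-level draws
    (baseline abundances) precede all cell-level draws (senescence flags,
    library sizes, counts), so results do not depend on how cells might be
    chunked. Counts are returned as a cells x genes sparse integer matrix in
    an :class:`~anndata.AnnData` whose ``obs`` carries the group label and
    the (ground-truth) senescent flag and whose ``var`` is the annotation.
    """
    _check_annotation(config, annotation)
    rng = np.random.default_rng(int(config.seed))
    n_genes = config.n_genes
    gene_index = {g: i for i, g in enumerate(config.gene_ids)}
    marker_idx = np.array([gene_index[g] for g in config.marker_gene_ids], dtype=int)
    gate_idx = gene_index[config.gate_gene_id]
    mito_idx = np.array([gene_index[g] for g in config.mito_gene_ids], dtype=int)

    # gene-level draws
    abundance = rng.lognormal(
        config.baseline_mean_log_mu, config.baseline_mean_log_sigma, n_genes
    )
    # gate gene: forced high so virtually every cell is albumin-positive
    abundance[gate_idx] = np.quantile(abundance, 0.99)
    # markers: forced low so they are nearly silent outside senescent cells
    if marker_idx.size:
        abundance[marker_idx] = np.quantile(abundance, config.marker_baseline_quantile)
    # mitochondrial block rescaled to its configured share of total abundance
    if mito_idx.size and config.mito_share > 0:
        other = np.setdiff1d(np.arange(n_genes), mito_idx, assume_unique=False)
        target = config.mito_share / (1.0 - config.mito_share) * abundance[other].sum()
        abundance[mito_idx] *= target / abundance[mito_idx].sum()

    p_normal = abundance / abundance.sum()
    boosted = abundance.copy()
    boosted[marker_idx] *= config.marker_fold
    p_senescent = boosted / boosted.sum()  # renormalised: depth unconfounded

    # cell-level draws
    n_cells = config.n_cells
    groups = np.array(
        ["young"] * config.n_cells_young + ["old"] * config.n_cells_old, dtype=object
    )
    frac = np.where(
        groups == "young", config.senescent_fraction_young, config.senescent_fraction_old
    )
    senescent = rng.random(n_cells) < frac
    depth = rng.lognormal(config.libsize_log_mu, config.libsize_log_sigma, n_cells)

    mean = depth[:, None] * np.where(senescent[:, None], p_senescent, p_normal)
    theta = config.nb_dispersion
    # negative binomial via the gamma-Poisson mixture
    lam = rng.gamma(theta, mean / theta)
    counts = rng.poisson(lam).astype(np.int32)

    cell_ids = [f"young_{i + 1:05d}" for i in range(config.n_cells_young)] + [
        f"old_{i + 1:05d}" for i in range(config.n_cells_old)
    ]
    obs = pd.DataFrame(
        {"group": pd.Categorical(groups, categories=["young", "old"]), "senescent": senescent},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = annotation.set_index("gene_id", drop=False)
    var.index.name = None
    adata = AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["simulation"] = {
        "marker_gene_ids": list(config.marker_gene_ids),
        "marker_fold": float(config.marker_fold),
        "gate_gene_id": config.gate_gene_id,
        "seed": int(config.seed),
    }

    truth = SimTruth(
        cells=pd.DataFrame(
            {"cell_id": cell_ids, "group": groups, "senescent": senescent}
        ),
        marker_gene_ids=tuple(config.marker_gene_ids),
        marker_fold=float(config.marker_fold),
    )
    return adata, truth
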