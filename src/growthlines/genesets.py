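"""Marker-based cell filtering and binned-control gene-set module scores.

Works on an :class:`anndata.AnnData` of non-negative integer counts
(cells x genes) with per-cell metadata.  The filtering step keeps cells of
the paraventricular lineage: cells expressing Otp and/or Sim1 are retained,
neural progenitor cells (NPCs) lacking those markers are kept through an
explicit per-cell flag, and contaminating populations are removed by two
exclusion lists (any cell with >0 UMIs of an exclusion gene is dropped).
Retention and exclusion are combined as a conjunction, so their order does
not matter.

Module scores follow the binned-control construction: genes are ranked by
dataset-mean expression into equal-frequency bins; each set gene draws
control genes from its own bin; the score is the per-cell mean over the set
minus the mean over the pooled controls.  Scoring expects normalised data
(log1p counts-per-10k by default; the normalisation used is echoed in
outputs).  Control draws are seeded and never include set genes, so a
planted uniform shift of a set is recovered as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneSet",
    "PRESET_GENE_SETS",
    "FilterReport",
    "filter_cells",
    "normalize_log1p_cp10k",
    "module_score",
    "score_table",
    "ClusterSummary",
    "cluster_summary",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with its role in the pipeline."""

    name: str
    genes: tuple[str, ...]
    role: str  # retain | exclude_any_umi | exclude_expressing | score

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.role not in ("retain", "exclude_any_umi", "exclude_expressing", "score"):
            raise ValueError(f"unknown role {self.role!r}")


#: The preset marker and score lists for the paraventricular-lineage analysis.
PRESET_GENE_SETS: dict[str, GeneSet] = {
    gs.name: gs
    for gs in (
        GeneSet("retain", ("Otp", "Sim1"), "retain"),
        GeneSet("exclude_ventral", ("Foxa1", "Foxa2", "Pitx2", "Shh"), "exclude_any_umi"),
        GeneSet(
            "exclude_markers",
            ("Nr5a1", "Foxb1", "Tbr1", "Agrp", "Pomc"),
            "exclude_expressing",
        ),
        GeneSet("terminal", ("Fgf15", "Six3", "Zic1", "Zic5"), "score"),
        GeneSet("peduncular", ("Mfap4", "Lmo4", "Rgs4"), "score"),
        GeneSet("progenitor", ("Mki67", "Top2a", "Pcna"), "score"),
        GeneSet("neuronal", ("Neurod1", "Dcx", "Tubb3"), "score"),
    )
}


def _gene_indices(adata: ad.AnnData, genes: Sequence[str], context: str) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"{context}: genes not found (case-sensitive): {missing}")
    return np.asarray([lookup[g] for g in genes], dtype=np.intp)


def _column(adata: ad.AnnData, idx: np.ndarray) -> np.ndarray:
    x = adata.X[:, idx]
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_marker_positive: int  # Otp and/or Sim1
    n_npc_included: int  # NPCs lacking the retention markers
    n_removed_umi_exclusion: int  # of retained, removed by the >0 UMI list
    n_removed_marker_exclusion: int  # of the remainder, removed by the marker list
    n_retained: int


def filter_cells(
    adata: ad.AnnData,
    npc_mask: Optional[np.ndarray] = None,
    sets: Mapping[str, GeneSet] = PRESET_GENE_SETS,
) -> tuple[ad.AnnData, FilterReport]:
    """Apply the retention/exclusion rules; returns the kept cells + report.

    ``npc_mask`` defaults to the boolean ``obs["npc"]`` column when present,
    else all-False.  A cell is kept iff (retention marker > 0 or NPC flag)
    and no exclusion gene has a positive count.
    """
    retain = sets["retain"] if "retain" in sets else PRESET_GENE_SETS["retain"]
    excl_sets = [g for g in sets.values() if g.role.startswith("exclude")]
    if npc_mask is None:
        npc_mask = (
            adata.obs["npc"].to_numpy(dtype=bool)
            if "npc" in adata.obs
            else np.zeros(adata.n_obs, dtype=bool)
        )
    npc_mask = np.asarray(npc_mask, dtype=bool)
    if npc_mask.shape != (adata.n_obs,):
        raise ValueError("npc_mask must be one flag per cell")

    ridx = _gene_indices(adata, retain.genes, "retention")
    marker_pos = (_column(adata, ridx) > 0).any(axis=1)
    kept = marker_pos | npc_mask

    n_marker = int(marker_pos.sum())
    n_npc = int((npc_mask & ~marker_pos).sum())

    removed_counts = []
    current = kept.copy()
    for gs in excl_sets:
        eidx = _gene_indices(adata, gs.genes, f"exclusion set {gs.name!r}")
        hits = (_column(adata, eidx) > 0).any(axis=1)
        removed_counts.append(int((current & hits).sum()))
        current &= ~hits

    if not current.any():
        raise ValueError("all cells filtered out: no cell passes retention and exclusion")

    report = FilterReport(
        n_input=adata.n_obs,
        n_marker_positive=n_marker,
        n_npc_included=n_npc,
        n_removed_umi_exclusion=removed_counts[0] if removed_counts else 0,
        n_removed_marker_exclusion=removed_counts[1] if len(removed_counts) > 1 else 0,
        n_retained=int(current.sum()),
    )
    return adata[current].copy(), report


def normalize_log1p_cp10k(adata: ad.AnnData, layer: Optional[str] = None) -> ad.AnnData:
    """log1p of counts-per-10k; stores the result in ``layers["lognorm"]``."""
    x = adata.layers[layer] if layer else adata.X
    if sp.issparse(x):
        x = x.tocsr(copy=True).astype(float)
        totals = np.asarray(x.sum(axis=1)).ravel()
        totals[totals == 0] = 1.0
        scale = sp.diags(1e4 / totals)
        x = scale @ x
        x.data = np.log1p(x.data)
    else:
        x = np.asarray(x, dtype=float)
        totals = x.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        x = np.log1p(x / totals * 1e4)
    out = adata.copy()
    out.layers["lognorm"] = x
    out.uns["normalisation"] = "log1p(counts-per-10k)"
    return out


def module_score(
    adata: ad.AnnData,
    genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    rng_seed: int = 0,
    layer: str = "lognorm",
) -> np.ndarray:
    """Per-cell binned-control module score for one gene set.

    Genes are ranked by dataset-mean expression and cut into ``n_bins``
    equal-frequency bins; for each set gene, ``n_ctrl`` control genes are
    drawn (without replacement, seeded) from that gene's bin, excluding the
    set itself.  Score = per-cell mean over set genes minus mean over the
    pooled controls.  When a bin is smaller than ``n_ctrl`` the whole bin is
    used, with a warning.
    """
    if layer not in adata.layers:
        raise KeyError(
            f"layer {layer!r} not found: normalise first (normalize_log1p_cp10k)"
        )
    x = adata.layers[layer]
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    n_genes = adata.n_vars
    if n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, have {n_genes}")
    set_idx = _gene_indices(adata, genes, "score set")

    means = dense.mean(axis=0)
    order = np.argsort(means, kind="stable")
    rank = np.empty(n_genes, dtype=np.intp)
    rank[order] = np.arange(n_genes)
    bins = (rank * n_bins) // n_genes  # equal-frequency bins by mean expression

    rng = np.random.default_rng(rng_seed)
    set_set = set(set_idx.tolist())
    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = np.asarray([p for p in pool if p not in set_set], dtype=np.intp)
        if len(pool) == 0:
            warnings.warn(
                f"no control candidates in the expression bin of gene index {gi}; "
                "skipping controls for this gene"
            )
            continue
        k = n_ctrl
        if len(pool) < n_ctrl:
            warnings.warn(
                f"expression bin has only {len(pool)} candidate controls; "
                f"reducing n_ctrl from {n_ctrl}"
            )
            k = len(pool)
        ctrl.update(int(g) for g in rng.choice(pool, size=k, replace=False))
    if not ctrl:
        raise ValueError("no control genes could be drawn")
    ctrl_idx = np.asarray(sorted(ctrl), dtype=np.intp)
    return dense[:, set_idx].mean(axis=1) - dense[:, ctrl_idx].mean(axis=1)


def score_table(
    adata: ad.AnnData,
    sets: Mapping[str, GeneSet] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    rng_seed: int = 0,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Module scores for every ``role == "score"`` set; cells x sets."""
    sets = sets or PRESET_GENE_SETS
    cols = {}
    for name, gs in sets.items():
        if gs.role != "score":
            continue
        cols[name] = module_score(
            adata, gs.genes, n_bins=n_bins, n_ctrl=n_ctrl, rng_seed=rng_seed, layer=layer
        )
    return pd.DataFrame(cols, index=adata.obs_names)


@dataclass
class ClusterSummary:
    means: pd.DataFrame  # clusters x score sets
    top_cluster: dict[str, list]  # per score set: argmax cluster(s); ties listed

    def ranked(self, score: str) -> pd.Series:
        return self.means[score].sort_values(ascending=False)


def cluster_summary(scores: pd.DataFrame, clusters: Sequence) -> ClusterSummary:
    """Per-cluster mean of each score, and the top cluster per score.

    Ties for the top cluster are reported as a list, never silently broken.
    """
    clusters = pd.Series(list(clusters), index=scores.index, name="cluster")
    if clusters.isna().any():
        raise ValueError("every retained cell must carry a cluster label")
    means = scores.groupby(clusters, observed=True).mean()
    top: dict[str, list] = {}
    for col in scores.columns:
        m = means[col]
        top[col] = sorted(m.index[m == m.max()].tolist())
    return ClusterSummary(means=means, top_cluster=top)
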