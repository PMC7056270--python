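"""Proteome-structure analytics: mass-dominance ranking, gene-set mass
fractions, and clustered heatmap matrices.

A few hundred highly abundant proteins account for most cellular protein
mass; ranking proteins by mean mass per cell and accumulating their mass
fractions quantifies that dominance (e.g. the smallest set of proteins
covering 75% of cell mass).  Gene-set aggregation reports how much of the
proteome's mass a pathway occupies.  The heatmap matrix reproduces the
abundance-filtered, row-scaled, correlation-clustered expression profiles
used to visualise selective proteome remodelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_tables import samples_by_condition
from .ruler import CopyNumberResult

__all__ = [
    "MassRankProfile",
    "HeatmapMatrix",
    "mass_rank_profile",
    "pathway_mass_summary",
    "build_heatmap_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class MassRankProfile:
    """Proteins of one condition ranked by descending mean mass per cell.

    ``cumulative_mass_fraction[k]`` is the mass fraction covered by the
    top k+1 proteins; ``quartile_counts`` are the numbers of proteins
    needed to reach 25/50/75/100% of total mass (cumulative, so
    non-decreasing); ``top75_set`` is the smallest prefix covering 75%.
    """

    condition: str
    ranked_ids: list[str]
    cumulative_mass_fraction: np.ndarray
    quartile_counts: tuple[int, int, int, int]
    top75_set: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_ids) + 1),
                "group_id": self.ranked_ids,
                "cumulative_mass_fraction": self.cumulative_mass_fraction,
                "condition": self.condition,
            }
        )


@dataclass
class HeatmapMatrix:
    """Row-scaled abundance matrix with clustering orders.

    ``values``: proteins x condition means, each row min-max scaled to
    [0, 1] (constant rows mapped to 0.5).  ``row_order`` is the leaf order
    of average-linkage hierarchical clustering under 1 - Pearson
    correlation distance (constant rows appended last); ``col_order``
    follows the design.
    """

    values: pd.DataFrame
    row_order: list[str]
    col_order: list[str]

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.row_order, self.col_order]


def _smallest_prefix(cum: np.ndarray, q: float, atol: float = 1e-12) -> int:
    """Smallest k with cum[k-1] >= q (1-based count)."""
    return int(np.searchsorted(cum, q - atol, side="left")) + 1


def mass_rank_profile(result: CopyNumberResult, condition: str) -> MassRankProfile:
    """Rank proteins of one condition by mean mass contribution.

    Sorting is by descending condition-mean mass per cell (replicate mean,
    zeros included), stable with ties broken by ``group_id``.  Raises
    ``ValueError`` when the condition carries no mass.
    """
    mean_mass = result.mean_mass()
    if condition not in mean_mass.columns:
        raise KeyError(f"condition {condition!r} not present")
    m = mean_mass[condition]
    total = float(m.sum())
    if not total > 0:
        raise ValueError(f"all masses are zero in condition {condition!r}")
    order = m.to_frame("mass").reset_index(names="group_id")
    order = order.sort_values(["mass", "group_id"], ascending=[False, True], kind="stable")
    cum = np.cumsum(order["mass"].to_numpy()) / total
    counts = tuple(_smallest_prefix(cum, q) for q in (0.25, 0.50, 0.75, 1.00))
    ids = order["group_id"].astype(str).tolist()
    return MassRankProfile(
        condition=condition,
        ranked_ids=ids,
        cumulative_mass_fraction=cum,
        quartile_counts=counts,
        top75_set=frozenset(ids[: counts[2]]),
    )


def pathway_mass_summary(
    result: CopyNumberResult, gene_set, design: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Mass carried by a gene set, per condition.

    Gene names are matched case-insensitively.  Returns a summary frame
    indexed by condition with columns ``mass_ug_per_million_cells`` and
    ``percent_of_total_mass``, plus the list of unmatched set members.  An
    empty intersection is a warning and a zero summary, not an error.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    wanted = {g.lower() for g in gene_set}
    genes = result.gene_name.fillna("").astype(str).str.lower()
    in_set = genes.isin(wanted)
    unmatched = sorted(wanted - set(genes[in_set]))
    if not in_set.any():
        warnings.warn("no proteins matched the gene set", stacklevel=2)

    mean_mass = result.mean_mass()
    set_mass = mean_mass.loc[in_set.to_numpy()].sum(axis=0)
    total_mass = mean_mass.sum(axis=0)
    summary = pd.DataFrame(
        {
            "mass_ug_per_million_cells": set_mass * 1e12,
            "percent_of_total_mass": np.where(
                total_mass > 0, 100.0 * set_mass / total_mass, 0.0
            ),
        }
    )
    summary.index.name = "condition"
    return summary, unmatched


def build_heatmap_matrix(
    result: CopyNumberResult,
    design: pd.DataFrame | None = None,
    min_mean_copies: float = 500.0,
    min_reps: int = 2,
    reference_celltype: str = "CD8",
) -> HeatmapMatrix:
    """Filtered, row-scaled, correlation-clustered condition-mean matrix.

    A protein is included iff, within the reference cell type's conditions,
    some condition has a mean of at least ``min_mean_copies`` copies per
    cell and some condition has detected intensity in at least ``min_reps``
    replicates.  Rows (condition-mean copies) are min-max scaled to [0, 1];
    rows ordered by average-linkage agglomerative clustering with
    1 - Pearson correlation distance and deterministic tie-break by
    ``group_id``; constant rows (Pearson undefined) are mapped to 0.5 and
    appended last.  Columns keep the design's condition order.
    """
    design = design if design is not None else result.design
    conditions = list(dict.fromkeys(samples_by_condition(design)))
    ref_conds = [
        c for c, ct in zip(
            conditions, (c.split(".")[1] for c in conditions)
        ) if ct == reference_celltype
    ]
    if not ref_conds:
        raise KeyError(f"no conditions with cell type {reference_celltype!r} in design")

    mean_copies = result.mean_copies[conditions]
    det_reps = result.detected_replicates()[ref_conds]
    keep = (mean_copies[ref_conds].max(axis=1) >= min_mean_copies) & (
        det_reps.max(axis=1) >= min_reps
    )
    if not keep.any():
        raise ValueError(
            f"no proteins pass the heatmap thresholds "
            f"(>= {min_mean_copies} mean copies and >= {min_reps} detected "
            f"replicates in a {reference_celltype} condition)"
        )
    mat = mean_copies.loc[keep].sort_index()  # deterministic base order

    lo = mat.min(axis=1)
    rng = mat.max(axis=1) - lo
    constant = rng <= 0
    scaled = mat.sub(lo, axis=0).div(rng.where(~constant, 1.0), axis=0)
    scaled.loc[constant, :] = 0.5

    variable_ids = scaled.index[~constant].tolist()
    if len(variable_ids) >= 2:
        x = scaled.loc[variable_ids].to_numpy()
        d = pdist(x, metric="correlation")
        z = hierarchy.linkage(d, method="average")
        leaf_order = [variable_ids[i] for i in hierarchy.leaves_list(z)]
    else:
        leaf_order = variable_ids
    row_order = leaf_order + scaled.index[constant].tolist()
    log.info(
        "heatmap: %d proteins (%d constant rows appended last), %d conditions",
        len(scaled), int(constant.sum()), len(conditions),
    )
    return HeatmapMatrix(values=scaled, row_order=row_order, col_order=conditions)
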