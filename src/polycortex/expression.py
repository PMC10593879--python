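"""Area-level neuropil-related expression scores and their alignment with
effect maps.

Two scoring routes cover the six neuropil components. Glial cell types
(astrocytes, microglia, oligodendrocytes) are scored by weighting every
gene's expression with its single-cell specificity for that type:
score(area, specimen) = sum_g w_g x_gas / sum_g w_g, then an unweighted
mean across specimens. Neuron compartments (axons, dendritic trees,
neuron-to-neuron synapses) are scored as the plain mean expression of their
gene-ontology marker genes per (area, specimen), again averaged across
specimens — the same computation with indicator weights.

Expression is assumed pre-normalized on a log scale; no further
normalization is applied. Scores per area are then correlated with
area-averaged effect-map statistics, with significance from random
reassignment permutations (the areas carry no spherical geometry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import reassignment_test_correlation
from .surfaces import SurfaceMesh, map_areas_to_parcels, map_values, parcellate

logger = logging.getLogger("polycortex")


class ExpressionError(ValueError):
    pass


@dataclass
class MarkerSet:
    """Marker genes of one neuron compartment."""

    component: str
    genes: list

    def __post_init__(self):
        if not self.genes:
            raise ExpressionError("marker set is empty")


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene", "area", "specimen", "value"):
        if col not in panel.columns:
            raise ExpressionError(f"panel lacks column '{col}'")
    return panel


def score_celltype(panel: pd.DataFrame, weights: pd.DataFrame,
                   cell_type: str) -> pd.Series:
    """Specificity-weighted mean expression per area for one cell type.

    Genes in the weight table but absent from the panel are dropped with a
    logged count, never imputed. Raises if the total weight of matched genes
    is zero.
    """
    _check_panel(panel)
    w = weights.loc[weights["cell_type"] == cell_type, ["gene", "specificity"]]
    if w.empty:
        raise ExpressionError(f"no weights for cell type '{cell_type}'")
    if (w["specificity"] < 0).any():
        raise ExpressionError("specificity weights must be nonnegative")
    present = set(panel["gene"].unique())
    missing = (~w["gene"].isin(present)).sum()
    if missing:
        logger.warning("%d/%d weighted genes absent from panel (%s)",
                       missing, len(w), cell_type)
    merged = panel.merge(w, on="gene", how="inner")
    if merged.empty or merged["specificity"].sum() == 0:
        raise ExpressionError(f"zero total weight for '{cell_type}'")

    def wmean(g):
        return np.average(g["value"], weights=g["specificity"])

    per_cell = merged.groupby(["area", "specimen"], sort=True).apply(
        wmean, include_groups=False)
    return per_cell.groupby("area", sort=True).mean().rename(cell_type)


def score_compartment(panel: pd.DataFrame, markers) -> pd.Series:
    """Mean expression of a compartment's marker genes per area.

    Equivalent to :func:`score_celltype` with indicator weights on the
    marker set.
    """
    _check_panel(panel)
    if isinstance(markers, MarkerSet):
        name, genes = markers.component, list(markers.genes)
    else:
        name, genes = "compartment", list(markers)
    if not genes:
        raise ExpressionError("marker set is empty")
    present = set(panel["gene"].unique())
    found = [g for g in genes if g in present]
    if not found:
        raise ExpressionError(f"no marker genes of '{name}' found in panel")
    if len(found) < len(genes):
        logger.warning("%d/%d marker genes absent from panel (%s)",
                       len(genes) - len(found), len(genes), name)
    sub = panel[panel["gene"].isin(found)]
    per = sub.groupby(["area", "specimen"], sort=True)["value"].mean()
    return per.groupby("area", sort=True).mean().rename(name)


def score_all_components(panel: pd.DataFrame, weights: pd.DataFrame,
                         markers: dict) -> pd.DataFrame:
    """Area x component score table (cell types then compartments)."""
    cols = {}
    for ct in sorted(weights["cell_type"].unique()):
        cols[ct] = score_celltype(panel, weights, ct)
    for comp, genes in markers.items():
        cols[comp] = score_compartment(panel, MarkerSet(comp, list(genes)))
    return pd.DataFrame(cols)


def area_effect_values(tmap, fine_labels, mesh: SurfaceMesh,
                       area_centroids=None, area_assignment=None,
                       stat: str = "mean"):
    """Area-averaged effect statistics via assigned fine parcels.

    Either a ready area -> parcel-id assignment (array, one id per area) or
    area centroids on the registration sphere (assigned by nearest parcel
    centroid) must be given. Returns the per-area values aligned to the
    area order.
    """
    if area_assignment is None:
        if area_centroids is None:
            raise ExpressionError("need area_assignment or area_centroids")
        area_assignment = map_areas_to_parcels(area_centroids, fine_labels,
                                               mesh)
    ids, vals = parcellate(map_values(tmap), fine_labels, stat=stat)
    lut = dict(zip(ids.tolist(), vals.tolist()))
    out = np.array([lut.get(int(pid), np.nan) for pid in area_assignment])
    return out, np.asarray(area_assignment, int)


def correlate_expression_with_effect(scores: pd.DataFrame, tmap,
                                     fine_labels, mesh: SurfaceMesh,
                                     area_centroids=None,
                                     area_assignment=None,
                                     n_perm: int = 10_000,
                                     seed: int | None = None):
    """Correlate each component's area score with area-averaged effects.

    Pearson r per component with two-tailed random-reassignment p. The
    ``scores`` index must be the area labels, in the same order as
    ``area_centroids`` / ``area_assignment``.

    Returns (table, nulls): DataFrame (component, r, p_perm, n_areas) and
    {component: NullResult}.
    """
    eff, assignment = area_effect_values(tmap, fine_labels, mesh,
                                         area_centroids=area_centroids,
                                         area_assignment=area_assignment)
    if not np.isfinite(eff).all():
        raise ExpressionError("NaN area-level effect values")
    if np.ptp(eff) == 0:
        raise ExpressionError("constant effect map: correlation undefined")
    rng = np.random.default_rng(seed)
    rows, nulls = [], {}
    for comp in scores.columns:
        s = scores[comp].to_numpy(float)
        res = reassignment_test_correlation(
            s, eff, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        nulls[comp] = res
        rows.append({"component": comp, "r": res.observed,
                     "p_perm": res.p, "n_areas": len(s)})
    return pd.DataFrame(rows), nulls
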