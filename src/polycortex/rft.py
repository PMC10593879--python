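"""Random-field-theory cluster-level correction on triangulated surfaces.

The chain is the classical one for t statistic fields: (1) estimate the
global smoothness (FWHM) of the normalized GLM residuals from the variance
of their differences along mesh edges, (2) convert the search region to
resolution elements (resels), (3) extract edge-connected suprathreshold
clusters at a primary threshold, and (4) assign each cluster a family-wise
corrected p-value from the expected Euler characteristic of the t field
combined with a Poisson clumping model for cluster extent.

Smoothness is treated as global (stationary); hemispheres form one search
region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .surfaces import SurfaceMesh, map_values

logger = logging.getLogger("polycortex")

#: lower clip of the edgewise autocorrelation estimate; fields rougher than
#: this are at the mesh resolution limit anyway
_RHO_FLOOR = 1e-3


class RFTError(ValueError):
    pass


@dataclass
class SmoothnessEstimate:
    """Global residual smoothness and the resel counts of the search region.

    resel_counts = (R0, R1, R2): Euler characteristic of the search region,
    boundary perimeter / (2 * FWHM), and area / FWHM^2.
    """

    fwhm: float
    total_resels: float
    resel_counts: tuple
    resels_per_face: np.ndarray | None = None
    n_maps: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.fwhm) and self.fwhm > 0):
            raise RFTError("fwhm must be positive")


def estimate_fwhm(resid_maps, mesh: SurfaceMesh) -> SmoothnessEstimate:
    """Estimate global FWHM from normalized residual gradients along edges.

    Residual maps (k >= 2, per subject) are scaled to unit sum of squares at
    each vertex; for an edge of length l the expected squared difference of
    the normalized field is 2(1 - rho(l)). Inverting the Gaussian
    autocorrelation model rho(l) = exp(-l^2 * lambda / 2) gives the
    roughness lambda = Var(du/dx) per edge, pooled over edges, and
    FWHM = sqrt(4 ln 2 / lambda).
    """
    U = np.asarray(resid_maps, float)
    if U.ndim != 2 or U.shape[0] < 2:
        raise RFTError("need >= 2 residual maps")
    if U.shape[1] != mesh.n_vertices:
        raise RFTError("residual maps not aligned to mesh")

    valid = np.isfinite(U).all(axis=0)
    if valid.sum() < 3:
        raise RFTError("too few valid vertices")
    norms = np.sqrt(np.einsum("ij,ij->j", U[:, valid], U[:, valid]))
    if (norms == 0).any():
        raise RFTError("constant (zero-variance) residuals: "
                       "smoothness undefined")
    Un = np.full_like(U, np.nan)
    Un[:, valid] = U[:, valid] / norms

    e = mesh.edges
    keep = valid[e[:, 0]] & valid[e[:, 1]]
    if keep.sum() == 0:
        raise RFTError("no valid edges")
    d = Un[:, e[keep, 0]] - Un[:, e[keep, 1]]
    s = np.einsum("ij,ij->j", d, d)            # ~ 2(1 - rho)
    rho = np.clip(1.0 - 0.5 * s, _RHO_FLOOR, 1.0 - 1e-12)
    lam = -2.0 * np.log(rho) / mesh.edge_lengths[keep] ** 2
    lam_bar = float(lam.mean())
    fwhm = float(np.sqrt(4.0 * np.log(2.0) / lam_bar))

    r0, r1, r2, rpf = _resel_counts(mesh, valid, fwhm)
    return SmoothnessEstimate(fwhm=fwhm, total_resels=r2,
                              resel_counts=(r0, r1, r2),
                              resels_per_face=rpf, n_maps=U.shape[0])


def _resel_counts(mesh: SurfaceMesh, valid: np.ndarray, fwhm: float):
    """Resel counts of the subcomplex spanned by fully-valid faces."""
    f = mesh.faces
    finc = valid[f].all(axis=1)
    areas = mesh.face_areas[finc]
    area = float(areas.sum())

    # edges of included faces, with multiplicity
    fe = np.vstack([f[finc][:, [0, 1]], f[finc][:, [1, 2]], f[finc][:, [2, 0]]])
    fe = np.sort(fe, axis=1)
    edges, counts = np.unique(fe, axis=0, return_counts=True)
    vinc = np.unique(f[finc].ravel())
    r0 = float(len(vinc) - len(edges) + int(finc.sum()))

    boundary = counts == 1
    perim = float(np.linalg.norm(mesh.vertices[edges[boundary, 0]]
                                 - mesh.vertices[edges[boundary, 1]],
                                 axis=1).sum())
    r1 = perim / (2.0 * fwhm)
    r2 = area / fwhm ** 2
    rpf = np.zeros(mesh.n_faces)
    rpf[finc] = mesh.face_areas[finc] / fwhm ** 2
    return r0, r1, r2, rpf


# ---------------------------------------------------------------------------
# Euler characteristic densities of a t field (resel units)
# ---------------------------------------------------------------------------

def ec_density_t(t: float, df: float, dim: int) -> float:
    """EC density of a t field with ``df`` degrees of freedom, dimension 0-2."""
    t = float(t)
    nu = float(df)
    if dim == 0:
        return float(t_dist.sf(t, nu))
    core = (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    if dim == 1:
        return float(np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi) * core)
    if dim == 2:
        lg = np.exp(gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0))
        return float(4.0 * np.log(2.0) / (2.0 * np.pi) ** 1.5
                     * lg / np.sqrt(nu / 2.0) * t * core)
    raise ValueError("dim must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# Cluster extraction and inference
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Suprathreshold clusters of a t map.

    ``vertex_labels`` assigns each vertex its cluster id (0 = subthreshold);
    ``table`` has one row per cluster (id, sign, n_vertices, area_mm2, peak
    t, peak vertex, and — after :func:`cluster_pvalues` — extent_resels,
    p_cluster and the significance flag at ``alpha``).
    """

    vertex_labels: np.ndarray
    table: pd.DataFrame
    primary_threshold: float
    sign: str
    alpha: float = 0.01
    smoothness: SmoothnessEstimate | None = None
    df: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def significant_mask(self) -> np.ndarray:
        """Boolean per-vertex mask of vertices in significant clusters."""
        if "significant" not in self.table.columns:
            raise RFTError("run cluster_pvalues first")
        ids = set(self.table.loc[self.table["significant"], "cluster_id"])
        return np.isin(self.vertex_labels, list(ids)) & (self.vertex_labels > 0)


def extract_clusters(tmap, mesh: SurfaceMesh, primary_threshold: float,
                     sign: str = "positive") -> ClusterResult:
    """Edge-connected components of suprathreshold vertices.

    NaN vertices (medial wall) are never cluster members. ``sign`` is
    "positive" (t >= thr), "negative" (t <= -thr) or "two_sided" (each sign
    processed separately; cluster ids are unique across signs).
    """
    t = map_values(tmap)
    if t.shape != (mesh.n_vertices,):
        raise RFTError("t map not aligned to mesh")
    if sign not in ("positive", "negative", "two_sided"):
        raise ValueError("sign must be positive, negative or two_sided")

    labels = np.zeros(mesh.n_vertices, dtype=int)
    rows = []
    next_id = 1
    signs = {"positive": ["positive"], "negative": ["negative"],
             "two_sided": ["positive", "negative"]}[sign]
    for sgn in signs:
        with np.errstate(invalid="ignore"):
            mask = (t >= primary_threshold) if sgn == "positive" \
                else (t <= -primary_threshold)
        mask &= np.isfinite(t)
        idx = np.where(mask)[0]
        if len(idx) == 0:
            continue
        sub = mesh.adjacency[idx][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[comp == c]
            tv = t[members]
            peak_loc = members[np.argmax(tv)] if sgn == "positive" \
                else members[np.argmin(tv)]
            labels[members] = next_id
            rows.append({"cluster_id": next_id, "sign": sgn,
                         "n_vertices": len(members),
                         "area_mm2": float(mesh.vertex_areas[members].sum()),
                         "peak_t": float(t[peak_loc]),
                         "peak_vertex": int(peak_loc)})
            next_id += 1
    cols = ["cluster_id", "sign", "n_vertices", "area_mm2",
            "peak_t", "peak_vertex"]
    table = pd.DataFrame(rows, columns=cols)
    return ClusterResult(vertex_labels=labels, table=table,
                         primary_threshold=float(primary_threshold),
                         sign=sign)


def expected_clusters(smoothness: SmoothnessEstimate, df: float,
                      threshold: float, two_sided: bool = False):
    """(E[number of clusters], E[suprathreshold resels]) at the threshold."""
    r0, r1, r2 = smoothness.resel_counts
    em = (r0 * ec_density_t(threshold, df, 0)
          + r1 * ec_density_t(threshold, df, 1)
          + r2 * ec_density_t(threshold, df, 2))
    en = r2 * float(t_dist.sf(threshold, df))
    if two_sided:
        em, en = 2.0 * em, 2.0 * en
    return max(em, 1e-12), max(en, 1e-300)


def cluster_pvalues(clusters: ClusterResult, smoothness: SmoothnessEstimate,
                    df: float, alpha: float = 0.01) -> ClusterResult:
    """Family-wise corrected cluster p-values (Poisson clumping model).

    With m ~ Poisson(E[m]) clusters whose resel extents are exponential with
    mean E[N]/E[m], the corrected p of a cluster of extent k resels is
    1 - exp(-E[m] * exp(-k * E[m]/E[N])). Monotone decreasing in extent;
    tends to the probability of observing any cluster as extent -> 0 and to
    0 as extent -> infinity.
    """
    if clusters.primary_threshold < 2.0:
        logger.warning("primary threshold %.2f is low for random field "
                       "theory; cluster p-values may be inaccurate",
                       clusters.primary_threshold)
    em, en = expected_clusters(smoothness, df, clusters.primary_threshold,
                               two_sided=clusters.sign == "two_sided")
    table = clusters.table.copy()
    k = table["area_mm2"].to_numpy(float) / smoothness.fwhm ** 2
    beta = em / en
    p = 1.0 - np.exp(-em * np.exp(-beta * k))
    table["extent_resels"] = k
    table["p_cluster"] = np.clip(p, np.finfo(float).tiny, 1.0)
    table["significant"] = table["p_cluster"] <= alpha
    return replace(clusters, table=table, alpha=float(alpha),
                   smoothness=smoothness, df=float(df))


def primary_threshold_from_p(p: float, df: float) -> float:
    """One-sided t quantile for a vertexwise primary p (e.g. 0.001)."""
    if not 0.0 < p < 1.0:
        raise ValueError("primary p must be in (0, 1)")
    return float(t_dist.isf(p, df))
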