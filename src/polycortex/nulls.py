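"""Null models for spatially autocorrelated cortical maps.

Two families of permutation null are provided. Spin permutations draw
uniform random 3D rotations (normalized quaternions, exact Haar measure),
rotate a map on its registration sphere — mirroring the rotation across the
midline for the contralateral hemisphere — and resample it by nearest
original vertex, preserving the map's spatial autocorrelation while
randomizing its alignment with anything compared against it. Random
reassignment permutations shuffle labels uniformly and are appropriate when
no spherical geometry exists (e.g. the 11 expression areas).

All p-values use the add-one rule p = (1 + #{|null| >= |obs|}) / (n_perm + 1)
(two-tailed), so p is never exactly zero. Everything is seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .surfaces import SurfaceMesh, map_values

logger = logging.getLogger("polycortex")

DEFAULT_N_PERM = 10_000


class NullModelError(ValueError):
    pass


@dataclass
class NullResult:
    """Observed statistic, permutation null sample, and permutation p."""

    observed: float
    null_sample: np.ndarray
    n_perm: int
    tails: str = "two"
    seed: int | None = None
    p: float = field(init=False)

    def __post_init__(self):
        self.null_sample = np.asarray(self.null_sample, float)
        self.p = permutation_pvalue(self.observed, self.null_sample,
                                    tails=self.tails)

    def summary(self) -> dict:
        q = np.nanpercentile(self.null_sample, [2.5, 50.0, 97.5])
        return {"observed": float(self.observed), "p": float(self.p),
                "n_perm": int(self.n_perm), "tails": self.tails,
                "seed": self.seed,
                "null_q025": float(q[0]), "null_median": float(q[1]),
                "null_q975": float(q[2])}


def permutation_pvalue(observed, null_sample, tails: str = "two") -> float:
    """Add-one permutation p-value; NaN permutations count as non-exceeding."""
    null = np.asarray(null_sample, float)
    n = len(null)
    if not np.isfinite(observed):
        raise NullModelError("observed statistic is not finite")
    if tails == "two":
        exceed = np.sum(np.abs(null[np.isfinite(null)]) >= abs(observed))
    elif tails == "one":
        exceed = np.sum(null[np.isfinite(null)] >= observed)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float((1 + exceed) / (n + 1))


# ---------------------------------------------------------------------------
# Rotations and spin resampling
# ---------------------------------------------------------------------------

def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def spin_indices(coords, hemispheres, n_perm: int,
                 seed: int | None = None) -> np.ndarray:
    """Source-vertex indices for each spin permutation, (n_perm, N) int32.

    Row k of the output maps target position i to the original point nearest
    to R_k^{-1} x_i, i.e. each point takes the value of the nearest original
    point on the rotated sphere. The left-hemisphere rotation is mirrored
    across the x = 0 plane for the right hemisphere, preserving bilateral
    symmetry. Nearest-neighbor ties resolve to the lowest index
    (deterministic).
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise NullModelError("sphere coordinates must be (N, 3)")
    hemispheres = np.asarray(hemispheres)
    rng = np.random.default_rng(seed)
    rots = random_rotations(n_perm, rng)
    out = np.empty((n_perm, len(coords)), dtype=np.int32)
    for h in np.unique(hemispheres):
        sel = np.where(hemispheres == h)[0]
        tree = cKDTree(coords[sel])
        for k in range(n_perm):
            R = rots[k] if h == "L" else _MIRROR @ rots[k] @ _MIRROR
            # R^T x_i for row-vector stacking is coords @ R
            _, j = tree.query(coords[sel] @ R)
            out[k, sel] = sel[j]
    return out


def spin_vertex(vmap, mesh: SurfaceMesh, n_perm: int = DEFAULT_N_PERM,
                seed: int | None = None) -> np.ndarray:
    """Stack of spun vertex maps, (n_perm, V). NaN travels with the spin."""
    if mesh.sphere_coords is None:
        raise NullModelError("mesh has no sphere coordinates")
    x = map_values(vmap)
    idx = spin_indices(mesh.sphere_coords, mesh.hemisphere, n_perm, seed)
    return x[idx]


def spin_parcel(pmap, centroids, n_perm: int = DEFAULT_N_PERM,
                seed: int | None = None, hemispheres=None) -> np.ndarray:
    """Stack of spun parcel maps, (n_perm, P), via rotated parcel centroids."""
    x = map_values(pmap)
    centroids = np.asarray(centroids, float)
    if len(centroids) < 3:
        raise NullModelError("need >= 3 parcels to spin")
    if len(x) != len(centroids):
        raise NullModelError("one centroid per parcel required")
    if hemispheres is None:
        hemispheres = np.where(centroids[:, 0] < 0, "L", "R")
    idx = spin_indices(centroids, hemispheres, n_perm, seed)
    return x[idx]


# ---------------------------------------------------------------------------
# Correlation tests
# ---------------------------------------------------------------------------

def _pearson_pairwise(x, y):
    """Pearson r over pairwise-complete entries; NaN if degenerate."""
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 3:
        return np.nan
    xs, ys = x[m], y[m]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    den = np.sqrt((xs @ xs) * (ys @ ys))
    if den == 0:
        return np.nan
    return float(xs @ ys / den)


def spin_test_correlation(x, y, centroids=None, n_perm: int = DEFAULT_N_PERM,
                          seed: int | None = None,
                          hemispheres=None) -> NullResult:
    """Spin test of the Pearson correlation between two parcel maps.

    The observed r uses pairwise-complete parcels; the null correlates the
    spun x with the fixed y, excluding NaN parcels pairwise after each spin.
    Two-tailed add-one p.
    """
    xv, yv = map_values(x), map_values(y)
    if centroids is None and hasattr(x, "centroids"):
        centroids = x.centroids
    if centroids is None:
        raise NullModelError("parcel centroids are required for a spin test")
    obs = _pearson_pairwise(xv, yv)
    if not np.isfinite(obs):
        raise NullModelError("zero variance or too few complete parcels")
    stack = spin_parcel(xv, centroids, n_perm=n_perm, seed=seed,
                        hemispheres=hemispheres)
    null = np.array([_pearson_pairwise(stack[k], yv) for k in range(n_perm)])
    return NullResult(observed=obs, null_sample=null, n_perm=n_perm,
                      tails="two", seed=seed)


def reassignment_test_correlation(x, y, n_perm: int = DEFAULT_N_PERM,
                                  seed: int | None = None) -> NullResult:
    """Random-reassignment permutation test of Pearson r (two-tailed).

    Used where no spherical geometry is available (e.g. area-level
    expression scores): the entries of x are uniformly permuted.
    """
    xv = np.asarray(map_values(x), float)
    yv = np.asarray(map_values(y), float)
    if xv.shape != yv.shape or xv.ndim != 1 or len(xv) < 3:
        raise NullModelError("x and y must be equal-length vectors, n >= 3")
    obs = _pearson_pairwise(xv, yv)
    if not np.isfinite(obs):
        raise NullModelError("zero variance in x or y")
    rng = np.random.default_rng(seed)
    null = np.array([_pearson_pairwise(xv[rng.permutation(len(xv))], yv)
                     for _ in range(n_perm)])
    return NullResult(observed=obs, null_sample=null, n_perm=n_perm,
                      tails="two", seed=seed)


# ---------------------------------------------------------------------------
# Class enrichment
# ---------------------------------------------------------------------------

def class_enrichment(tmap, class_labels, mesh: SurfaceMesh,
                     class_names: dict | None = None, stat: str = "median",
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None):
    """Within-class statistic of a t map against spin nulls.

    For every class (cytoarchitectural type or functional network), the
    observed within-class median (or mean) of the map is compared with the
    same statistic computed on spun maps against the fixed labels. Reports
    the observed statistic, the within-class SD, and a two-tailed add-one p
    per class; no cross-class multiplicity correction is applied.

    Returns (table, nulls): a DataFrame and {class_id: NullResult}.
    """
    t = map_values(tmap)
    labels = np.asarray(class_labels)
    if labels.shape != t.shape:
        raise NullModelError("labels not aligned to map")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    agg = np.nanmedian if stat == "median" else np.nanmean

    ids = np.unique(labels[labels > 0])
    for cid in ids:
        if not np.isfinite(t[labels == cid]).any():
            raise NullModelError(f"class {cid} has no finite vertices")

    idx = spin_indices(mesh.sphere_coords, mesh.hemisphere, n_perm, seed)
    spun = t[idx]  # (n_perm, V)
    rows, nulls = [], {}
    for cid in ids:
        sel = labels == cid
        obs = float(agg(t[sel]))
        null = agg(spun[:, sel], axis=1)
        res = NullResult(observed=obs, null_sample=null, n_perm=n_perm,
                         tails="two", seed=seed)
        nulls[int(cid)] = res
        rows.append({
            "class_id": int(cid),
            "class_name": (class_names or {}).get(cid, str(cid)),
            "n_vertices": int(np.isfinite(t[sel]).sum()),
            stat: obs,
            "sd": float(np.nanstd(t[sel], ddof=0)),
            "p_spin": res.p,
        })
    return pd.DataFrame(rows), nulls


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def edge_moran(vmap, mesh: SurfaceMesh) -> float:
    """Moran-type spatial autocorrelation: Pearson r of values across edges."""
    x = map_values(vmap)
    e = mesh.edges
    keep = np.isfinite(x[e[:, 0]]) & np.isfinite(x[e[:, 1]])
    a = np.concatenate([x[e[keep, 0]], x[e[keep, 1]]])
    b = np.concatenate([x[e[keep, 1]], x[e[keep, 0]]])
    return _pearson_pairwise(a, b)
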