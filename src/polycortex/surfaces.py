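"""Cortical surface meshes and the scalar fields that live on them.

This module provides the geometric substrate shared by every stage of the
package: a triangulated surface with paired spherical (registration)
coordinates, per-vertex scalar maps with a NaN medial-wall convention,
diffusion smoothing, parcel aggregation, and nearest-centroid assignment of
expression areas to surface parcels.

Scalar maps are stored as plain ``numpy`` arrays (NaN on the medial wall);
:class:`VertexMap` / :class:`ParcelMap` are thin wrappers that carry the
mesh/atlas reference for provenance. All public functions accept either the
wrapper or the raw array.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

logger = logging.getLogger("polycortex")

#: conversion between Gaussian kernel sigma and full width at half maximum
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


class MeshError(ValueError):
    """Raised when a mesh or a map attached to it violates its invariants."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

class SurfaceMesh:
    """Triangulated cortical surface with registration-sphere coordinates.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        Triangles as vertex index triples.
    sphere_coords : (V, 3) float array, optional
        Position of each vertex on the registration sphere (constant radius).
        Defaults to ``vertices`` (appropriate for synthetic sphere meshes).
    medial_wall : (V,) bool array, optional
        True where the surface is non-cortical; maps are NaN there.
    hemisphere : (V,) array of {"L", "R"}, optional
        Hemisphere assignment per vertex. Defaults to sign of x on the sphere.
    """

    def __init__(self, vertices, faces, sphere_coords=None, medial_wall=None,
                 hemisphere=None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        V = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= V:
            raise MeshError("faces index out-of-range vertices")
        used = np.zeros(V, dtype=bool)
        used[self.faces.ravel()] = True
        if not used.all():
            raise MeshError("every vertex must belong to at least one face")

        if sphere_coords is None:
            sphere_coords = self.vertices
        self.sphere_coords = np.asarray(sphere_coords, dtype=float)
        if self.sphere_coords.shape != (V, 3):
            raise MeshError("sphere_coords must be (V, 3)")
        radii = np.linalg.norm(self.sphere_coords, axis=1)
        r0 = radii.mean()
        if r0 <= 0 or np.abs(radii - r0).max() > 1e-6 * r0:
            raise MeshError("sphere_coords must lie on a sphere of constant "
                            "radius (1e-6 relative tolerance)")
        self.sphere_radius = float(r0)

        if medial_wall is None:
            medial_wall = np.zeros(V, dtype=bool)
        self.medial_wall = np.asarray(medial_wall, dtype=bool)
        if self.medial_wall.shape != (V,):
            raise MeshError("medial_wall must be (V,)")

        if hemisphere is None:
            hemisphere = np.where(self.sphere_coords[:, 0] < 0, "L", "R")
        self.hemisphere = np.asarray(hemisphere, dtype="U1")
        if self.hemisphere.shape != (V,):
            raise MeshError("hemisphere must be (V,)")

    # -- derived geometry, computed lazily and cached -----------------------

    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    @cached_property
    def edges(self):
        """Unique undirected edges as an (E, 2) array, i < j."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def edge_lengths(self):
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @cached_property
    def mean_edge_length(self):
        return float(self.edge_lengths.mean())

    @cached_property
    def adjacency(self):
        """Sparse symmetric vertex adjacency (unweighted)."""
        i, j = self.edges.T
        V = self.n_vertices
        data = np.ones(len(i))
        A = sp.coo_matrix((data, (i, j)), shape=(V, V))
        return (A + A.T).tocsr()

    @cached_property
    def face_areas(self):
        p = self.vertices[self.faces]
        c = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    @cached_property
    def vertex_areas(self):
        """One third of the area of incident faces, per vertex."""
        a = np.zeros(self.n_vertices)
        np.add.at(a, self.faces.ravel(), np.repeat(self.face_areas / 3.0, 3))
        return a

    @cached_property
    def total_area(self):
        return float(self.face_areas.sum())

    @cached_property
    def euler_characteristic(self):
        return self.n_vertices - len(self.edges) + self.n_faces

    @property
    def cortex_mask(self):
        """Boolean mask of cortical (non-medial-wall) vertices."""
        return ~self.medial_wall

    def __repr__(self):
        return (f"SurfaceMesh(V={self.n_vertices}, F={self.n_faces}, "
                f"medial={int(self.medial_wall.sum())})")


@dataclass
class VertexMap:
    """Scalar field over the vertices of a :class:`SurfaceMesh`.

    NaN values are permitted only on the medial wall.
    """

    values: np.ndarray
    mesh: SurfaceMesh

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_vertices,):
            raise MeshError("map length must equal vertex count")
        bad = np.isnan(self.values) & ~self.mesh.medial_wall
        if bad.any():
            raise MeshError(f"{bad.sum()} NaN values off the medial wall")


@dataclass
class ParcelMap:
    """Scalar per parcel of a surface atlas (NaN allowed, e.g. medial wall)."""

    values: np.ndarray
    parcel_ids: np.ndarray
    parcel_names: list | None = None
    centroids: np.ndarray | None = None  # sphere coords, for spin nulls
    atlas_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=np.int64)
        if self.values.shape != self.parcel_ids.shape:
            raise MeshError("one value per parcel required")


def map_values(obj):
    """Return the raw value array of a VertexMap/ParcelMap or array-like."""
    if isinstance(obj, (VertexMap, ParcelMap)):
        return obj.values
    return np.asarray(obj, dtype=float)


# ---------------------------------------------------------------------------
# Diffusion smoothing
# ---------------------------------------------------------------------------

def _heat_steps(mesh: SurfaceMesh, fwhm: float, valid: np.ndarray):
    """Plan explicit heat-equation steps achieving a Gaussian kernel of the
    requested FWHM on the subgraph of ``valid`` vertices.

    Each step applies x <- x - tau * L x with the combinatorial Laplacian L
    of the valid subgraph. The step is mass-conserving (columns of I - tau*L
    sum to 1 because L is symmetric with zero row sums) and positivity
    preserving for tau * max_degree <= 1. One step spreads mass to the
    neighbors at squared distance ~ edge length^2; on a two-dimensional
    surface the per-step variance in each tangent direction is
    tau * mean(sum_j l_ij^2) / 2, so k steps of size tau give sigma^2 =
    k * tau * mean(sum_j l_ij^2) / 2.
    """
    sub = mesh.adjacency[valid][:, valid]
    deg = np.asarray(sub.sum(axis=1)).ravel()
    L = sp.diags(deg) - sub
    # squared-edge-length second moment per valid vertex
    e = mesh.edges
    keep = valid[e[:, 0]] & valid[e[:, 1]]
    l2 = mesh.edge_lengths[keep] ** 2
    idx = np.cumsum(valid) - 1  # old -> new index
    s2 = np.zeros(int(valid.sum()))
    np.add.at(s2, idx[e[keep, 0]], l2)
    np.add.at(s2, idx[e[keep, 1]], l2)
    m2 = s2.mean()
    sigma2 = (fwhm / FWHM_PER_SIGMA) ** 2
    tau_max = 0.5 / max(deg.max(), 1)
    k = max(1, int(np.ceil(2.0 * sigma2 / (m2 * tau_max))))
    tau = 2.0 * sigma2 / (k * m2)
    return L, tau, k


def smooth(vmap, mesh: SurfaceMesh, fwhm: float):
    """Geodesic diffusion smoothing of one or many vertex maps.

    Parameters
    ----------
    vmap : array (V,) or (k, V), or VertexMap
    fwhm : total kernel full width at half maximum in mm; 0 is the identity.

    NaN vertices are excluded from every kernel and preserved as NaN, so no
    cortical signal bleeds across the medial wall.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    x = map_values(vmap) if not isinstance(vmap, np.ndarray) else np.asarray(vmap, float)
    single = x.ndim == 1
    X = np.atleast_2d(x).astype(float).copy()
    if X.shape[1] != mesh.n_vertices:
        raise MeshError("map length must equal vertex count")
    if fwhm == 0:
        return X[0] if single else X
    valid = np.isfinite(X).all(axis=0)
    if valid.sum() < 2:
        return X[0] if single else X
    L, tau, k = _heat_steps(mesh, fwhm, valid)
    Y = X[:, valid].T  # (Vv, k_maps)
    for _ in range(k):
        Y = Y - tau * (L @ Y)
    out = np.full_like(X, np.nan)
    out[:, valid] = Y.T
    out[:, ~valid & ~np.isnan(X).any(axis=0)] = X[:, ~valid & ~np.isnan(X).any(axis=0)]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Parcel aggregation
# ---------------------------------------------------------------------------

def parcellate(vmap, labels, stat: str = "mean"):
    """Aggregate a vertex map into per-parcel statistics.

    ``labels`` is a per-vertex integer array; label 0 (and negatives) marks
    unassigned vertices and is excluded. NaN vertices do not contribute; a
    parcel whose vertices are all NaN gets NaN.

    Returns
    -------
    (parcel_ids, values) : sorted unique positive labels and the statistic.
    """
    x = map_values(vmap)
    labels = np.asarray(labels)
    if labels.shape != x.shape:
        raise MeshError("label/map length mismatch")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    ids = np.unique(labels[labels > 0])
    out = np.full(len(ids), np.nan)
    for k, pid in enumerate(ids):
        v = x[labels == pid]
        v = v[np.isfinite(v)]
        if len(v):
            out[k] = np.mean(v) if stat == "mean" else np.median(v)
    return ids, out


def vertex_broadcast(parcel_values, parcel_ids, labels):
    """Inverse of :func:`parcellate`: paint parcel values back onto vertices."""
    lut = dict(zip(np.asarray(parcel_ids).tolist(),
                   np.asarray(parcel_values, dtype=float).tolist()))
    out = np.full(len(labels), np.nan)
    for k, lab in enumerate(np.asarray(labels)):
        if lab in lut:
            out[k] = lut[lab]
    return out


def parcel_centroids(mesh: SurfaceMesh, labels):
    """Spherical centroid of each positive parcel, projected to the sphere.

    Returns (parcel_ids, (P, 3) coords, hemisphere labels). The hemisphere of
    a parcel is the majority hemisphere of its vertices.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    cent = np.zeros((len(ids), 3))
    hemi = np.empty(len(ids), dtype="U1")
    for k, pid in enumerate(ids):
        sel = labels == pid
        m = mesh.sphere_coords[sel].mean(axis=0)
        n = np.linalg.norm(m)
        if n == 0:
            raise MeshError(f"degenerate (antipodally balanced) parcel {pid}")
        cent[k] = m / n * mesh.sphere_radius
        hemi[k] = "L" if (mesh.hemisphere[sel] == "L").mean() >= 0.5 else "R"
    return ids, cent, hemi


def great_circle_distance(a, b, radius=1.0):
    """Great-circle distance between points on a common sphere.

    ``a`` (N, 3) and ``b`` (M, 3) give an (N, M) matrix.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    an = a / np.linalg.norm(a, axis=-1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=-1, keepdims=True)
    cosang = np.clip(an @ bn.T, -1.0, 1.0)
    return radius * np.arccos(cosang)


def map_areas_to_parcels(area_centroids, fine_labels, mesh: SurfaceMesh):
    """Assign each expression area to the nearest fine parcel.

    Each area (given by its coordinates on the registration sphere) is
    assigned the parcel of the fine decomposition whose spherical centroid is
    nearest in great-circle distance. Deterministic; ties broken by the
    lowest parcel id.

    Returns an integer array of parcel ids, one per area.
    """
    ids, cents, _ = parcel_centroids(mesh, fine_labels)
    if len(ids) == 0:
        raise MeshError("empty atlas")
    D = great_circle_distance(np.asarray(area_centroids, float), cents,
                              radius=mesh.sphere_radius)
    # argmin returns the first (lowest-id) minimum since ids are sorted
    return ids[np.argmin(D, axis=1)]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
# Meshes travel as Wavefront OBJ plus a JSON sidecar holding what OBJ cannot:
# spherical coordinates, the medial-wall mask and hemisphere labels. Label
# atlases are one integer per line with a TSV label dictionary; vertex-map
# stacks are CSV with one column per subject.

def write_mesh(mesh: SurfaceMesh, path):
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(path, file_type="obj")
    sidecar = {
        "sphere_coords": mesh.sphere_coords.tolist(),
        "medial_wall": mesh.medial_wall.astype(int).tolist(),
        "hemisphere": mesh.hemisphere.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    tm = trimesh.load(path, file_type="obj", process=False)
    side = json.loads(path.with_suffix(".json").read_text())
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        sphere_coords=np.asarray(side["sphere_coords"], float),
        medial_wall=np.asarray(side["medial_wall"], bool),
        hemisphere=np.asarray(side["hemisphere"]),
    )


def write_labels(labels, names, path):
    """Per-vertex integer labels, one per line, plus a TSV label dictionary."""
    path = Path(path)
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")
    dic = pd.DataFrame({"label": sorted(names), "name": [names[k] for k in sorted(names)]})
    dic.to_csv(path.with_suffix(".dict.tsv"), sep="\t", index=False)


def read_labels(path):
    path = Path(path)
    labels = np.loadtxt(path, dtype=int)
    dic_path = path.with_suffix(".dict.tsv")
    names = {}
    if dic_path.exists():
        dic = pd.read_csv(dic_path, sep="\t")
        names = dict(zip(dic["label"], dic["name"]))
    return labels, names


def write_vertex_maps(stack, path, subject_ids=None):
    """(n_subjects, V) stack as CSV, one column per subject."""
    stack = np.atleast_2d(np.asarray(stack, float))
    cols = subject_ids if subject_ids is not None else [f"s{i}" for i in range(len(stack))]
    pd.DataFrame(stack.T, columns=list(cols)).to_csv(path, index=False)


def read_vertex_maps(path):
    df = pd.read_csv(path)
    return df.to_numpy().T, list(df.columns)
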