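"""Synthetic data with planted structure for every stage of the analysis.

The generators emulate the six inputs the pipeline consumes — a spherical
surface mesh, a developmental cohort table, per-subject morphometry with a
planted per-vertex score effect, surface atlases, a gene x area x specimen
expression panel with planted cell-type gradients, and parcel-level disorder
effect-size maps with planted correlations — so that parameter recovery and
statistical calibration can be tested without any controlled-access data.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .surfaces import (SurfaceMesh, great_circle_distance, map_values,
                       parcellate, smooth)

logger = logging.getLogger("polycortex")

#: the 11 cytoarchitecturally defined neocortical expression areas
AREAS_11 = ["A1C", "DFC", "IPC", "ITC", "M1C", "MFC",
            "OFC", "S1C", "STC", "V1C", "VFC"]

#: glial cell types scored through specificity weights
CELL_TYPES = ["astrocyte", "microglia", "oligodendrocyte"]

#: neuron compartments scored through gene-ontology marker sets
COMPARTMENTS = ["main_axon", "dendritic_tree", "neuron_to_neuron_synapse"]

COMPONENTS = CELL_TYPES + COMPARTMENTS

CYTO_TYPE_NAMES = ["agranular", "dysgranular", "eulaminate_I",
                   "eulaminate_II", "eulaminate_III", "koniocortical"]
NETWORK_NAMES = ["visual", "somatomotor", "dorsal_attention",
                 "ventral_attention", "limbic", "frontoparietal",
                 "default_mode"]


class SpecError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

def make_sphere_mesh(subdivisions: int, radius: float = 50.0,
                     medial_wall_fraction: float = 0.05) -> SurfaceMesh:
    """Icosphere stand-in for a registered cortical surface.

    Vertex count is 10 * 4**subdivisions + 2. Hemispheres are split at the
    x = 0 plane; a contiguous cap of ``medial_wall_fraction`` of each
    hemisphere's vertices (centered on the hemisphere pole) is flagged as
    medial wall. Deterministic.
    """
    if subdivisions < 0:
        raise SpecError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    hemi = np.where(vertices[:, 0] < 0, "L", "R")
    medial = np.zeros(len(vertices), dtype=bool)
    for h, pole in (("L", np.array([-1.0, 0.0, 0.0])),
                    ("R", np.array([1.0, 0.0, 0.0]))):
        idx = np.where(hemi == h)[0]
        n_cap = int(round(medial_wall_fraction * len(idx)))
        if n_cap:
            ang = great_circle_distance(vertices[idx], pole[None, :]).ravel()
            medial[idx[np.argsort(ang, kind="stable")[:n_cap]]] = True
    return SurfaceMesh(vertices, faces, sphere_coords=vertices,
                       medial_wall=medial, hemisphere=hemi)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Marginals of the simulated developmental cohort.

    Defaults emulate a PING-like sample: n = 390 children and adolescents,
    ages uniform on 3-21 years (sample mean ~12), 46.8% female, a handful of
    scanners, ten genetic principal components, and a standardized polygenic
    score drawn independently of age.
    """

    n_subjects: int = 390
    age_range: tuple = (3.0, 21.0)
    sex_ratio: float = 0.468
    n_scanners: int = 3
    n_pcs: int = 10
    score_mean: float = 0.0
    score_sd: float = 1.0
    brain_volume_mean: float = 1.25e6
    brain_volume_sd: float = 1.2e5
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")
        if not self.age_range[0] < self.age_range[1]:
            raise SpecError("age range min must be below max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise SpecError("sex_ratio must be in [0, 1]")
        if self.n_pcs < 0:
            raise SpecError("n_pcs must be >= 0")
        if self.n_scanners < 1:
            raise SpecError("n_scanners must be >= 1")
        if self.score_sd <= 0:
            raise SpecError("score_sd must be > 0")


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate a subject table with score independent of age by construction."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    lo, hi = spec.age_range
    df = pd.DataFrame({
        "subject_id": [f"sub{i:04d}" for i in range(n)],
        "score": rng.normal(spec.score_mean, spec.score_sd, n),
        "age": rng.uniform(lo, hi, n),
        "sex": np.where(rng.uniform(size=n) < spec.sex_ratio, "F", "M"),
        "scanner": [f"scanner{k}" for k in rng.integers(0, spec.n_scanners, n)],
        "brain_volume": np.clip(
            rng.normal(spec.brain_volume_mean, spec.brain_volume_sd, n),
            1e5, None),
    })
    for j in range(spec.n_pcs):
        df[f"pc{j + 1}"] = rng.normal(0.0, 1.0, n)
    return df


# ---------------------------------------------------------------------------
# Morphometry with a planted effect
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted truth for per-subject vertexwise morphometry.

    ``effect_map`` is the true per-vertex slope of the score term;
    ``covariate_betas`` maps subject-table column names (or "intercept") to a
    scalar or per-vertex slope. Residual noise is white Gaussian smoothed to
    ``noise_fwhm`` mm and rescaled so each vertex has residual SD
    ``noise_sd`` (thickness units) across subjects.
    """

    effect_map: np.ndarray
    covariate_betas: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    noise_fwhm: float = 0.0

    def __post_init__(self):
        self.effect_map = np.asarray(map_values(self.effect_map), dtype=float)
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if self.noise_fwhm < 0:
            raise SpecError("noise_fwhm must be >= 0")


def simulate_thickness(mesh: SurfaceMesh, subjects: pd.DataFrame,
                       effect: EffectSpec, seed: int | None = None):
    """Simulate an (n_subjects, V) morphometry stack.

    Each subject's map is the linear predictor from ``covariate_betas`` plus
    ``effect_map * score`` plus spatially smooth noise; medial-wall vertices
    are NaN for every subject. The smoothed noise is standardized per vertex
    (across subjects) before scaling by ``noise_sd``, so the planted
    signal-to-noise ratio |beta| * SD(score) / noise_sd is exact.
    """
    V = mesh.n_vertices
    if effect.effect_map.shape != (V,):
        raise SpecError("effect_map is not defined on the target mesh")
    n = len(subjects)
    rng = np.random.default_rng(seed)

    eff = np.nan_to_num(effect.effect_map, nan=0.0)
    signal = np.outer(subjects["score"].to_numpy(float), eff)
    for name, beta in effect.covariate_betas.items():
        x = (np.ones(n) if name == "intercept"
             else subjects[name].to_numpy(float))
        b = np.broadcast_to(np.nan_to_num(np.asarray(beta, float), nan=0.0), (V,))
        signal = signal + np.outer(x, b)

    noise = rng.standard_normal((n, V))
    if effect.noise_fwhm > 0:
        noise = smooth(noise, mesh, effect.noise_fwhm)
    if n > 1:
        sd = noise.std(axis=0, ddof=1)
        sd[~np.isfinite(sd) | (sd == 0)] = 1.0
        noise = (noise - noise.mean(axis=0)) / sd
    stack = signal + effect.noise_sd * noise
    stack[:, mesh.medial_wall] = np.nan
    return stack


# ---------------------------------------------------------------------------
# Atlases
# ---------------------------------------------------------------------------

def _farthest_point_sample(coords, k, rng, start=None):
    """Deterministic farthest-point sampling on the sphere (indices)."""
    n = len(coords)
    first = int(rng.integers(n)) if start is None else int(start)
    chosen = [first]
    d = great_circle_distance(coords, coords[[first]]).ravel()
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, great_circle_distance(coords, coords[[nxt]]).ravel())
    return np.array(chosen)


def _voronoi_labels(mesh: SurfaceMesh, n_patches: int, rng,
                    bilateral: str = "shared",
                    patches_per_class: int = 1) -> np.ndarray:
    """Bilaterally symmetric patches: spherical Voronoi cells of
    farthest-point seed directions, mirrored across the midline.

    Seed directions are sampled on the left hemisphere and reflected
    through the x = 0 plane for the right, emulating the bilateral
    organization of cytoarchitectural and functional atlases. With
    ``bilateral="shared"`` the mirrored patch keeps the same label (one
    class spans both hemispheres, as for functional networks); with
    ``"split"`` the left and right patches get distinct labels (as for a
    parcellation counting hemispheres separately; requires even
    ``n_patches``). Cells of a nearest-seed assignment on the sphere are
    geodesically convex, hence contiguous within each hemisphere.

    ``patches_per_class > 1`` makes each class a union of that many
    spatially separated Voronoi patches (farthest-point seeds interleaved
    across classes), emulating the distributed, multi-patch layout of real
    functional networks and cytoarchitectural types; only available with
    shared labels. Medial-wall vertices get label 0.
    """
    if bilateral == "split":
        if n_patches % 2:
            raise SpecError("split bilateral atlas needs an even patch count")
        if patches_per_class != 1:
            raise SpecError("multi-patch classes require shared labels")
        k = n_patches // 2
    else:
        k = n_patches * patches_per_class
    left = np.where(mesh.cortex_mask & (mesh.hemisphere == "L"))[0]
    seeds = left[_farthest_point_sample(mesh.sphere_coords[left], k, rng)]
    seed_dirs = mesh.sphere_coords[seeds]

    cortex = np.where(mesh.cortex_mask)[0]
    pos = mesh.sphere_coords[cortex].copy()
    right = mesh.hemisphere[cortex] == "R"
    pos[right, 0] = -pos[right, 0]  # mirror right hemisphere onto left
    nearest = np.argmin(great_circle_distance(pos, seed_dirs), axis=1)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    if bilateral == "split":
        labels[cortex] = nearest + 1
        labels[cortex[right]] += k
    else:
        # farthest-point order is spread out, so interleaving assigns each
        # class patches that are far apart
        labels[cortex] = (nearest % n_patches) + 1
    return labels


def make_atlases(mesh: SurfaceMesh, n_types: int = 6, n_networks: int = 7,
                 n_parcels: int = 64, n_fine_parcels: int = 200,
                 seed: int | None = None) -> dict:
    """Label maps emulating the four atlases the contextualization uses.

    Returns a dict with keys "types" (cytoarchitectural classes, agranular
    through koniocortical), "networks" (seven canonical functional networks),
    "parcels" (a Desikan-Killiany-like 64-parcel atlas) and "fine" (a
    200-parcel decomposition); each value is ``(labels, names)`` with labels
    a per-vertex int array (0 = medial wall) and names a label -> name dict.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for key, k, names, mode, ppc in (
            ("types", n_types, CYTO_TYPE_NAMES, "shared", 3),
            ("networks", n_networks, NETWORK_NAMES, "shared", 3),
            ("parcels", n_parcels, None, "split", 1),
            ("fine", n_fine_parcels, None, "split", 1)):
        labels = _voronoi_labels(mesh, k, rng, bilateral=mode,
                                 patches_per_class=ppc)
        if names is None:
            names = {i + 1: f"{key[:-1]}_{i + 1:03d}" for i in range(k)}
        else:
            names = {i + 1: nm for i, nm in enumerate(names[:k])}
        out[key] = (labels, names)
    return out


def make_area_centroids(mesh: SurfaceMesh, areas=None,
                        seed: int | None = None):
    """Well-spread spherical centroids for the expression areas.

    Returns (names, (A, 3) sphere coordinates).
    """
    areas = list(AREAS_11 if areas is None else areas)
    rng = np.random.default_rng(seed)
    cortex = np.where(mesh.cortex_mask)[0]
    idx = cortex[_farthest_point_sample(mesh.sphere_coords[cortex],
                                        len(areas), rng)]
    return areas, mesh.sphere_coords[idx].copy()


# ---------------------------------------------------------------------------
# Expression panel
# ---------------------------------------------------------------------------

def default_gradients(areas=None) -> dict:
    """Deterministic planted area-level mean expression per component.

    Sine/cosine harmonics over the area list (log-expression units):
    mutually orthogonal over equally indexed areas, so each component's
    planted spatial profile is distinct and recoverable without leakage
    into the others.
    """
    areas = list(AREAS_11 if areas is None else areas)
    a = np.arange(len(areas), dtype=float)
    out = {}
    for k, comp in enumerate(COMPONENTS):
        freq = 1 + k % 3
        phase = 0.0 if k < 3 else np.pi / 2.0
        out[comp] = np.sin(2.0 * np.pi * freq * a / len(areas) + phase)
    return out


@dataclass
class ExpressionSpec:
    """Planted structure of the synthetic expression panel."""

    n_genes: int = 300
    n_specimens: int = 12
    areas: list = field(default_factory=lambda: list(AREAS_11))
    component_gradients: dict | None = None
    specimen_noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0

    def __post_init__(self):
        if self.n_specimens < 1:
            raise SpecError("n_specimens must be >= 1")
        if self.specimen_noise_sd < 0:
            raise SpecError("specimen_noise_sd must be >= 0")
        if self.component_gradients is None:
            self.component_gradients = default_gradients(self.areas)
        for comp, g in self.component_gradients.items():
            if len(np.asarray(g, float)) != len(self.areas):
                raise SpecError(f"gradient for {comp} must have one value "
                                f"per area ({len(self.areas)})")
        n_assigned = len(self.component_gradients) * self.genes_per_component
        if n_assigned > self.n_genes:
            raise SpecError("n_genes too small for the component blocks")

    @property
    def genes_per_component(self) -> int:
        return max(5, self.n_genes // (2 * max(len(self.component_gradients), 1)))


@dataclass
class SyntheticExpression:
    """Expression panel plus the planted truth and derived weight tables."""

    panel: pd.DataFrame          # tidy: gene, area, specimen, value
    weights: pd.DataFrame        # gene, cell_type, specificity
    markers: dict                # compartment -> gene list
    gradients: dict              # component -> planted per-area means
    gene_components: dict        # gene -> component ("" = background)
    specimen_ages: pd.DataFrame  # specimen, age


def simulate_expression(spec: ExpressionSpec,
                        seed: int | None = None) -> SyntheticExpression:
    """Simulate a log-scale gene x area x specimen panel.

    Genes are partitioned into one block per component plus unstructured
    background genes. A component gene's expression tracks the component's
    planted area gradient (plus a gene-specific baseline and i.i.d. specimen
    noise). Specificity weights are concentrated on the cell-type blocks;
    marker lists partition the compartment blocks.
    """
    rng = np.random.default_rng(seed)
    comps = list(spec.component_gradients)
    gpc = spec.genes_per_component
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    gene_comp = {}
    for k, comp in enumerate(comps):
        for g in genes[k * gpc:(k + 1) * gpc]:
            gene_comp[g] = comp
    for g in genes[len(comps) * gpc:]:
        gene_comp[g] = ""

    A, S = len(spec.areas), spec.n_specimens
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    grad = np.zeros((spec.n_genes, A))
    for i, g in enumerate(genes):
        if gene_comp[g]:
            grad[i] = np.asarray(spec.component_gradients[gene_comp[g]], float)
    x = (baseline[:, None, None] + grad[:, :, None]
         + spec.specimen_noise_sd * rng.standard_normal((spec.n_genes, A, S)))

    panel = pd.DataFrame({
        "gene": np.repeat(genes, A * S),
        "area": np.tile(np.repeat(spec.areas, S), spec.n_genes),
        "specimen": np.tile([f"spec{j:02d}" for j in range(S)],
                            spec.n_genes * A),
        "value": x.ravel(),
    })

    rows = []
    for ct in [c for c in comps if c in CELL_TYPES]:
        for g in genes:
            w = (abs(rng.normal(1.0, 0.2)) if gene_comp[g] == ct else 0.0)
            if w > 0:
                rows.append((g, ct, w))
    weights = pd.DataFrame(rows, columns=["gene", "cell_type", "specificity"])

    markers = {c: [g for g in genes if gene_comp[g] == c]
               for c in comps if c in COMPARTMENTS}

    ages = pd.DataFrame({"specimen": [f"spec{j:02d}" for j in range(S)],
                         "age": np.sort(rng.uniform(3.0, 21.0, S))})
    return SyntheticExpression(panel=panel, weights=weights, markers=markers,
                               gradients={c: np.asarray(g, float) for c, g
                                          in spec.component_gradients.items()},
                               gene_components=gene_comp, specimen_ages=ages)


# ---------------------------------------------------------------------------
# Disorder maps
# ---------------------------------------------------------------------------

def simulate_disorder_maps(mesh: SurfaceMesh, labels, reference_values,
                           target_correlations: dict,
                           seed: int | None = None,
                           field_fwhm: float | None = None) -> dict:
    """Parcel-level effect-size maps with planted correlations to a reference.

    For each requested disorder, an independent smooth vertexwise field is
    parcellated with the same atlas, orthogonalized against the reference
    over the parcels where both are finite (Gram-Schmidt), and mixed as
    r * ref + sqrt(1 - r^2) * residual so the sample correlation with the
    reference equals the requested r exactly. NaN parcels of the reference
    stay NaN.

    Returns disorder -> per-parcel value array (aligned to the sorted
    positive labels of the atlas).
    """
    rng = np.random.default_rng(seed)
    ref = np.asarray(map_values(reference_values), float)
    finite = np.isfinite(ref)
    if finite.sum() < 3:
        raise SpecError("reference map needs >= 3 finite parcels")
    r_std = ref[finite] - ref[finite].mean()
    nr = np.linalg.norm(r_std)
    if nr == 0:
        raise SpecError("degenerate constant reference map")
    r_std = r_std / nr
    if field_fwhm is None:
        field_fwhm = 3.0 * mesh.mean_edge_length

    out = {}
    for name, r in target_correlations.items():
        if not -1.0 <= r <= 1.0:
            raise SpecError(f"|target correlation| must be <= 1 ({name})")
        z_vert = smooth(rng.standard_normal(mesh.n_vertices), mesh, field_fwhm)
        z_vert[mesh.medial_wall] = np.nan
        _, z = parcellate(z_vert, labels, stat="mean")
        if z.shape != ref.shape:
            raise SpecError("atlas does not match the reference parcel map")
        zc = z[finite] - z[np.isfinite(z) & finite].mean()
        zc = zc - (zc @ r_std) * r_std
        nz = np.linalg.norm(zc)
        if nz == 0:  # pragma: no cover - measure-zero degeneracy
            raise SpecError("degenerate independent field")
        zc = zc / nz
        y = np.full_like(ref, np.nan)
        y[finite] = r * r_std + np.sqrt(max(0.0, 1.0 - r * r)) * zc
        out[name] = y
    return out


# ---------------------------------------------------------------------------
# Planted focal effects
# ---------------------------------------------------------------------------

def focal_effect_map(mesh: SurfaceMesh, center_direction,
                     angular_radius: float, amplitude: float) -> np.ndarray:
    """A constant-amplitude geodesic cap of planted effect (0 elsewhere).

    ``center_direction`` is a 3-vector (normalized internally);
    ``angular_radius`` is the cap radius in radians on the sphere.
    """
    c = np.asarray(center_direction, float)
    c = c / np.linalg.norm(c)
    ang = great_circle_distance(mesh.sphere_coords, c[None, :]).ravel()
    eff = np.where(ang <= angular_radius, amplitude, 0.0)
    eff[mesh.medial_wall] = 0.0
    return eff
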