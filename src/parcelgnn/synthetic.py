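"""Synthetic cortices: mesh, parcellation, parcel-structured signals.

Generates a fully self-contained stand-in for a surface-based imaging
cohort: an icosphere mesh (with optional radial vertex noise — geometric
only; the unweighted graph and hence its spectrum are unchanged), a
geodesic-Voronoi ground-truth parcellation whose parcels are connected by
construction, a coarser "anatomical" atlas for regionalized connectivity
features, per-subject/per-session time series in which every parcel
carries a latent signal (correlated across parcels of the same coarse
region, emulating the overlapping connectivity fingerprints of neighboring
cortical areas) plus vertex noise, and parcel-structured scalar maps.
Per-subject label maps can be jittered at parcel boundaries to mimic
inter-subject areal variability.

Everything derives deterministically from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import trimesh

from parcelgnn.features import TimeSeriesMatrix
from parcelgnn.labels import LabelMap
from parcelgnn.surface import SurfaceGraph, build_graph, geodesic_hops

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "make_mesh",
    "make_parcellation",
    "make_time_series",
    "make_scalar_maps",
    "make_cohort",
]

SCALAR_NAMES = ("thickness", "curvature", "sulcal_depth", "myelin")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe the desk-scale benchmark cohort: a subdivision-3
    icosphere (642 vertices), 8 parcels, 20 subjects, 200 time points at
    signal-to-noise ratio 3, and no boundary jitter (all subjects share the
    template parcellation).
    """

    mesh_subdivisions: int = 3
    num_parcels: int = 8
    num_subjects: int = 20
    sessions_per_subject: int = 1
    timepoints: int = 200
    snr: float = 3.0
    boundary_jitter: int = 0
    seed: int = 0
    radial_noise: float = 0.02
    atlas_regions: int = 0  # 0 = auto: num_parcels - 2, floor 2
    scalar_noise: float = 0.5
    parcel_similarity: float = 0.9

    def __post_init__(self) -> None:
        if self.num_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if self.timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def effective_atlas_regions(self) -> int:
        return self.atlas_regions or max(2, self.num_parcels - 2)


@dataclass
class SyntheticCohort:
    """A generated cohort; all arrays share the mesh's vertex count."""

    config: SyntheticConfig
    mesh: SurfaceGraph
    template_labels: LabelMap
    atlas: LabelMap
    subject_labels: list[LabelMap]
    time_series: list[list[TimeSeriesMatrix]]  # [subject][session]
    scalars: list[dict[str, np.ndarray]]  # [subject][name]
    parcel_regions: dict[int, int] = None  # parcel -> modal atlas region


def make_mesh(
    subdivisions: int, radial_noise: float = 0.02, seed: int = 0
) -> SurfaceGraph:
    """Icosphere by repeated triangle subdivision; 10 * 4**s + 2 vertices.

    Radial noise perturbs vertex radii by up to ``radial_noise`` (relative).
    This breaks geometric symmetry only — the induced unweighted graph, and
    therefore the graph-Laplacian spectrum, is unaffected.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=100.0)
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if radial_noise > 0:
        rng = np.random.default_rng(seed)
        scale = 1.0 + radial_noise * rng.uniform(-1.0, 1.0, size=vertices.shape[0])
        vertices = vertices * scale[:, None]
    return build_graph(vertices, faces)


def _farthest_point_seeds(g: SurfaceGraph, p: int, rng: np.random.Generator) -> np.ndarray:
    seeds = [int(rng.integers(g.num_vertices))]
    for _ in range(p - 1):
        hops = geodesic_hops(g, np.array(seeds))
        seeds.append(int(hops.argmax()))
    return np.array(seeds)


def make_parcellation(g: SurfaceGraph, p: int, seed: int = 0) -> LabelMap:
    """Geodesic-hop Voronoi parcellation from farthest-point-sampled seeds.

    Regions grow by simultaneous breadth-first search from the seeds, so
    every parcel is a connected subgraph and non-empty.
    """
    n = g.num_vertices
    if p > n:
        raise ValueError(f"cannot place {p} parcels on {n} vertices")
    rng = np.random.default_rng(seed)
    seeds = _farthest_point_seeds(g, p, rng)
    labels = np.zeros(n, dtype=np.int64)
    labels[seeds] = np.arange(1, p + 1)
    frontier = list(seeds)
    while frontier:
        nxt = []
        for v in frontier:  # seed-order claiming breaks ties deterministically
            for u in g.neighbors(v):
                if labels[u] == 0:
                    labels[u] = labels[v]
                    nxt.append(u)
        frontier = nxt
    return LabelMap(labels=labels, num_classes=p)


def make_time_series(
    g: SurfaceGraph,
    labels: LabelMap,
    t: int,
    snr: float,
    seed: int = 0,
    *,
    parcel_groups: dict[int, int] | None = None,
    similarity: float = 0.0,
) -> TimeSeriesMatrix:
    """Parcel latent signals plus vertex noise at the requested SNR.

    Each parcel gets a unit-variance Gaussian white latent series; a
    vertex's series is its parcel latent plus Gaussian noise with standard
    deviation 1/snr, so within-parcel correlations rise with snr.

    When ``parcel_groups`` maps parcels to coarser groups and ``similarity``
    is positive, parcels of the same group share a group-level signal with
    variance fraction ``similarity``: latent_p = sqrt(similarity) * eta_g +
    sqrt(1 - similarity) * eps_p. This emulates the overlapping, correlated
    connectivity fingerprints of neighboring cortical areas, which is what
    makes labels near areal boundaries genuinely ambiguous in real data.
    """
    if not (0.0 <= similarity < 1.0) and similarity != 0.0:
        raise ValueError("similarity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = g.num_vertices
    areas = [int(a) for a in labels.present_labels()]
    if parcel_groups and similarity > 0:
        groups = {parcel_groups[a] for a in areas}
        etas = {gid: rng.standard_normal(t) for gid in sorted(groups)}
        latents = {
            a: np.sqrt(similarity) * etas[parcel_groups[a]]
            + np.sqrt(1.0 - similarity) * rng.standard_normal(t)
            for a in areas
        }
    else:
        latents = {a: rng.standard_normal(t) for a in areas}
    x = rng.standard_normal((n, t)) / snr
    for area, latent in latents.items():
        x[labels.labels == area] += latent
    return TimeSeriesMatrix(values=x)


def make_scalar_maps(
    labels: LabelMap,
    parcel_means: dict[str, np.ndarray],
    noise_sd: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Scalar maps: per-parcel mean level plus vertex noise."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, means in parcel_means.items():
        base = np.zeros(labels.n_vertices)
        for i, area in enumerate(labels.present_labels()):
            base[labels.labels == area] = means[i]
        out[name] = base + noise_sd * rng.standard_normal(labels.n_vertices)
    return out


def _jitter_labels(
    g: SurfaceGraph, labels: LabelMap, rounds: int, rng: np.random.Generator
) -> LabelMap:
    """Flip random boundary vertices to a neighboring parcel's label, ``rounds`` times."""
    lab = labels.labels.copy()
    for _ in range(rounds):
        adj = g.adjacency.tocoo()
        boundary = np.unique(adj.row[lab[adj.row] != lab[adj.col]])
        flip = boundary[rng.random(boundary.size) < 0.5]
        for v in flip:
            nbr_labels = np.unique(lab[g.neighbors(v)])
            nbr_labels = nbr_labels[nbr_labels != lab[v]]
            if nbr_labels.size:
                lab[v] = int(rng.choice(nbr_labels))
    return LabelMap(labels=lab, unlabeled_code=labels.unlabeled_code,
                    num_classes=labels.num_classes)


def make_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate the full cohort described by ``cfg``; reproducible from its seed."""
    root = np.random.default_rng(cfg.seed)
    mesh = make_mesh(cfg.mesh_subdivisions, cfg.radial_noise,
                     seed=int(root.integers(2**31)))
    template = make_parcellation(mesh, cfg.num_parcels, seed=int(root.integers(2**31)))
    atlas = make_parcellation(mesh, cfg.effective_atlas_regions,
                              seed=int(root.integers(2**31)))
    parcel_means = {
        name: root.standard_normal(cfg.num_parcels) for name in SCALAR_NAMES
    }
    # each parcel belongs to the atlas region covering most of its vertices;
    # parcels of one region share correlated latent signals
    parcel_regions = {
        int(a): int(np.bincount(atlas.labels[template.labels == a]).argmax())
        for a in template.present_labels()
    }
    subject_labels = []
    time_series = []
    scalars = []
    for _ in range(cfg.num_subjects):
        sub_rng_seed = int(root.integers(2**31))
        sub_rng = np.random.default_rng(sub_rng_seed)
        if cfg.boundary_jitter > 0:
            lab = _jitter_labels(mesh, template, cfg.boundary_jitter, sub_rng)
        else:
            lab = template
        subject_labels.append(lab)
        sessions = [
            make_time_series(mesh, lab, cfg.timepoints, cfg.snr,
                             seed=int(sub_rng.integers(2**31)),
                             parcel_groups=parcel_regions,
                             similarity=cfg.parcel_similarity)
            for _ in range(cfg.sessions_per_subject)
        ]
        time_series.append(sessions)
        scalars.append(
            make_scalar_maps(lab, parcel_means, cfg.scalar_noise,
                             seed=int(sub_rng.integers(2**31)))
        )
    return SyntheticCohort(
        config=cfg,
        mesh=mesh,
        template_labels=template,
        atlas=atlas,
        subject_labels=subject_labels,
        time_series=time_series,
        scalars=scalars,
        parcel_regions=parcel_regions,
    )
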