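"""Synthetic cortical phantoms with known ground truth.

Generates everything the downstream pipeline consumes — folded white/pial
surface pairs, a myelin density field with sharply bounded islands
(MT+-like and auditory-like high-myelin islands, a BA7-like low-myelin
island), T1w/T2w volumes whose ratio encodes that field, multiplicative
low-spatial-frequency bias, additive noise, and multi-species populations
of subjects x two hemispheres — so every stage can be tested against known
truth without external data.

Geometry is a radially perturbed icosphere: a base sphere (radius set by
the species size factor) indented by a few low-order sinusoidal "sulci" to
exercise curvature handling.  Parcels are geodesic patches grown from
fixed, well-separated anchor directions until their surface-area fraction
matches the species target; the myelin field is a background level plus a
per-parcel contrast with a hard step at the parcel border.  The right
hemisphere
is the exact mirror image of the left (x → −x), sharing vertex ids, which
stands in for cross-subject/hemisphere surface registration.

All randomness flows from named seeds; the same (seed, subject, hemisphere)
always yields bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import csgraph

from .geometry import (
    MetricMap,
    SurfacePair,
    TriangleMesh,
    adjacency_matrix,
    compute_midthickness,
    vertex_areas,
    vertex_normals,
)
from .myelin import VolumeImage
from .parcellation import ParcelLabelMap

__all__ = [
    "SpeciesSpec",
    "PhantomTruth",
    "SubjectRecord",
    "PhantomResolutionError",
    "make_hemisphere",
    "rasterize_volumes",
    "make_population",
]

BASE_RADIUS_MM = 10.0  # hemisphere radius at total_area_scale = 1
INTENSITY_SCALE = 100.0  # scanner-ish arbitrary units

# well-separated unit anchor directions for parcel placement, in assignment
# order; larger parcels should come later in the spec dict if many are used
_ANCHORS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)


class PhantomResolutionError(ValueError):
    """A target parcel fraction is unreachable at the mesh resolution."""


@dataclass
class SpeciesSpec:
    """Generation parameters for one species' phantom population.

    ``target_fractions`` maps parcel name → fraction of total surface area
    (0–1); ``myelin_levels`` maps parcel name → contrast added to the
    background myelin ratio (background 1.0; e.g. +0.8 for an MT+-like
    island, −0.3 for a BA7-like low-myelin island).  ``total_area_scale``
    multiplies the 10 mm base radius.  ``sampling_fwhm_mm`` is the
    species-tuned depth-weighting kernel for myelin sampling.
    """

    name: str
    n_subjects: int
    target_fractions: dict[str, float] = field(default_factory=dict)
    myelin_levels: dict[str, float] = field(default_factory=dict)
    mean_thickness_mm: float = 2.0
    total_area_scale: float = 1.0
    sampling_fwhm_mm: float = 1.8
    seed: int = 0
    # mesh / variability knobs
    subdivisions: int = 5
    background_myelin: float = 1.0
    thickness_levels: dict[str, float] = field(default_factory=dict)
    fold_amplitude_mm: float | None = None
    n_folds: int = 3
    area_jitter_sd: float = 0.06
    thickness_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.mean_thickness_mm <= 0 or self.total_area_scale <= 0:
            raise ValueError("all lengths must be > 0")
        if self.sampling_fwhm_mm <= 0:
            raise ValueError("sampling_fwhm_mm must be > 0")
        fr = self.target_fractions
        if any(f <= 0 for f in fr.values()):
            raise ValueError("target fractions must be > 0")
        if sum(fr.values()) > 1.0:
            raise ValueError("target fractions must sum to <= 1")
        if set(self.myelin_levels) - set(fr):
            raise ValueError("myelin_levels for unknown parcels")
        if len(fr) > len(_ANCHORS):
            raise ValueError(f"at most {len(_ANCHORS)} parcels supported")

    @property
    def radius_mm(self) -> float:
        return BASE_RADIUS_MM * self.total_area_scale


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated hemisphere."""

    labels: ParcelLabelMap
    myelin_field: MetricMap
    true_fractions: dict[str, float]
    true_parcel_areas_mm2: dict[str, float]
    seeds: dict[str, int]
    thickness_mm: np.ndarray | None = None


@dataclass
class SubjectRecord:
    """One hemisphere of one phantom subject."""

    species: str
    subject_id: str
    hemisphere: str
    pair: SurfacePair
    truth: PhantomTruth
    t1w: VolumeImage | None = None
    t2w: VolumeImage | None = None
    bias: VolumeImage | None = None


# ---------------------------------------------------------------------------
# Hemisphere generation
# ---------------------------------------------------------------------------

def _base_sphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(s.vertices, dtype=np.float64), np.asarray(s.faces, dtype=np.int64)


def make_hemisphere(
    spec: SpeciesSpec, subject_index: int, hemisphere: str
) -> tuple[SurfacePair, PhantomTruth]:
    """Generate one phantom hemisphere with ground truth.

    Deterministic given (spec.seed, subject_index, hemisphere); the right
    hemisphere is the exact mirror (x → −x) of the left, with identical
    truth, so L/R vertex correspondence is the identity.
    """
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    rng = np.random.default_rng([max(spec.seed, 0), subject_index, 0x9E3779])
    u, faces = _base_sphere(spec.subdivisions)

    radius = spec.radius_mm * np.sqrt(
        np.clip(1.0 + rng.normal() * spec.area_jitter_sd, 0.25, 4.0)
    )
    fold_amp = (
        spec.fold_amplitude_mm
        if spec.fold_amplitude_mm is not None
        else 0.06 * spec.radius_mm
    )
    r = np.full(len(u), radius)
    for _ in range(spec.n_folds):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        freq = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * np.pi)
        r += (fold_amp / spec.n_folds) * np.sin(freq * np.pi * (u @ axis) + phase)
    white = TriangleMesh(u * r[:, None], faces)

    labels, seeds = _grow_parcels(white, spec)
    thickness = np.full(len(u), spec.mean_thickness_mm * float(
        np.clip(1.0 + rng.normal() * spec.thickness_jitter_sd, 0.5, 1.5)
    ))
    for name, dt in spec.thickness_levels.items():
        lab = labels.label_of(name)
        thickness[labels.labels == lab] += dt
    normals = vertex_normals(white)
    pial = TriangleMesh(white.vertices + thickness[:, None] * normals, faces)
    pair = SurfacePair(white, pial)

    myelin = np.full(len(u), spec.background_myelin)
    for name in spec.target_fractions:
        lab = labels.label_of(name)
        myelin[labels.labels == lab] += spec.myelin_levels.get(name, 0.0)

    mid = compute_midthickness(pair)
    va = vertex_areas(mid).values
    total = float(va.sum())
    fractions, areas = {}, {}
    for name in spec.target_fractions:
        lab = labels.label_of(name)
        area = float(va[labels.labels == lab].sum())
        areas[name] = area
        fractions[name] = area / total

    if hemisphere == "R":
        pair = _mirror_pair(pair)

    truth = PhantomTruth(
        labels=labels,
        myelin_field=MetricMap(myelin, units="ratio"),
        true_fractions=fractions,
        true_parcel_areas_mm2=areas,
        seeds=seeds,
        thickness_mm=thickness,
    )
    return pair, truth


def _mirror_pair(pair: SurfacePair) -> SurfacePair:
    def mirror(mesh: TriangleMesh) -> TriangleMesh:
        v = mesh.vertices.copy()
        v[:, 0] *= -1.0
        return TriangleMesh(v, mesh.faces[:, ::-1].copy())

    return SurfacePair(mirror(pair.white), mirror(pair.pial))


def _grow_parcels(
    white: TriangleMesh, spec: SpeciesSpec
) -> tuple[ParcelLabelMap, dict[str, int]]:
    """Grow geodesic patches to the target area fractions on the white mesh."""
    labels = np.zeros(white.n_vertices, dtype=np.int64)
    names: dict[int, str] = {}
    seeds: dict[str, int] = {}
    if not spec.target_fractions:
        return ParcelLabelMap(labels, names), seeds

    va = vertex_areas(white).values
    total = float(va.sum())
    wadj = adjacency_matrix(white, weighted=True)
    unit = white.vertices / np.linalg.norm(white.vertices, axis=1, keepdims=True)
    for k, (name, frac) in enumerate(spec.target_fractions.items(), start=1):
        seed = int(np.argmax(unit @ _ANCHORS[k - 1]))
        dist = csgraph.dijkstra(wadj, directed=False, indices=seed)
        dist[labels != 0] = np.inf  # never absorb an earlier parcel
        order = np.argsort(dist, kind="stable")
        order = order[np.isfinite(dist[order])]
        cum = np.cumsum(va[order])
        target = frac * total
        n_take = int(np.argmin(np.abs(cum - target))) + 1
        realized = cum[n_take - 1] / total
        if abs(realized - frac) / frac > 0.10:
            raise PhantomResolutionError(
                f"parcel {name!r}: realized fraction {realized:.4f} vs target "
                f"{frac:.4f} unreachable at subdivision {spec.subdivisions}"
            )
        patch = order[:n_take]
        labels[patch] = k
        names[k] = name
        seeds[name] = seed
    return ParcelLabelMap(labels, names), seeds


# ---------------------------------------------------------------------------
# Volume rasterization
# ---------------------------------------------------------------------------

def _default_contrast(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invertible monotone contrast model with T1w/T2w == myelin exactly.

    t1 = S*sqrt(m) (increasing), t2 = S/sqrt(m) (decreasing), so the
    noiseless unbiased ratio equals the myelin field value.
    """
    root = np.sqrt(m)
    return INTENSITY_SCALE * root, INTENSITY_SCALE / root


def rasterize_volumes(
    pair: SurfacePair,
    truth: PhantomTruth,
    voxel_mm: float,
    bias_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VolumeImage, VolumeImage, VolumeImage]:
    """Render T1w/T2w volumes encoding the phantom myelin field.

    Within the cortical ribbon the noiseless, unbiased T1w/T2w ratio at a
    voxel equals the myelin value of the nearest correspondence segment;
    the multiplicative bias field B (a smooth sum of three long-wavelength
    cosine components, wavelength ≥ 30 mm) enters as T1w·B and T2w/B so
    the ratio carries B².  Additive Gaussian noise of sd
    ``noise_sd · S / sqrt(2)`` per channel makes the resulting ratio noise
    ≈ ``noise_sd`` in ratio units near baseline.  Outside the ribbon,
    background intensities give a ratio (0.125) well separated from
    cortical values.

    Returns (T1w, T2w, bias); the bias volume holds B at voxel centres.
    """
    thick = np.linalg.norm(pair.pial.vertices - pair.white.vertices, axis=1)
    if voxel_mm > 0.5 * float(np.median(thick)) + 1e-12:
        raise ValueError(
            f"voxel_mm={voxel_mm} exceeds half the median thickness "
            f"({0.5 * float(np.median(thick)):.3f} mm); ribbon needs >= 2 voxels"
        )
    rng = np.random.default_rng([max(seed, 0), 0xB10B])

    lo = pair.pial.vertices.min(axis=0) - 3 * voxel_mm
    hi = pair.pial.vertices.max(axis=0) + 3 * voxel_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = lo

    pts, vals = _splat_points(pair, truth, voxel_mm)
    idx = np.round((pts - lo) / voxel_mm).astype(int)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    pts, idx, vals = pts[ok], idx[ok], vals[ok]
    # nearest-sample-wins: each occupied voxel takes the value of the splat
    # point closest to its centre, so the voxel encodes the myelin of the
    # nearest correspondence segment and step borders stay voxel-sharp
    centers_of = lo + voxel_mm * idx
    dist = np.linalg.norm(pts - centers_of, axis=1)
    order = np.argsort(-dist, kind="stable")
    myelin_vox = np.full(shape, np.nan)
    myelin_vox[idx[order, 0], idx[order, 1], idx[order, 2]] = vals[order]
    ribbon = np.isfinite(myelin_vox)
    ribbon, myelin_vox = _fill_ribbon_holes(ribbon, myelin_vox)

    centers = lo + voxel_mm * np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    )
    B = _bias_field(centers, bias_amplitude, rng)

    t1 = np.empty(shape)
    t2 = np.empty(shape)
    t1_c, t2_c = _default_contrast(np.where(ribbon, myelin_vox, 1.0))
    t1[:] = np.where(ribbon, t1_c, 0.25 * INTENSITY_SCALE)
    t2[:] = np.where(ribbon, t2_c, 2.0 * INTENSITY_SCALE)
    t1 *= B
    t2 /= B
    if noise_sd > 0:
        s = noise_sd * INTENSITY_SCALE / np.sqrt(2.0)
        t1 = t1 + rng.normal(0.0, s, size=shape)
        t2 = t2 + rng.normal(0.0, s, size=shape)

    return (
        VolumeImage(t1, affine),
        VolumeImage(t2, affine),
        VolumeImage(B, affine),
    )


def _fill_ribbon_holes(
    ribbon: np.ndarray, myelin_vox: np.ndarray, passes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Close unsplatted voxels surrounded by ribbon (coarse-mesh gaps).

    A non-ribbon voxel with >= 4 of its 6 face neighbours in the ribbon is
    interior to the sheet; it takes the neighbour mean.  Two passes close
    gaps up to ~2 voxels.
    """
    vals = np.where(ribbon, myelin_vox, 0.0)
    for _ in range(passes):
        nb_cnt = np.zeros(ribbon.shape)
        nb_sum = np.zeros(ribbon.shape)
        for axis in range(3):
            for shift in (1, -1):
                nb_cnt += np.roll(ribbon, shift, axis=axis)
                nb_sum += np.roll(vals, shift, axis=axis)
        fill = ~ribbon & (nb_cnt >= 4)
        if not fill.any():
            break
        vals[fill] = nb_sum[fill] / nb_cnt[fill]
        ribbon = ribbon | fill
    return ribbon, np.where(ribbon, vals, np.nan)


def _splat_points(
    pair: SurfacePair, truth: PhantomTruth, voxel_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dense point samples of the ribbon with myelin values.

    Samples run along the white→pial correspondence segments (extended by
    0.6 voxel beyond each end so trilinear reads near the surfaces stay
    inside correctly valued voxels), through each vertex, each face
    centroid (value: the median of its corners, preserving step borders),
    and each edge midpoint (value: the lower-index endpoint's).
    """
    w = pair.white.vertices
    p = pair.pial.vertices
    f = pair.white.faces
    m = truth.myelin_field.values
    thick = np.linalg.norm(p - w, axis=1)
    ext = 0.6 * voxel_mm
    n_depth = int(np.ceil((thick.max() + 2 * ext) / (0.5 * voxel_mm))) + 1

    def segment_samples(wp: np.ndarray, pp: np.ndarray, vv: np.ndarray):
        seg = pp - wp
        ln = np.linalg.norm(seg, axis=1, keepdims=True)
        ln = np.maximum(ln, 1e-12)
        unit = seg / ln
        a = wp - ext * unit
        b = pp + ext * unit
        s = np.linspace(0.0, 1.0, n_depth)
        pts = a[None, :, :] + s[:, None, None] * (b - a)[None, :, :]
        return pts.reshape(-1, 3), np.tile(vv, n_depth)

    pts_v, val_v = segment_samples(w, p, m)
    cw = w[f].mean(axis=1)
    cp = p[f].mean(axis=1)
    cv = np.median(m[f], axis=1)
    pts_c, val_c = segment_samples(cw, cp, cv)
    e = np.unique(np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0)
    ew = 0.5 * (w[e[:, 0]] + w[e[:, 1]])
    ep = 0.5 * (p[e[:, 0]] + p[e[:, 1]])
    ev = m[e.min(axis=1)]
    pts_e, val_e = segment_samples(ew, ep, ev)
    return np.concatenate([pts_v, pts_c, pts_e]), np.concatenate([val_v, val_c, val_e])


def _bias_field(xyz: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative bias B(x) = 1 + amplitude * smooth(x), |smooth| <= 1.

    Three cosine components with wavelengths in [100, 180] mm — smoothness
    (derivative) scale wavelength/2π >= 15 mm, i.e. near-linear ramps over
    a small primate head, like B1-transmit profiles — so the field is
    separable from areal transitions by the 5 mm surface correction.
    Always generated (consuming the same RNG draws) so volumes are
    comparable across amplitudes.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("bias_amplitude must be in [0, 1)")
    comp = np.zeros(xyz.shape[:-1])
    weights = []
    parts = []
    for _ in range(3):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        wavelength = rng.uniform(100.0, 180.0)
        phase = rng.uniform(0, 2 * np.pi)
        c = rng.uniform(0.5, 1.0)
        parts.append(c * np.cos(2 * np.pi * (xyz @ axis) / wavelength + phase))
        weights.append(c)
    comp = sum(parts) / sum(weights)
    return 1.0 + amplitude * comp


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def make_population(
    specs: list[SpeciesSpec],
    voxel_mm: float | None = None,
    bias_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    with_volumes: bool = True,
) -> list[SubjectRecord]:
    """Generate n_subjects × 2 hemispheres per species.

    Per-hemisphere seeds are derived deterministically from each spec's
    seed.  ``voxel_mm`` defaults per species to 0.25 × mean thickness —
    comfortably inside the at-least-two-voxels-across-the-ribbon criterion,
    mirroring the submillimetre resolutions used for small-brain imaging.
    Duplicate species names are rejected.
    """
    if not specs:
        raise ValueError("need at least one species spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate species names: {names}")
    records: list[SubjectRecord] = []
    for spec in specs:
        vx = voxel_mm if voxel_mm is not None else 0.25 * spec.mean_thickness_mm
        for subj in range(spec.n_subjects):
            for hemi in ("L", "R"):
                pair, truth = make_hemisphere(spec, subj, hemi)
                rec = SubjectRecord(
                    species=spec.name,
                    subject_id=f"{spec.name}-{subj:03d}",
                    hemisphere=hemi,
                    pair=pair,
                    truth=truth,
                )
                if with_volumes:
                    vseed = int(
                        np.random.default_rng(
                            [max(spec.seed, 0), subj, 0 if hemi == "L" else 1, 0xF00D]
                        ).integers(2**31)
                    )
                    rec.t1w, rec.t2w, rec.bias = rasterize_volumes(
                        pair, truth, vx, bias_amplitude, noise_sd, seed=vseed
                    )
                records.append(rec)
    return records
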