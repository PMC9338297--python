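"""Synthetic vascular phantoms with exact ground truth.

Digital stand-ins for perfused implantation sites: labelled 3D volumes of
straight tubes, helices ("tightly coiled" spiral-artery-like vessels) and
small branching trees, each carrying its analytic centerlines, radii,
vessel classes and terminal (inlet/outlet) roles.  Two-group cohorts with
controlled diameter/length effect sizes emulate a case/control comparison
of implantation sites.

Rasterization rule: a voxel is foreground iff its center lies within the
tube's (linearly interpolated) radius of the centerline polyline.
Foreground/background intensities are fixed at 200/20 with optional
additive Gaussian noise; only the intensity volume is noisy — the label
volume is the exact voxelized geometry, standing in for the study's manual
segmentation, which is taken as given by the analysis pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .voxelio import BACKGROUND, CANAL, RADIAL, SPIRAL, LabelVolume, Volume

FOREGROUND_INTENSITY = 200.0
BACKGROUND_INTENSITY = 20.0


@dataclass
class CenterlineTube:
    """A single vessel tube: ordered centerline points with per-point radii (μm)."""

    points: np.ndarray  # (N, 3) μm
    radius_profile: np.ndarray  # (N,) μm
    vessel_class: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 points of dimension 3")
        if len(self.radius_profile) != len(self.points):
            raise ValueError("radius profile length must match point count")
        if np.any(self.radius_profile <= 0):
            raise ValueError("all radii must be positive")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def arc_length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TruthTerminal:
    """Ground-truth role of a spiral-subnetwork terminal."""

    position: np.ndarray  # (3,) μm
    role: str  # "inlet" | "outlet" | "none"
    tube_index: int

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.role not in ("inlet", "outlet", "none"):
            raise ValueError(f"unknown terminal role {self.role!r}")


@dataclass
class Phantom:
    """A labelled synthetic volume plus its exact geometric ground truth."""

    volume: Volume
    labels: LabelVolume
    truth_tubes: list
    truth_terminals: list
    seed: int
    truth_junctions: list = field(default_factory=list)

    def export_truth_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "voxel_size_um": self.volume.voxel_size_um,
            "tubes": [
                {
                    "points_um": t.points.tolist(),
                    "radius_profile_um": t.radius_profile.tolist(),
                    "vessel_class": int(t.vessel_class),
                }
                for t in self.truth_tubes
            ],
            "terminals": [
                {"position_um": t.position.tolist(), "role": t.role, "tube_index": t.tube_index}
                for t in self.truth_terminals
            ],
            "junctions_um": [np.asarray(j).tolist() for j in self.truth_junctions],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


@dataclass
class CohortSpec:
    """Two-group cohort design with controlled ground-truth effect sizes."""

    n_sites_per_group: int
    group_b_diameter_scale: float = 0.85
    group_b_length_scale: float = 1.38
    noise_sd: float = 10.0
    seed: int = 0
    voxel_size_um: float = 8.0
    volume_shape: tuple = (128, 128, 128)

    def __post_init__(self):
        if self.n_sites_per_group < 1:
            raise ValueError("n_sites_per_group must be >= 1")
        if self.group_b_diameter_scale <= 0 or self.group_b_length_scale <= 0:
            raise ValueError("effect-size scales must be positive")


# ---------------------------------------------------------------------------
# rasterization


def rasterize_tubes(tubes, shape, voxel_size_um) -> np.ndarray:
    """Voxelize tubes into a label grid (later tubes overwrite earlier ones).

    A voxel belongs to a tube iff its center is within the interpolated
    radius of the centerline polyline (point-to-segment distance).
    """
    labels = np.zeros(shape, dtype=np.uint8)
    h = float(voxel_size_um)
    shape = np.asarray(shape)
    for tube in tubes:
        pts = tube.points / h - 0.5  # voxel-index coordinates of centerline
        radii = tube.radius_profile / h
        for i in range(len(pts) - 1):
            p0, p1 = pts[i], pts[i + 1]
            r0, r1 = radii[i], radii[i + 1]
            rmax = max(r0, r1)
            lo = np.maximum(np.floor(np.minimum(p0, p1) - rmax - 1).astype(int), 0)
            hi = np.minimum(np.ceil(np.maximum(p0, p1) + rmax + 1).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            grid = np.stack(
                np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij"),
                axis=-1,
            ).astype(float)
            d = p1 - p0
            L2 = float(d @ d)
            t = np.clip(((grid - p0) @ d) / L2, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            dist2 = ((grid - closest) ** 2).sum(axis=-1)
            r_t = r0 + t * (r1 - r0)
            sel = dist2 <= r_t**2
            sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            sub[sel] = tube.vessel_class
    return labels


def _volume_from_labels(labels: np.ndarray, voxel_size_um, noise_sd, rng) -> Volume:
    data = np.where(labels > 0, FOREGROUND_INTENSITY, BACKGROUND_INTENSITY)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=labels.shape)
    return Volume(data.astype(np.float64), float(voxel_size_um))


# ---------------------------------------------------------------------------
# centerline constructors


def _straight_points(p0, p1, step_um) -> np.ndarray:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step_um)) + 1)
    return p0 + np.linspace(0.0, 1.0, n)[:, None] * (p1 - p0)


def helix_points(
    start,
    axis_direction,
    outward,
    coil_radius_um,
    pitch_um,
    total_angle_rad,
    step_um,
) -> np.ndarray:
    """Sample a circular helix that starts at ``start`` and winds about the
    axis through ``start + coil_radius * outward`` along ``axis_direction``.

    ``outward`` (projected perpendicular to the axis) points from the first
    helix point toward the coil center.
    """
    axis = np.asarray(axis_direction, float)
    axis = axis / np.linalg.norm(axis)
    outward = np.asarray(outward, float)
    outward = outward - (outward @ axis) * axis
    norm = np.linalg.norm(outward)
    if norm == 0:
        raise ValueError("outward direction must not be parallel to the helix axis")
    outward = outward / norm
    center = np.asarray(start, float) + coil_radius_um * outward
    e1 = -outward  # radial direction of the first point
    e2 = np.cross(axis, e1)
    chord = 2.0 * np.arcsin(min(1.0, step_um / (2.0 * coil_radius_um)))
    n = max(8, int(np.ceil(total_angle_rad / max(chord, 1e-6))) + 1)
    theta = np.linspace(0.0, total_angle_rad, n)
    pts = (
        center
        + coil_radius_um * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        + (theta * pitch_um / (2 * np.pi))[:, None] * axis
    )
    return pts


def helix_arc_per_radian(coil_radius_um, pitch_um) -> float:
    return float(np.hypot(coil_radius_um, pitch_um / (2 * np.pi)))


# ---------------------------------------------------------------------------
# phantom factories


def make_tube_phantom(
    shape_spec: str,
    radius_um: float,
    length_um: float,
    voxel_size_um: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction=(1.0, 0.0, 0.0),
    coil_radius_um: float | None = None,
    pitch_um: float | None = None,
) -> Phantom:
    """A single spiral-class tube: straight or helical, with constant radius.

    Helix defaults: pitch = 4 x radius, coil radius = 3 x radius (keeps the
    coil from self-intersecting); ``length_um`` is the centerline arc length
    in both cases.
    """
    if radius_um < 1.5 * voxel_size_um:
        raise ValueError(
            f"radius {radius_um} μm below resolvability (needs >= 1.5 x voxel "
            f"size = {1.5 * voxel_size_um} μm)"
        )
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    h = float(voxel_size_um)
    step = 0.5 * h
    margin = radius_um + 3 * h

    if shape_spec == "straight":
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        # anchor the axis on a voxel center: an axis exactly between voxel
        # columns is a lattice-degenerate input with an ambiguous medial curve
        p0 = (np.ceil(margin / h) + 0.5) * np.full(3, h)
        pts = _straight_points(p0, p0 + d * length_um, step)
    elif shape_spec == "helix":
        coil_r = coil_radius_um if coil_radius_um is not None else 3.0 * radius_um
        pitch = pitch_um if pitch_um is not None else 4.0 * radius_um
        total_angle = length_um / helix_arc_per_radian(coil_r, pitch)
        start = np.full(3, margin) + np.array([0.0, coil_r, coil_r])
        pts = helix_points(
            start, (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), coil_r, pitch, total_angle, step
        )
        pts = pts - pts.min(axis=0) + margin
    else:
        raise ValueError(f"unknown shape_spec {shape_spec!r}")

    tube = CenterlineTube(pts, np.full(len(pts), float(radius_um)), SPIRAL)
    shape = tuple(int(np.ceil(x / h)) for x in pts.max(axis=0) + margin)
    labels = rasterize_tubes([tube], shape, h)
    rng = np.random.default_rng(seed)
    return Phantom(
        volume=_volume_from_labels(labels, h, noise_sd, rng),
        labels=LabelVolume(labels, h),
        truth_tubes=[tube],
        truth_terminals=[
            TruthTerminal(pts[0], "none", 0),
            TruthTerminal(pts[-1], "none", 0),
        ],
        seed=seed,
    )


def _polyline_min_distance(point, pts) -> float:
    """Distance from a point to a polyline."""
    point = np.asarray(point, float)
    p0, p1 = pts[:-1], pts[1:]
    d = p1 - p0
    L2 = (d * d).sum(axis=1)
    t = np.clip(((point - p0) * d).sum(axis=1) / L2, 0.0, 1.0)
    closest = p0 + t[:, None] * d
    return float(np.sqrt(((point - closest) ** 2).sum(axis=1)).min())


def make_tree_phantom(
    tubes,
    voxel_size_um: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    junction_tol_um: float | None = None,
    volume_shape: tuple | None = None,
) -> Phantom:
    """Voxelize a connected set of tubes and derive spiral terminal roles.

    The tube set must be connected (endpoints touching another tube within
    ``junction_tol_um + that tube's radius``).  Spiral tube endpoints not
    shared with another spiral tube are spiral-subnetwork terminals; a
    terminal adjacent to a radial tube is an inlet, adjacent to a canal an
    outlet.  At least one inlet and one outlet are required.
    """
    tubes = list(tubes)
    h = float(voxel_size_um)
    tol = junction_tol_um if junction_tol_um is not None else 1.5 * h

    def touches(point, tube) -> bool:
        return _polyline_min_distance(point, tube.points) <= tube.radius_profile.max() + tol

    # connectivity over tubes
    n = len(tubes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            for p in (tubes[i].points[0], tubes[i].points[-1]):
                if touches(p, tubes[j]):
                    parent[find(i)] = find(j)
                    break
            else:
                for p in (tubes[j].points[0], tubes[j].points[-1]):
                    if touches(p, tubes[i]):
                        parent[find(i)] = find(j)
                        break
    if len({find(i) for i in range(n)}) != 1:
        raise ValueError("tube spec is disconnected")

    spiral_idx = [i for i, t in enumerate(tubes) if t.vessel_class == SPIRAL]
    terminals: list[TruthTerminal] = []
    junctions: list[np.ndarray] = []
    for i in spiral_idx:
        for p in (tubes[i].points[0], tubes[i].points[-1]):
            shared_spiral = any(
                j != i and touches(p, tubes[j]) for j in spiral_idx
            )
            near_radial = any(
                t.vessel_class == RADIAL and touches(p, t) for t in tubes
            )
            near_canal = any(
                t.vessel_class == CANAL and touches(p, t) for t in tubes
            )
            if shared_spiral:
                junctions.append(np.asarray(p, float))
                continue
            if near_radial:
                role = "inlet"
            elif near_canal:
                role = "outlet"
            else:
                role = "none"
            terminals.append(TruthTerminal(p, role, i))
            if near_radial or near_canal:
                junctions.append(np.asarray(p, float))

    if not any(t.role == "inlet" for t in terminals):
        raise ValueError("tree spec has no radial-adjacent spiral terminal (inlet)")
    if not any(t.role == "outlet" for t in terminals):
        raise ValueError("tree spec has no canal-adjacent spiral terminal (outlet)")

    if volume_shape is None:
        all_pts = np.vstack([t.points for t in tubes])
        rmax = max(t.radius_profile.max() for t in tubes)
        shape = tuple(int(np.ceil(x / h)) for x in all_pts.max(axis=0) + rmax + 3 * h)
    else:
        shape = tuple(volume_shape)
    # draw spiral first: where tubes overlap at junctions the adjacent class
    # wins, so spiral terminals sit directly against radial/canal voxels
    order = sorted(range(n), key=lambda i: (tubes[i].vessel_class != SPIRAL, i))
    labels = rasterize_tubes([tubes[i] for i in order], shape, h)
    rng = np.random.default_rng(seed)
    return Phantom(
        volume=_volume_from_labels(labels, h, noise_sd, rng),
        labels=LabelVolume(labels, h),
        truth_tubes=tubes,
        truth_terminals=terminals,
        seed=seed,
        truth_junctions=junctions,
    )


# ---------------------------------------------------------------------------
# implantation-site-like tree geometry and cohorts

#: geometry priors for a synthetic implantation site, in μm.  Chosen to put
#: spiral radii at 3-4 voxels (26-34 μm at 8 μm voxels, matching the scale of
#: mouse spiral arteries at mid-gestation) inside a 128^3 field of view.
SITE_PRIORS = {
    "n_spirals": 3,
    "spiral_radius_range": (26.0, 34.0),
    "coil_radius_range": (50.0, 65.0),
    "pitch_range": (130.0, 160.0),  # clears the canal's short down-leg
    "turns_range": (1.5, 2.1),
    "trunk_radius": 38.0,
    "trunk_length": 420.0,
    # attachments sit >=120 μm from either blunt trunk end (thinning retracts
    # the axis line by up to ~2 radii there) and ~90 μm apart so every
    # attachment survives as a distinct degree-3 junction
    "attach_offsets": (120.0, 210.0, 300.0),
    "canal_radius": 42.0,
    "canal_length": 50.0,
    # radial gap between trunk axis and helix start; also the coil's nearest
    # approach to the trunk axis, so it must clear trunk radius + max spiral
    # radius by well over a voxel or rasterized surfaces can bridge
    "standoff": 100.0,
}


def _sample_site_params(rng: np.random.Generator, priors=None) -> dict:
    pr = dict(SITE_PRIORS, **(priors or {}))
    k = pr["n_spirals"]
    params = {
        "trunk_radius": pr["trunk_radius"],
        "trunk_length": pr["trunk_length"],
        "canal_radius": pr["canal_radius"],
        "canal_length": pr["canal_length"],
        "standoff": pr["standoff"],
        "helices": [],
    }
    # sub-voxel jitter of the whole site breaks lattice alignment (no real
    # specimen sits exactly on the scanner grid); shared by matched pairs
    params["origin_jitter_vox"] = [float(x) for x in rng.uniform(0.2, 0.45, 3)]
    for i in range(k):
        params["helices"].append(
            {
                "radius": float(rng.uniform(*pr["spiral_radius_range"])),
                "coil_radius": float(rng.uniform(*pr["coil_radius_range"])),
                "pitch": float(rng.uniform(*pr["pitch_range"])),
                "turns": float(rng.uniform(*pr["turns_range"])),
                "azimuth": float(2 * np.pi * i / k + rng.uniform(-0.1, 0.1)),
                "attach_offset": pr["attach_offsets"][i % len(pr["attach_offsets"])],
            }
        )
    return params


def site_tubes_from_params(
    params: dict,
    extent_um: np.ndarray,
    step_um: float,
    diameter_scale: float = 1.0,
    length_scale: float = 1.0,
) -> list:
    """Build the tube list for one implantation-site phantom.

    ``diameter_scale`` multiplies every *spiral* ground-truth radius and
    ``length_scale`` every spiral tube's arc length exactly (the helix gains
    winding angle at fixed coil geometry).  The radial trunk and canal stubs
    are identical across matched groups: the controlled effects model
    spiral-artery remodeling specifically, and matched feeder anatomy makes
    feeder-related measurement contamination cancel in group ratios.
    """
    ds, ls = float(diameter_scale), float(length_scale)
    center = np.array([0.0, extent_um[1] / 2.0, extent_um[2] / 2.0])
    trunk_len = params["trunk_length"]
    trunk_r = params["trunk_radius"]
    trunk_lo = center + np.array([75.0, 0.0, 0.0])  # boundary margin > max radius
    trunk_hi = trunk_lo + np.array([trunk_len, 0.0, 0.0])
    tubes = []
    trunk_pts = _straight_points(trunk_lo, trunk_hi, step_um)
    tubes.append(CenterlineTube(trunk_pts, np.full(len(trunk_pts), trunk_r), RADIAL))

    for hp in params["helices"]:
        r = hp["radius"] * ds
        coil_r = hp["coil_radius"]
        pitch = hp["pitch"]
        azim = hp["azimuth"]
        attach = trunk_lo + np.array([hp["attach_offset"], 0.0, 0.0])
        radial_dir = np.array([0.0, np.cos(azim), np.sin(azim)])
        start = attach + radial_dir * (params["standoff"])
        # spiral polyline: outward connector, then helix winding about +x
        connector = _straight_points(attach, start, step_um)
        arc_out = float(np.linalg.norm(start - attach))
        arc_helix_a = hp["turns"] * 2 * np.pi * helix_arc_per_radian(coil_r, pitch)
        total_a = arc_out + arc_helix_a
        # solve winding angle so the whole spiral arc scales exactly by ls
        arc_helix = ls * total_a - arc_out
        if arc_helix <= 0:
            raise ValueError("length_scale too small for the connector geometry")
        total_angle = arc_helix / helix_arc_per_radian(coil_r, pitch)
        # helix starts at the connector end, coil center further outward
        hpts = helix_points(
            start, (1.0, 0.0, 0.0), radial_dir, coil_r, pitch, total_angle, step_um
        )
        spiral_pts = np.vstack([connector[:-1], hpts])
        tubes.append(CenterlineTube(spiral_pts, np.full(len(spiral_pts), r), SPIRAL))
        # short canal stub above the helix end: long enough to label the
        # outlet neighborhood, short enough that its skeleton line (after
        # blunt-end retraction of ~1 radius) barely extends the spiral chain
        c_start = hpts[-1]
        c_end = hpts[-1] + np.array([params["canal_length"], 0.0, 0.0])
        cpts = _straight_points(c_start, c_end, step_um)
        tubes.append(CenterlineTube(cpts, np.full(len(cpts), params["canal_radius"]), CANAL))
    return tubes


def make_site_phantom(
    rng_or_seed,
    voxel_size_um: float = 8.0,
    volume_shape=(128, 128, 128),
    noise_sd: float = 10.0,
    diameter_scale: float = 1.0,
    length_scale: float = 1.0,
    params: dict | None = None,
) -> Phantom:
    """One random implantation-site-like phantom (radial trunk, coiled
    spirals, canal stubs)."""
    if isinstance(rng_or_seed, np.random.Generator):
        rng = rng_or_seed
        seed = -1
    else:
        seed = int(rng_or_seed)
        rng = np.random.default_rng(seed)
    if params is None:
        params = _sample_site_params(rng)
    h = float(voxel_size_um)
    extent = np.asarray(volume_shape, float) * h
    tubes = site_tubes_from_params(params, extent, 0.5 * h, diameter_scale, length_scale)
    jitter = h * np.asarray(params.get("origin_jitter_vox", (0.25, 0.3, 0.35)))
    tubes = [
        CenterlineTube(t.points + jitter, t.radius_profile, t.vessel_class) for t in tubes
    ]
    all_pts = np.vstack([t.points for t in tubes])
    rmax = max(t.radius_profile.max() for t in tubes)
    if np.any(all_pts - rmax < 0) or np.any(all_pts + rmax > extent):
        raise ValueError("site geometry does not fit the requested volume")
    ph = make_tree_phantom(
        tubes, h, noise_sd=noise_sd, seed=seed, volume_shape=tuple(volume_shape)
    )
    # reseed the intensity noise from the site rng for cohort reproducibility
    labels = ph.labels.labels
    ph.volume = _volume_from_labels(labels, h, noise_sd, rng)
    return ph


def make_cohort(spec: CohortSpec):
    """Matched two-group cohort: per pair, group B shares group A's random
    geometry with all radii scaled by ``group_b_diameter_scale`` and all arc
    lengths by ``group_b_length_scale``.

    Returns a list of ``(phantom_a, phantom_b)`` pairs.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_sites_per_group)
    pairs = []
    for child in children:
        rng = np.random.default_rng(child)
        params = _sample_site_params(rng)
        noise_seeds = rng.integers(0, 2**31 - 1, size=2)
        ph_a = make_site_phantom(
            int(noise_seeds[0]),
            spec.voxel_size_um,
            spec.volume_shape,
            spec.noise_sd,
            params=params,
        )
        ph_b = make_site_phantom(
            int(noise_seeds[1]),
            spec.voxel_size_um,
            spec.volume_shape,
            spec.noise_sd,
            diameter_scale=spec.group_b_diameter_scale,
            length_scale=spec.group_b_length_scale,
            params=params,
        )
        pairs.append((ph_a, ph_b))
    return pairs


def truth_spiral_summary(phantom: Phantom) -> dict:
    """Ground-truth spiral morphometry: arc-length-weighted mean diameter and
    mean tube arc length (the node-basis / segment-basis analogues)."""
    diam_num = diam_den = 0.0
    lengths = []
    for t in phantom.truth_tubes:
        if t.vessel_class != SPIRAL:
            continue
        steps = np.linalg.norm(np.diff(t.points, axis=0), axis=1)
        mid_d = t.radius_profile[:-1] + t.radius_profile[1:]  # 2 x mean pair radius
        diam_num += float((steps * mid_d).sum())
        diam_den += float(steps.sum())
        lengths.append(t.arc_length_um)
    return {
        "mean_diameter_um": diam_num / diam_den,
        "mean_segment_length_um": float(np.mean(lengths)),
        "n_segments": len(lengths),
    }
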