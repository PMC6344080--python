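"""Ground-truthed synthetic data: anisotropy titrations and AFM topographs.

The generators emulate the two kinds of raw data the analysis modules
consume:

* noisy titration tables drawn from the binding models (or from the exact
  mechanistic competition equilibrium, so that an IC50 *emerges* instead of
  being imposed), and
* height maps (nm) of surface-equilibrated worm-like-chain DNA, bridged
  DNA multimers, circular molecules and multi-lobed protein particles,
  with tip convolution, per-scanline offsets and pixel noise.

Every generator takes an explicit integer seed and is deterministic.
Default imaging geometry is a 1000 x 1000 nm^2 field at 512 x 512 pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy.ndimage import grey_dilation
from scipy.spatial import cKDTree

from .binding import (
    CompetitionSystem,
    HyperbolicParams,
    Ic50Params,
    TightBindingParams,
    Titration,
    hyperbolic_model,
    ic50_model,
    solve_competition_equilibrium,
    tight_binding_model,
)

__all__ = [
    "RISE_PER_BP_NM",
    "WlcChain",
    "SceneGroundTruth",
    "Topograph",
    "ParticleTemplate",
    "ParticlePlacement",
    "generate_wlc_chain",
    "generate_circle",
    "build_bridged_scene",
    "build_particle_scene",
    "place_particle",
    "render_topograph",
    "render_scene",
    "generate_titration",
]

RISE_PER_BP_NM = 0.34  # B-form DNA helical rise

DEFAULT_FIELD_NM = 1000.0
DEFAULT_SIZE_PX = 512
DEFAULT_PERSISTENCE_NM = 50.0
DEFAULT_DNA_HEIGHT_NM = 0.5
DEFAULT_DNA_SIGMA_NM = 2.0


# --------------------------------------------------------------------------
# Polymer geometry
# --------------------------------------------------------------------------

@dataclass
class WlcChain:
    """A discrete 2-D worm-like chain (vertices in nm).

    ``closed`` marks circular molecules; their closure edge (last vertex
    back to first) is part of the contour.
    """

    vertices: np.ndarray
    rise_per_bp: float
    n_bp: int
    seed: int
    closed: bool = False

    @property
    def contour_nm(self) -> float:
        v = self.vertices
        d = float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))
        if self.closed:
            d += float(np.linalg.norm(v[0] - v[-1]))
        return d

    def translated(self, dx: float, dy: float) -> "WlcChain":
        return WlcChain(self.vertices + np.array([dx, dy]), self.rise_per_bp, self.n_bp, self.seed, self.closed)

    def rotated(self, angle: float) -> "WlcChain":
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        return WlcChain(self.vertices @ R.T, self.rise_per_bp, self.n_bp, self.seed, self.closed)


def generate_wlc_chain(
    n_bp: int,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    step_nm: float = 1.0,
    seed: int = 0,
    rise_per_bp: float = RISE_PER_BP_NM,
    rng: np.random.Generator | None = None,
    start_angle: float | None = None,
) -> WlcChain:
    """Sample one surface-equilibrated (2-D) worm-like chain.

    The walk takes equal steps of length L/n_steps (so total contour is
    exactly ``n_bp * rise_per_bp``) and turns by a zero-mean Gaussian angle
    of variance ``step / persistence`` at each step, giving a tangent
    correlation exp(-s / (2 P)) appropriate for a chain equilibrated in two
    dimensions.
    """
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    if persistence_nm <= 0:
        raise ValueError("persistence_nm must be positive")
    if step_nm > 2.0:
        raise ValueError("step_nm must be <= 2 nm to resolve the curvature")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = n_bp * rise_per_bp
    n_steps = max(1, int(round(L / step_nm)))
    ds = L / n_steps
    theta0 = rng.uniform(0, 2 * np.pi) if start_angle is None else start_angle
    turns = rng.normal(0.0, np.sqrt(ds / persistence_nm), size=n_steps - 1)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    verts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return WlcChain(verts, rise_per_bp, n_bp, seed)


def generate_circle(n_bp: int, rise_per_bp: float = RISE_PER_BP_NM, n_vertices: int = 200) -> WlcChain:
    """Closed circular molecule whose polygon perimeter is exactly the contour."""
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    L = n_bp * rise_per_bp
    # chord-corrected radius: perimeter of the n-gon equals L exactly
    r = L / (2 * n_vertices * np.sin(np.pi / n_vertices))
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = r * np.column_stack([np.cos(ang), np.sin(ang)])
    return WlcChain(verts, rise_per_bp, n_bp, seed=-1, closed=True)


def _self_clearance_ok(verts: np.ndarray, clearance: float, min_arc_gap: float) -> bool:
    """True if no two vertices far apart along the chain come closer than
    ``clearance`` in the plane (a proxy for self-crossing / self-touching)."""
    n = len(verts)
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    d2 = np.sum((verts[:, None, :] - verts[None, :, :]) ** 2, axis=-1)
    arc_gap = np.abs(arc[:, None] - arc[None, :])
    mask = arc_gap > min_arc_gap
    if not mask.any():
        return True
    return bool(np.sqrt(d2[mask]).min() > clearance)


# --------------------------------------------------------------------------
# Protein particle templates
# --------------------------------------------------------------------------

_CLASS_SPOTS = {"I": 1, "II": 1, "III": 2, "IV": 3, "V": 4}


@dataclass
class ParticleTemplate:
    """Sum-of-lobe particle model in its own (centred) frame.

    ``lobes`` are (x, y, height, sigma) Gaussians; ``ridges`` are
    (x0, y0, x1, y1, height, sigma) rods with a Gaussian cross-section.
    Fields are combined by pointwise maximum.
    """

    class_id: str
    lobes: list[tuple[float, float, float, float]]
    ridges: list[tuple[float, float, float, float, float, float]]
    volume_nm3: float = 0.0
    spot_positions: np.ndarray | None = None

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        h = np.zeros(np.broadcast(x, y).shape)
        for cx, cy, hh, sg in self.lobes:
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            np.maximum(h, hh * np.exp(-d2 / (2 * sg * sg)), out=h)
        for x0, y0, x1, y1, hh, sg in self.ridges:
            d2 = _dist2_to_segment(x, y, x0, y0, x1, y1)
            np.maximum(h, hh * np.exp(-d2 / (2 * sg * sg)), out=h)
        return h

    @property
    def radius_nm(self) -> float:
        pts = [(cx, cy, sg) for cx, cy, _, sg in self.lobes]
        pts += [(x0, y0, sg) for x0, y0, _, _, _, sg in self.ridges]
        pts += [(x1, y1, sg) for _, _, x1, y1, _, sg in self.ridges]
        return max(np.hypot(px, py) + 4 * sg for px, py, sg in pts)


def _dist2_to_segment(x, y, x0, y0, x1, y1):
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return (x - x0) ** 2 + (y - y0) ** 2
    t = np.clip(((x - x0) * vx + (y - y0) * vy) / L2, 0.0, 1.0)
    px, py = x0 + t * vx, y0 + t * vy
    return (x - px) ** 2 + (y - py) ** 2


def place_particle(
    class_id: str,
    spot_sep_nm: float = 30.0,
    spot_height_nm: float = 2.0,
    rod_height_nm: float = 0.5,
    spot_sigma_nm: float = 4.0,
    rod_sigma_nm: float = 2.0,
    tail_len_nm: float = 15.0,
) -> ParticleTemplate:
    """Build the height template for one morphology class.

    Classes: I single lobe; II single lobe with a tail rod; III dumbbell
    (two lobes joined by a rod, default separation 30 nm); IV three lobes
    in a shallow arc; V four connected lobes.
    """
    if class_id not in _CLASS_SPOTS:
        raise ValueError(f"unknown particle class {class_id!r}; expected I..V")
    s = spot_sep_nm
    lobes: list[tuple[float, float, float, float]] = []
    ridges: list[tuple[float, float, float, float, float, float]] = []
    if class_id == "I":
        lobes = [(0.0, 0.0, spot_height_nm, spot_sigma_nm)]
    elif class_id == "II":
        lobes = [(0.0, 0.0, spot_height_nm, spot_sigma_nm)]
        ridges = [(0.0, 0.0, tail_len_nm + spot_sigma_nm, 0.0, rod_height_nm, rod_sigma_nm)]
    elif class_id == "III":
        lobes = [(-s / 2, 0.0, spot_height_nm, spot_sigma_nm), (s / 2, 0.0, spot_height_nm, spot_sigma_nm)]
        ridges = [(-s / 2, 0.0, s / 2, 0.0, rod_height_nm, rod_sigma_nm)]
    elif class_id == "IV":
        ys = 0.25 * s
        centers = [(-s, -ys), (0.0, ys), (s, -ys)]
        lobes = [(cx, cy, spot_height_nm, spot_sigma_nm) for cx, cy in centers]
        for (ax, ay), (bx, by) in zip(centers[:-1], centers[1:]):
            ridges.append((ax, ay, bx, by, rod_height_nm, rod_sigma_nm))
    else:  # V
        ys = 0.25 * s
        centers = [(-1.5 * s, ys), (-0.5 * s, -ys), (0.5 * s, ys), (1.5 * s, -ys)]
        lobes = [(cx, cy, spot_height_nm, spot_sigma_nm) for cx, cy in centers]
        for (ax, ay), (bx, by) in zip(centers[:-1], centers[1:]):
            ridges.append((ax, ay, bx, by, rod_height_nm, rod_sigma_nm))
    tpl = ParticleTemplate(class_id, lobes, ridges)
    tpl.spot_positions = np.array([[cx, cy] for cx, cy, _, _ in lobes])
    tpl.volume_nm3 = _template_volume(tpl)
    return tpl


def _template_volume(tpl: ParticleTemplate, grid_nm: float = 0.25) -> float:
    r = tpl.radius_nm
    ax = np.arange(-r, r + grid_nm, grid_nm)
    X, Y = np.meshgrid(ax, ax)
    return float(tpl.evaluate(X, Y).sum() * grid_nm * grid_nm)


@dataclass
class ParticlePlacement:
    template: ParticleTemplate
    center: tuple[float, float]
    angle: float = 0.0

    def spot_positions_nm(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        return self.template.spot_positions @ R.T + np.array(self.center)


# --------------------------------------------------------------------------
# Scenes
# --------------------------------------------------------------------------

@dataclass
class SceneGroundTruth:
    """Exact bookkeeping for every rendered object."""

    molecules: list[dict]
    scale_nm_per_px: float
    image_size_px: int
    n_fields: int = 1
    field_nm: float = DEFAULT_FIELD_NM


class _FieldPacker:
    """Greedy non-overlapping placement of polylines into square fields."""

    def __init__(self, field_nm: float, margin_nm: float, clearance_nm: float,
                 max_units: float, rng: np.random.Generator):
        self.field_nm = field_nm
        self.margin = margin_nm
        self.clearance = clearance_nm
        self.max_units = max_units
        self.rng = rng
        self.field_index = 0
        self._points: list[np.ndarray] = []
        self._units = 0.0
        self._tree: cKDTree | None = None

    def _new_field(self):
        self.field_index += 1
        self._points = []
        self._units = 0.0
        self._tree = None

    def place(self, verts: np.ndarray, units: float, attempts: int = 120) -> tuple[np.ndarray, int] | None:
        """Try to place ``verts`` (centred arbitrary coords) into the current
        field; opens a new field when full. Returns (placed_verts, field)."""
        for field_try in range(40):
            if self._units + units > self.max_units and self._points:
                self._new_field()
            for _ in range(attempts):
                ang = self.rng.uniform(0, 2 * np.pi)
                c, s = np.cos(ang), np.sin(ang)
                v = verts @ np.array([[c, -s], [s, c]]).T
                lo = v.min(axis=0)
                hi = v.max(axis=0)
                span = hi - lo
                avail = self.field_nm - 2 * self.margin - span
                if np.any(avail < 0):
                    continue
                off = self.margin - lo + self.rng.uniform(0, 1, size=2) * avail
                cand = v + off
                if self._tree is not None:
                    d, _ = self._tree.query(cand, k=1)
                    if d.min() <= self.clearance:
                        continue
                self._points.append(cand)
                self._tree = cKDTree(np.vstack(self._points))
                self._units += units
                return cand, self.field_index
            self._new_field()
        return None


def build_bridged_scene(
    n_molecules: int,
    multimer_fractions: dict[int, float] | None = None,
    circle_fraction: float = 0.0,
    seed: int = 0,
    n_bp: int = 587,
    persistence_nm: float = DEFAULT_PERSISTENCE_NM,
    junction: str = "end_to_end",
    field_nm: float = DEFAULT_FIELD_NM,
    size_px: int = DEFAULT_SIZE_PX,
    margin_nm: float = 30.0,
    clearance_nm: float = 10.0,
    avoid_self_crossing: bool = True,
    max_units_per_field: float = 8.0,
) -> tuple[list[WlcChain], SceneGroundTruth]:
    """Deposit a population of DNA monomers, k-mer bridges and circles.

    k-mers are built by joining k monomer chains (``junction`` one of
    ``end_to_end``, ``end_to_centre``, ``centre_to_centre``; only
    end-to-end joins produce a simple path of k-fold contour, the others
    produce branched objects that a tracer excludes). Ground truth records
    the exact multiplicity and contour of every molecule, and the field
    (image tile) each molecule was deposited into.
    """
    multimer_fractions = dict(multimer_fractions or {})
    frac_sum = sum(multimer_fractions.values()) + circle_fraction
    if frac_sum > 1 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    if junction not in ("end_to_end", "end_to_centre", "centre_to_centre"):
        raise ValueError("unknown junction mode")

    rng = np.random.default_rng(seed)
    counts = {k: int(round(f * n_molecules)) for k, f in multimer_fractions.items()}
    n_circ = int(round(circle_fraction * n_molecules))
    n_mono = n_molecules - sum(counts.values()) - n_circ
    if n_mono < 0:
        raise ValueError("fractions leave no room for monomers")
    kinds: list[tuple[str, int]] = (
        [("dna_monomer", 1)] * n_mono
        + [("dna_multimer", k) for k, c in sorted(counts.items()) for _ in range(c)]
        + [("circle", 1)] * n_circ
    )
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    L_mono = n_bp * RISE_PER_BP_NM
    packer = _FieldPacker(field_nm, margin_nm, clearance_nm, max_units_per_field, rng)
    chains: list[WlcChain] = []
    records: list[dict] = []
    for mol_id, (kind, k) in enumerate(kinds):
        if kind == "circle":
            geom = generate_circle(n_bp)
            true_contour = L_mono
        else:
            geom = _sample_chain(k * n_bp if kind == "dna_multimer" and junction == "end_to_end" else n_bp,
                                 k, kind, junction, n_bp, persistence_nm, rng,
                                 avoid_self_crossing, clearance_nm)
            true_contour = k * L_mono if kind == "dna_multimer" else L_mono
        units = float(k)
        placed = packer.place(geom.vertices - geom.vertices.mean(axis=0), units)
        if placed is None:
            raise RuntimeError("could not place molecule; loosen packing parameters")
        verts, fld = placed
        chain = WlcChain(verts, geom.rise_per_bp, geom.n_bp, seed, geom.closed)
        chains.append(chain)
        records.append(
            {
                "id": mol_id,
                "type": kind,
                "k": k,
                "true_contour_nm": true_contour,
                "field": fld,
                "junction": junction if kind == "dna_multimer" else None,
            }
        )
    gt = SceneGroundTruth(
        molecules=records,
        scale_nm_per_px=field_nm / size_px,
        image_size_px=size_px,
        n_fields=packer.field_index + 1,
        field_nm=field_nm,
    )
    return chains, gt


def _sample_chain(total_bp, k, kind, junction, n_bp, persistence_nm, rng,
                  avoid_self_crossing, clearance_nm) -> WlcChain:
    """Draw one (possibly multimeric) chain, resampling self-touching ones."""
    for _ in range(200):
        if kind == "dna_multimer" and junction != "end_to_end":
            # branched bridge: not a simple path; return the main duplex with
            # partner chains attached at the junction point
            parts = [generate_wlc_chain(n_bp, persistence_nm, rng=rng).vertices]
            anchor = parts[0][len(parts[0]) // 2] if junction == "end_to_centre" else parts[0][len(parts[0]) // 2]
            for _j in range(k - 1):
                extra = generate_wlc_chain(n_bp, persistence_nm, rng=rng).vertices
                if junction == "centre_to_centre":
                    extra = extra - extra[len(extra) // 2] + anchor
                else:
                    extra = extra - extra[0] + anchor
                parts.append(extra)
            verts = np.vstack(parts)
            return WlcChain(verts, RISE_PER_BP_NM, k * n_bp, -1)
        # simple path of total_bp (monomer, or end-to-end k-mer with kinks)
        if kind == "dna_multimer":
            segs = []
            pos = np.zeros(2)
            for _j in range(k):
                part = generate_wlc_chain(n_bp, persistence_nm, rng=rng)
                v = part.vertices - part.vertices[0] + pos
                segs.append(v if not segs else v[1:])
                pos = v[-1]
            verts = np.vstack(segs)
            chain = WlcChain(verts, RISE_PER_BP_NM, k * n_bp, -1)
        else:
            chain = generate_wlc_chain(n_bp, persistence_nm, rng=rng)
        if not avoid_self_crossing:
            return chain
        if _self_clearance_ok(chain.vertices, clearance_nm * 0.6, min_arc_gap=4 * clearance_nm):
            return chain
    warnings.warn("could not draw a non-self-touching chain; returning last sample")
    return chain


def build_particle_scene(
    class_counts: dict[str, int],
    seed: int = 0,
    field_nm: float = DEFAULT_FIELD_NM,
    size_px: int = DEFAULT_SIZE_PX,
    margin_nm: float = 60.0,
    clearance_nm: float = 40.0,
    **template_kw,
) -> tuple[list[ParticlePlacement], SceneGroundTruth]:
    """Scatter particle templates (classes I..V) without overlap."""
    rng = np.random.default_rng(seed)
    ids = [cid for cid, n in sorted(class_counts.items()) for _ in range(n)]
    ids = [ids[i] for i in rng.permutation(len(ids))]
    placements: list[ParticlePlacement] = []
    records: list[dict] = []
    packer = _FieldPacker(field_nm, margin_nm, clearance_nm, max_units=12.0, rng=rng)
    for mol_id, cid in enumerate(ids):
        tpl = place_particle(cid, **template_kw)
        ring = np.array([[tpl.radius_nm, 0.0], [-tpl.radius_nm, 0.0], [0.0, tpl.radius_nm], [0.0, -tpl.radius_nm], [0.0, 0.0]])
        placed = packer.place(ring, units=1.0)
        if placed is None:
            raise RuntimeError("could not place particle")
        verts, fld = placed
        center = tuple(verts[-1])
        ang = rng.uniform(0, 2 * np.pi)
        pl = ParticlePlacement(tpl, center, ang)
        placements.append(pl)
        records.append(
            {
                "id": mol_id,
                "type": f"particle_class_{cid}",
                "k": 1,
                "true_volume_nm3": tpl.volume_nm3,
                "spot_positions": pl.spot_positions_nm().tolist(),
                "field": fld,
            }
        )
    gt = SceneGroundTruth(records, field_nm / size_px, size_px, packer.field_index + 1, field_nm)
    return placements, gt


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

@dataclass
class Topograph:
    """AFM height map: heights in nm on a square pixel grid."""

    heights: np.ndarray
    scale: float  # nm per pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def write(self, tiff_path) -> None:
        tifffile.imwrite(str(tiff_path), self.heights.astype(np.float32))
        sidecar = str(tiff_path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"scale_nm_per_px": self.scale, **self.metadata}, fh, sort_keys=True, indent=2)
            fh.write("\n")

    @classmethod
    def read(cls, tiff_path) -> "Topograph":
        heights = tifffile.imread(str(tiff_path)).astype(float)
        sidecar = str(tiff_path) + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        scale = float(meta.pop("scale_nm_per_px"))
        return cls(heights, scale, meta)


def _spherical_cap_structure(tip_radius_nm: float, scale: float) -> np.ndarray:
    r_px = int(np.ceil(tip_radius_nm / scale))
    ax = np.arange(-r_px, r_px + 1) * scale
    X, Y = np.meshgrid(ax, ax)
    r2 = X * X + Y * Y
    cap = np.full(X.shape, -1e9)
    inside = r2 <= tip_radius_nm**2
    cap[inside] = np.sqrt(tip_radius_nm**2 - r2[inside]) - tip_radius_nm
    return cap


def _stamp_polyline(img: np.ndarray, verts: np.ndarray, closed: bool, scale: float,
                    height: float, sigma: float) -> None:
    """Max-blend a Gaussian-cross-section ridge along a polyline (nm coords)."""
    v = np.vstack([verts, verts[:1]]) if closed else verts
    seg = np.diff(v, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    spacing = 0.3 * scale
    pts = [v[:1]]
    for a, d, ln in zip(v[:-1], seg, lens):
        if ln == 0:
            continue
        n = max(1, int(np.ceil(ln / spacing)))
        t = (np.arange(n) + 1.0) / n
        pts.append(a + t[:, None] * d)
    samples = np.vstack(pts)
    w = int(np.ceil(3 * sigma / scale))
    n_px = img.shape[0]
    off = np.arange(-w, w + 1)
    OY, OX = np.meshgrid(off, off, indexing="ij")
    for x, y in samples:
        col = x / scale
        row = y / scale
        ic, ir = int(round(col)), int(round(row))
        r0, r1 = ir - w, ir + w + 1
        c0, c1 = ic - w, ic + w + 1
        if r1 <= 0 or c1 <= 0 or r0 >= n_px or c0 >= n_px:
            continue
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, n_px), min(c1, n_px)
        sub_oy = OY[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        sub_ox = OX[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        d2 = ((ir + sub_oy) * scale - y) ** 2 + ((ic + sub_ox) * scale - x) ** 2
        patch = height * np.exp(-d2 / (2 * sigma * sigma))
        np.maximum(img[rr0:rr1, cc0:cc1], patch, out=img[rr0:rr1, cc0:cc1])


def render_topograph(
    objects: Iterable,
    scale_nm_per_px: float = DEFAULT_FIELD_NM / DEFAULT_SIZE_PX,
    tip_radius_nm: float = 0.0,
    noise_rms_nm: float = 0.0,
    line_offset_rms_nm: float = 0.0,
    seed: int = 0,
    size_px: int = DEFAULT_SIZE_PX,
    dna_height_nm: float = DEFAULT_DNA_HEIGHT_NM,
    dna_sigma_nm: float = DEFAULT_DNA_SIGMA_NM,
) -> Topograph:
    """Rasterise chains and particles, then apply tip broadening and noise.

    DNA is drawn as a ridge with Gaussian cross-section (peak height
    ``dna_height_nm``); particles evaluate their templates. Tip convolution
    is a grayscale dilation with a spherical-cap structuring element of the
    given radius (radius 0 is a no-op). Per-scanline offsets and per-pixel
    Gaussian noise are added last.
    """
    if scale_nm_per_px <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    img = np.zeros((size_px, size_px))
    field_nm = size_px * scale_nm_per_px
    clipped = 0
    for obj in objects:
        if isinstance(obj, WlcChain):
            if obj.vertices.min() < 0 or obj.vertices.max() > field_nm:
                clipped += 1
            _stamp_polyline(img, obj.vertices, obj.closed, scale_nm_per_px, dna_height_nm, dna_sigma_nm)
        elif isinstance(obj, ParticlePlacement):
            tpl, (cx, cy), ang = obj.template, obj.center, obj.angle
            r = tpl.radius_nm
            if cx - r < 0 or cy - r < 0 or cx + r > field_nm or cy + r > field_nm:
                clipped += 1
            c0 = max(0, int((cx - r) / scale_nm_per_px))
            c1 = min(size_px, int((cx + r) / scale_nm_per_px) + 1)
            r0 = max(0, int((cy - r) / scale_nm_per_px))
            r1 = min(size_px, int((cy + r) / scale_nm_per_px) + 1)
            if c1 <= c0 or r1 <= r0:
                continue
            X = (np.arange(c0, c1) * scale_nm_per_px)[None, :] - cx
            Y = (np.arange(r0, r1) * scale_nm_per_px)[:, None] - cy
            ca, sa = np.cos(-ang), np.sin(-ang)
            Xl = ca * X - sa * Y
            Yl = sa * X + ca * Y
            patch = tpl.evaluate(Xl, Yl)
            np.maximum(img[r0:r1, c0:c1], patch, out=img[r0:r1, c0:c1])
        else:
            raise TypeError(f"cannot render object of type {type(obj)!r}")
    if clipped:
        warnings.warn(f"{clipped} object(s) extend outside the field and were clipped")
    if tip_radius_nm > 0:
        img = grey_dilation(img, structure=_spherical_cap_structure(tip_radius_nm, scale_nm_per_px))
        img = np.clip(img, 0.0, None)
    if line_offset_rms_nm > 0:
        img = img + rng.normal(0.0, line_offset_rms_nm, size=size_px)[:, None]
    if noise_rms_nm > 0:
        img = img + rng.normal(0.0, noise_rms_nm, size=img.shape)
    meta = {
        "seed": seed,
        "tip_radius_nm": tip_radius_nm,
        "noise_rms_nm": noise_rms_nm,
        "line_offset_rms_nm": line_offset_rms_nm,
        "dna_height_nm": dna_height_nm,
        "dna_sigma_nm": dna_sigma_nm,
    }
    return Topograph(img, scale_nm_per_px, meta)


def render_scene(
    objects: Sequence,
    gt: SceneGroundTruth,
    tip_radius_nm: float = 0.0,
    noise_rms_nm: float = 0.0,
    line_offset_rms_nm: float = 0.0,
    seed: int = 0,
    **kw,
) -> list[Topograph]:
    """Render one Topograph per field of a packed scene."""
    out = []
    for fld in range(gt.n_fields):
        objs = [o for o, rec in zip(objects, gt.molecules) if rec["field"] == fld]
        out.append(
            render_topograph(
                objs,
                scale_nm_per_px=gt.scale_nm_per_px,
                tip_radius_nm=tip_radius_nm,
                noise_rms_nm=noise_rms_nm,
                line_offset_rms_nm=line_offset_rms_nm,
                seed=seed + 7919 * fld,
                size_px=gt.image_size_px,
                **kw,
            )
        )
    return out


# --------------------------------------------------------------------------
# Titration generator
# --------------------------------------------------------------------------

def generate_titration(
    model: str,
    params,
    conc_grid,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    probe_conc: float = 5.0,
) -> list[Titration]:
    """Simulate anisotropy titrations from a chosen model plus Gaussian noise.

    ``model`` is one of ``hyperbolic``, ``ic50``, ``tight_binding`` or
    ``mechanistic``. For ``mechanistic`` the signal is computed from the
    exact competition equilibrium (``params`` is a dict with ``r_tot``,
    ``k_p``, ``k_c`` and optional ``b_ini``/``amp``), so the apparent IC50
    emerges from mass action rather than being imposed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(conc_grid, dtype=float)
    if model == "hyperbolic":
        assert isinstance(params, HyperbolicParams)
        clean = hyperbolic_model(x, params)
        mode = "direct"
    elif model == "ic50":
        assert isinstance(params, Ic50Params)
        clean = ic50_model(x, params)
        mode = "competition"
    elif model == "tight_binding":
        assert isinstance(params, TightBindingParams)
        clean = tight_binding_model(x, probe_conc, params)
        mode = "tight_binding"
    elif model == "mechanistic":
        p = dict(params)
        amp = p.get("amp", 100.0)
        b0 = p.get("b_ini", 0.0)
        clean = np.array(
            [
                b0
                + amp
                * solve_competition_equilibrium(
                    CompetitionSystem(p["r_tot"], probe_conc, dc, p["k_p"], p["k_c"])
                )[1]
                for dc in x
            ]
        )
        mode = "competition"
    else:
        raise ValueError(f"unknown model {model!r}")
    out = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
        out.append(Titration(conc=x.copy(), signal=clean + noise, probe_conc=probe_conc, mode=mode, replicate=rep))
    return out
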