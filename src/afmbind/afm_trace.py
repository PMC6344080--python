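"""DNA quantification on AFM topographs.

Workflow: per-scanline flattening, ridge thresholding, skeleton-based
contour tracing, Gaussian fitting of the length histogram, cumulative
frequency curves, and classification of contour-length multimers as the
signature of intermolecular DNA bridging.

Lengths are in nm throughout; pixel-centre coordinates, 0-based rows and
columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import label
from skimage.morphology import skeletonize

from .synthetic import RISE_PER_BP_NM, Topograph

__all__ = [
    "TracedMolecule",
    "LengthDistribution",
    "BridgingReport",
    "flatten",
    "trace_dna",
    "expected_contour_length",
    "fit_length_histogram",
    "cumulative_frequency",
    "classify_bridging",
    "write_molecule_table",
    "read_molecule_table",
]

_SQRT2 = math.sqrt(2.0)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class TracedMolecule:
    """One traced DNA backbone. ``path`` is (N, 2) pixel-centre (x, y) nm."""

    path: np.ndarray
    contour_nm: float
    is_closed: bool = False
    touches_border: bool = False
    excluded_reason: str | None = None
    mol_id: int = -1

    @property
    def valid(self) -> bool:
        return self.excluded_reason is None


@dataclass
class LengthDistribution:
    """Sample of contour lengths with a single-Gaussian histogram fit."""

    lengths: np.ndarray
    mu: float
    sigma: float
    fit_ok: bool


@dataclass
class BridgingReport:
    """Multimer census relative to a monomer control distribution."""

    n_total: int
    pct_above_threshold: float
    pct_multimer_exact: dict[int, float]
    pct_2x: float
    pct_3x_plus: float
    threshold_nm: float

    def to_json(self, path=None) -> str:
        payload = {
            "n_total": self.n_total,
            "pct_above_threshold": self.pct_above_threshold,
            "pct_multimer_exact": {str(k): v for k, v in sorted(self.pct_multimer_exact.items())},
            "pct_2x": self.pct_2x,
            "pct_3x_plus": self.pct_3x_plus,
            "threshold_nm": self.threshold_nm,
        }
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# --------------------------------------------------------------------------
# Flattening
# --------------------------------------------------------------------------

def flatten(t: Topograph, order: int = 1) -> Topograph:
    """Remove per-scanline polynomial background and a global plane.

    The background estimate is computed on a foreground-masked copy: pixels
    above median + 2 robust-SD (1.4826 * MAD) are treated as features and
    excluded from the fits. Afterwards the background median is ~0.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    h = t.heights.copy()
    med = np.median(h)
    mad = np.median(np.abs(h - med))
    fg = h > med + 2.0 * 1.4826 * mad
    cols = np.arange(h.shape[1], dtype=float)
    for i in range(h.shape[0]):
        bg = ~fg[i]
        if bg.sum() < order + 2:
            bg = np.ones_like(bg)
        if order == 0:
            h[i] -= np.median(h[i][bg])
        else:
            coef = np.polyfit(cols[bg], h[i][bg], order)
            h[i] -= np.polyval(coef, cols)
    # global plane on background pixels
    rows = np.arange(h.shape[0], dtype=float)
    C, R = np.meshgrid(cols, rows)
    bg = ~fg
    A = np.column_stack([np.ones(bg.sum()), C[bg], R[bg]])
    coef, *_ = np.linalg.lstsq(A, h[bg], rcond=None)
    h -= coef[0] + coef[1] * C + coef[2] * R
    h -= np.median(h[bg])
    return Topograph(h, t.scale, {**t.metadata, "flattened_order": order})


# --------------------------------------------------------------------------
# Tracing
# --------------------------------------------------------------------------

def _skeleton_adjacency(pixels: set[tuple[int, int]]) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """8-connected adjacency with spurious diagonals dropped.

    A diagonal link is kept only when the two pixels share no 4-connected
    skeleton neighbour; otherwise the path through that neighbour already
    connects them and the diagonal would create a phantom triangle.
    """
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pixels}
    for r, c in pixels:
        for dr, dc in ((0, 1), (1, 0)):
            q = (r + dr, c + dc)
            if q in pixels:
                adj[(r, c)].append(q)
                adj[q].append((r, c))
        for dr, dc in ((1, 1), (1, -1)):
            q = (r + dr, c + dc)
            if q in pixels:
                if (r, c + dc) in pixels or (r + dr, c) in pixels:
                    continue
                adj[(r, c)].append(q)
                adj[q].append((r, c))
    return adj


def _step_len(a: tuple[int, int], b: tuple[int, int]) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _prune_spurs(adj, prune_px: float) -> None:
    """Iteratively remove endpoint branches shorter than ``prune_px``.

    Only branches terminating at a junction (degree >= 3) are spurs; a free
    path between two endpoints is a molecule and is never pruned.
    """
    while True:
        removed_any = False
        for ep in [p for p, nb in adj.items() if len(nb) == 1]:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            branch = [ep]
            length = 0.0
            prev, cur = None, ep
            reached_junction = False
            while True:
                nbs = [q for q in adj[cur] if q != prev]
                if not nbs:
                    break
                nxt = nbs[0]
                length += _step_len(cur, nxt)
                if len(adj[nxt]) >= 3:
                    reached_junction = True
                    break
                prev, cur = cur, nxt
                branch.append(cur)
                if length >= prune_px:
                    break
            if reached_junction and length < prune_px:
                for p in branch:
                    for q in adj[p]:
                        adj[q] = [z for z in adj[q] if z != p]
                    del adj[p]
                removed_any = True
        if not removed_any:
            break


def _walk_path(adj, start) -> tuple[list[tuple[int, int]], float]:
    path = [start]
    length = 0.0
    prev = None
    cur = start
    while True:
        nbs = [q for q in adj[cur] if q != prev]
        if not nbs:
            break
        nxt = nbs[0]
        length += _step_len(cur, nxt)
        path.append(nxt)
        prev, cur = cur, nxt
        if cur == start:
            break
    return path, length


def _smooth_path(path: np.ndarray, window: int, closed: bool) -> np.ndarray:
    """Moving-average smoothing of the pixel path (wraps for closed loops).

    Chain-code lengths with 1 / sqrt(2) steps overestimate the length of
    lines at intermediate orientations by up to ~8%; averaging the path
    coordinates over a few pixels removes most of that staircase bias.
    """
    n = len(path)
    if n < window:
        return path
    k = window // 2
    if closed:
        ext = np.vstack([path[-k:], path, path[:k]])
    else:
        ext = np.vstack([path[0] + (path[0] - path[k:0:-1]), path, path[-1] + (path[-1] - path[-2 : -k - 2 : -1])])
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(ext[:, j], kernel, mode="valid") for j in range(2)]
    )
    return sm


def trace_dna(
    t: Topograph,
    height_threshold_nm: float = 0.25,
    min_length_nm: float = 20.0,
    prune_nm: float = 8.0,
    smooth_window: int | None = None,
) -> list[TracedMolecule]:
    """Trace DNA backbones: threshold, skeletonise, prune, extract paths.

    Step lengths are 1 px laterally and sqrt(2) px diagonally, scaled to nm.
    ``smooth_window`` (e.g. 5) optionally smooths the path coordinates
    before the length sum, suppressing the staircase overestimate of the
    raw chain code. Closed skeletons are reported with ``is_closed``.
    Components that touch the image border or retain more than two
    endpoints after spur pruning (branched or crossing molecules) are
    excluded with a reason.
    """
    h = t.heights
    scale = t.scale
    mask = h > height_threshold_nm
    if not mask.any():
        return []
    labels = label(mask, connectivity=2)
    out: list[TracedMolecule] = []
    mol_id = 0
    for lab_idx in range(1, labels.max() + 1):
        comp = labels == lab_idx
        if comp.sum() < max(3, int(min_length_nm / scale)):
            continue
        rows, colsn = np.nonzero(comp)
        touches = (
            rows.min() == 0
            or colsn.min() == 0
            or rows.max() == h.shape[0] - 1
            or colsn.max() == h.shape[1] - 1
        )
        skel = skeletonize(comp)
        pixels = set(zip(*map(list, np.nonzero(skel))))
        if len(pixels) < 2:
            continue
        adj = _skeleton_adjacency(pixels)
        _prune_spurs(adj, prune_nm / scale)
        if not adj:
            continue
        degs = {p: len(nb) for p, nb in adj.items()}
        endpoints = [p for p, d in degs.items() if d == 1]
        junctions = [p for p, d in degs.items() if d >= 3]

        def finish(path_px, length_px, closed, reason=None):
            nonlocal mol_id
            path_nm = np.array([[c * scale, r * scale] for r, c in path_px])
            if smooth_window and reason is None and len(path_nm) >= smooth_window:
                if closed and path_nm.shape[0] > 1 and np.allclose(path_nm[0], path_nm[-1]):
                    path_nm = path_nm[:-1]
                path_nm = _smooth_path(path_nm, smooth_window, closed)
                contour = float(np.sum(np.linalg.norm(np.diff(path_nm, axis=0), axis=1)))
                if closed:
                    contour += float(np.linalg.norm(path_nm[0] - path_nm[-1]))
            else:
                contour = length_px * scale
            if reason is None and contour < min_length_nm:
                return
            out.append(
                TracedMolecule(path_nm, contour, closed, touches, reason, mol_id)
            )
            mol_id += 1

        if touches:
            finish([next(iter(adj))], 0.0, False, "border")
            continue
        if junctions or len(endpoints) > 2:
            finish([next(iter(adj))], 0.0, False, "branched")
            continue
        if len(endpoints) == 2:
            path, length = _walk_path(adj, endpoints[0])
            finish(path, length, False)
        elif len(endpoints) == 0:
            path, length = _walk_path(adj, next(iter(adj)))
            finish(path, length, True)
    return out


def expected_contour_length(n_bp: int, rise_per_bp: float = RISE_PER_BP_NM) -> float:
    """Expected B-DNA contour: n_bp * 0.34 nm."""
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    return n_bp * rise_per_bp


# --------------------------------------------------------------------------
# Length statistics
# --------------------------------------------------------------------------

def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma * sigma))


def fit_length_histogram(lengths: Sequence[float], bins="fd") -> LengthDistribution:
    """Single-Gaussian least-squares fit to the binned length histogram.

    A single dominant mode is assumed; minority populations (e.g. a small
    multimer fraction) perturb the fitted mean far less than they would a
    sample mean. Degenerate input (all lengths equal) returns the common
    value with ``fit_ok=False``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 20:
        raise ValueError("need at least 20 lengths for a histogram fit")
    if np.ptp(lengths) == 0:
        return LengthDistribution(lengths, float(lengths[0]), 0.0, False)
    counts, edges = np.histogram(lengths, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [counts.max(), centers[np.argmax(counts)], max(np.std(lengths) / 2, np.diff(edges).mean())]
    try:
        popt, _ = curve_fit(_gauss, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError:
        return LengthDistribution(lengths, float(np.mean(lengths)), float(np.std(lengths)), False)
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    if a <= 0 or sigma == 0 or not np.isfinite(mu):
        return LengthDistribution(lengths, float(np.mean(lengths)), float(np.std(lengths)), False)
    return LengthDistribution(lengths, float(mu), sigma, True)


def cumulative_frequency(lengths: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous survival curve: fraction of molecules >= length.

    Returns (x, y) where x is the sorted lengths prefixed with 0 and y the
    fraction of molecules at least that long (1 at length 0).
    """
    lengths = np.sort(np.asarray(lengths, dtype=float))
    if lengths.size == 0:
        raise ValueError("no lengths")
    n = lengths.size
    x = np.concatenate([[0.0], lengths])
    # at x = lengths[i], the fraction of molecules >= x is (n - i)/n
    y = np.concatenate([[1.0], (n - np.arange(n)) / n])
    return x, y


def survival_at(lengths: Sequence[float], at: float) -> float:
    """Evaluate the cumulative-frequency curve at a single length."""
    lengths = np.asarray(lengths, dtype=float)
    return float(np.mean(lengths >= at))


def classify_bridging(
    lengths: Sequence[float],
    control: LengthDistribution,
    k_max: int = 5,
    window_sd: float | None = None,
) -> BridgingReport:
    """Census of contour-length multimers against a monomer control.

    Threshold = control mean + 1 SD; a molecule counts as an exact k-mer
    when its length falls within k*mu +/- 2 sigma (control sigma by
    default; pass ``window_sd`` to use another SD). Windows for k=2..k_max
    are mutually exclusive, which requires sigma < mu/4.
    """
    if not control.fit_ok:
        raise ValueError("control distribution fit failed; cannot classify")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no lengths to classify")
    mu, sigma = control.mu, control.sigma if window_sd is None else window_sd
    if sigma >= mu / 4:
        raise ValueError(
            "multimer windows overlap (sigma >= mu/4); tighten the tracing "
            "or the control fit before classifying"
        )
    threshold = mu + control.sigma
    n = lengths.size
    pct_above = 100.0 * float(np.mean(lengths > threshold))
    pct_exact: dict[int, float] = {}
    for k in range(2, k_max + 1):
        in_win = (lengths >= k * mu - 2 * sigma) & (lengths <= k * mu + 2 * sigma)
        # sub-monomer fragments are never multimers (windows start > mu anyway)
        in_win &= lengths >= 0.5 * mu
        pct_exact[k] = 100.0 * float(np.mean(in_win))
    pct_2x = pct_exact.get(2, 0.0)
    pct_3x_plus = float(sum(v for k, v in pct_exact.items() if k >= 3))
    return BridgingReport(n, pct_above, pct_exact, pct_2x, pct_3x_plus, threshold)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_molecule_table(path, molecules: Sequence[TracedMolecule]) -> None:
    """TSV per-molecule table: id, contour_nm, is_closed, excluded_reason."""
    with open(path, "w") as fh:
        fh.write("id\tcontour_nm\tis_closed\texcluded_reason\n")
        for m in molecules:
            reason = m.excluded_reason or ""
            fh.write(f"{m.mol_id}\t{m.contour_nm:.6f}\t{int(m.is_closed)}\t{reason}\n")


def read_molecule_table(path) -> list[TracedMolecule]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["id", "contour_nm"]:
            raise ValueError("not a molecule table")
        for line in fh:
            fid, contour, closed, reason = (line.rstrip("\n").split("\t") + [""])[:4]
            out.append(
                TracedMolecule(
                    path=np.empty((0, 2)),
                    contour_nm=float(contour),
                    is_closed=bool(int(closed)),
                    excluded_reason=reason or None,
                    mol_id=int(fid),
                )
            )
    return out
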