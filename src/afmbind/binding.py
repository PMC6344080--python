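"""Equilibrium binding analysis by fluorescence anisotropy.

Implements the standard isotherm models used to quantify protein-DNA
interactions in solution:

* anisotropy from polarised emission intensities,
* percent-of-maximum-change normalisation,
* the simple binding hyperbola (non-depleting regime),
* a hyperbolic decay for competition (unbinding) titrations, yielding IC50,
* the Morrison-type tight-binding quadratic with an explicit stoichiometry
  ``n`` (binding units per DNA molecule), fitted globally across probe
  concentrations,
* an exact mechanistic competition equilibrium (one receptor, two DNA
  ligands) used as an independent oracle for what an IC50 can and cannot
  report.

Concentrations are in nM throughout; protein concentrations refer to the
tetramer unless a caller states otherwise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "IntensityPair",
    "Titration",
    "HyperbolicParams",
    "Ic50Params",
    "TightBindingParams",
    "CompetitionSystem",
    "FitResult",
    "compute_anisotropy",
    "normalize_signal",
    "denormalize_signal",
    "normalize_titration",
    "hyperbolic_model",
    "ic50_model",
    "tight_binding_model",
    "fraction_bound",
    "fit_hyperbolic",
    "fit_ic50",
    "fit_stoichiometry_global",
    "solve_competition_equilibrium",
    "read_titration_csv",
    "write_titration_csv",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityPair:
    """Polarised emission intensities (vertical excitation).

    ``i_vv``: vertical/vertical component, ``i_vh``: vertical/horizontal.
    Arbitrary units; the anisotropy is a pure ratio.
    """

    i_vv: float
    i_vh: float

    def __post_init__(self) -> None:
        if self.i_vv < 0 or self.i_vh < 0:
            raise ValueError("intensities must be non-negative")


TitrationMode = Literal["direct", "competition", "tight_binding"]


@dataclass
class Titration:
    """One titration series: titrant concentration vs anisotropy signal.

    ``conc`` is the titrant concentration in nM (protein tetramer for direct
    and tight-binding assays, competitor DNA for competition assays).
    ``probe_conc`` is the labelled-DNA concentration in nM.
    """

    conc: np.ndarray
    signal: np.ndarray
    probe_conc: float
    mode: TitrationMode
    replicate: int = 0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.conc.ndim != 1 or self.conc.shape != self.signal.shape:
            raise ValueError("conc and signal must be 1-D and equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be positive")
        if self.mode not in ("direct", "competition", "tight_binding"):
            raise ValueError(f"unknown mode {self.mode!r}")
        order = np.argsort(self.conc, kind="stable")
        self.conc = self.conc[order]
        self.signal = self.signal[order]

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.conc).size)


@dataclass(frozen=True)
class HyperbolicParams:
    """Simple hyperbola: signal = b_max*c/(k_d + c) + c0."""

    b_max: float
    k_d: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_d > 0:
            raise ValueError("k_d must be positive")
        if not math.isfinite(self.b_max):
            raise ValueError("b_max must be finite")


@dataclass(frozen=True)
class Ic50Params:
    """Hyperbolic decay: signal = b_ini - c*x/(ic50 + x)."""

    c: float
    ic50: float
    b_ini: float

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError("ic50 must be positive")
        if self.c < 0:
            raise ValueError("amplitude c must be >= 0")


@dataclass(frozen=True)
class TightBindingParams:
    """Morrison-type quadratic with stoichiometry n (tetramers per DNA)."""

    b_max: float
    k_d: float
    n: float
    b_ini: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_d > 0:
            raise ValueError("k_d must be positive")
        if not self.n > 0:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class CompetitionSystem:
    """One receptor species, labelled probe DNA and unlabelled competitor.

    ``r_tot``: total binding-unit concentration; ``dp_tot``/``dc_tot``:
    total probe and competitor DNA; ``k_p``/``k_c``: their dissociation
    constants. All nM.
    """

    r_tot: float
    dp_tot: float
    dc_tot: float
    k_p: float
    k_c: float

    def __post_init__(self) -> None:
        if min(self.r_tot, self.dp_tot, self.dc_tot) < 0:
            raise ValueError("concentrations must be non-negative")
        if not (self.k_p > 0 and self.k_c > 0):
            raise ValueError("dissociation constants must be positive")


_PARAM_ORDER = ("b_max", "k_d", "c", "ic50", "b_ini", "n")


@dataclass
class FitResult:
    """Outcome of a least-squares fit of one binding model."""

    params: object
    stderr: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    message: str = ""
    extra: dict = field(default_factory=dict)

    def param_dict(self) -> dict[str, float]:
        d = {}
        for name in _PARAM_ORDER:
            if hasattr(self.params, name):
                d[name] = float(getattr(self.params, name))
        return d

    def to_json(self, path=None) -> str:
        payload = self.param_dict()
        payload["stderr"] = {k: float(v) for k, v in self.stderr.items()}
        payload["rss"] = float(self.rss)
        payload["n_points"] = int(self.n_points)
        payload["converged"] = bool(self.converged)
        if self.message:
            payload["message"] = self.message
        payload.update({k: v for k, v in self.extra.items()})
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------

def compute_anisotropy(pair: IntensityPair) -> float:
    """Anisotropy r = (I_VV - I_VH) / (I_VV + 2 I_VH).

    Raises ValueError on a degenerate (zero) denominator.
    """
    denom = pair.i_vv + 2.0 * pair.i_vh
    if denom <= 0:
        raise ValueError("degenerate intensities: i_vv + 2*i_vh must be > 0")
    return (pair.i_vv - pair.i_vh) / denom


def normalize_signal(a, a_min: float, a_max: float):
    """Percent-of-maximum-change normalisation: 100*(a - a_min)/(a_max - a_min)."""
    if not a_max > a_min:
        raise ValueError("a_max must exceed a_min")
    return 100.0 * (np.asarray(a, dtype=float) - a_min) / (a_max - a_min)


def denormalize_signal(pct, a_min: float, a_max: float):
    """Inverse of :func:`normalize_signal`."""
    if not a_max > a_min:
        raise ValueError("a_max must exceed a_min")
    return a_min + np.asarray(pct, dtype=float) * (a_max - a_min) / 100.0


def hyperbolic_model(conc, p: HyperbolicParams):
    """Non-depleting binding hyperbola; ``conc`` is free ≈ total titrant (nM)."""
    conc = np.asarray(conc, dtype=float)
    return p.b_max * conc / (p.k_d + conc) + p.c


def ic50_model(comp_conc, p: Ic50Params):
    """Hyperbolic decay of the probe signal with competitor concentration."""
    x = np.asarray(comp_conc, dtype=float)
    return p.b_ini - p.c * x / (p.ic50 + x)


def tight_binding_model(ctip_conc, dna_conc: float, p: TightBindingParams):
    """Ligand-depletion (Morrison) quadratic with effective sites S = n*[DNA].

    Returns b_ini + b_max * bound_fraction where bound_fraction is the
    occupied fraction of the S sites, the exact solution of
    ``R + D <-> RD`` with totals P (protein) and S.
    """
    if dna_conc <= 0:
        raise ValueError("dna_conc must be positive")
    P = np.asarray(ctip_conc, dtype=float)
    if np.any(P < 0):
        raise ValueError("protein concentrations must be non-negative")
    S = p.n * dna_conc
    b = P + S + p.k_d
    disc = b * b - 4.0 * P * S
    if np.any(disc < 0):
        warnings.warn("negative discriminant clamped to 0 (numerical)", RuntimeWarning)
        disc = np.clip(disc, 0.0, None)
    bound = (b - np.sqrt(disc)) / (2.0 * S)
    return p.b_ini + p.b_max * bound


def fraction_bound(ctip_conc: float, k_d: float) -> float:
    """Hyperbolic probe occupancy c/(K_d + c) in the non-depleting regime."""
    if ctip_conc <= 0 or k_d <= 0:
        raise ValueError("ctip_conc and k_d must be positive")
    return ctip_conc / (k_d + ctip_conc)


# --------------------------------------------------------------------------
# Mechanistic competition equilibrium (independent oracle for IC50 meaning)
# --------------------------------------------------------------------------

def solve_competition_equilibrium(sys: CompetitionSystem) -> tuple[float, float, float]:
    """Exact free-receptor concentration for one receptor and two ligands.

    Solves ``R * (1 + dp/(k_p+R) + dc/(k_c+R)) = r_tot`` for the free
    receptor R by monotone bracketing on [0, r_tot], then returns
    ``(free_r, probe_bound_fraction, comp_bound_fraction)`` where the bound
    fractions are R/(K+R) for each DNA species.
    """
    if sys.r_tot == 0:
        return 0.0, 0.0, 0.0

    def f(r: float) -> float:
        return r * (1.0 + sys.dp_tot / (sys.k_p + r) + sys.dc_tot / (sys.k_c + r)) - sys.r_tot

    # f is strictly increasing; f(0) = -r_tot < 0, f(r_tot) >= 0.
    free_r = brentq(f, 0.0, sys.r_tot, xtol=1e-300, rtol=1e-15, maxiter=200)
    fp = free_r / (sys.k_p + free_r)
    fc = free_r / (sys.k_c + free_r)
    return float(free_r), float(fp), float(fc)


# --------------------------------------------------------------------------
# Fitting engine
# --------------------------------------------------------------------------

_LSQ_KW = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)


def _multistart_lsq(
    residual: Callable[[np.ndarray], np.ndarray],
    p0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    n_starts: int = 5,
    seed: int = 0,
):
    """Bounded least squares from ``n_starts`` perturbed starting points.

    Start 0 is the data-driven guess itself; further starts scatter each
    parameter by a log-normal factor (positive parameters) or a normal
    perturbation, to guard against local minima.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    best = None
    for k in range(max(1, n_starts)):
        if k == 0:
            start = p0.copy()
        else:
            start = p0 * np.exp(rng.normal(0.0, 0.7, size=p0.shape))
            flat = p0 == 0
            start[flat] = rng.normal(0.0, 1.0, size=int(flat.sum()))
        start = np.clip(start, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, start))
        try:
            sol = least_squares(residual, start, bounds=bounds, **_LSQ_KW)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _stderr_from_jac(sol, n_params: int) -> np.ndarray:
    m = sol.fun.size
    rss = float(2.0 * sol.cost)
    dof = m - n_params
    if dof <= 0:
        return np.full(n_params, np.inf)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.inf)
    return se


def fit_hyperbolic(t: Titration, n_starts: int = 5, seed: int = 0) -> FitResult:
    """Fit the binding hyperbola (b_max, k_d, c) to a direct titration."""
    if t.mode != "direct":
        raise ValueError("fit_hyperbolic requires a direct-mode titration")
    if t.n_distinct < 4:
        raise ValueError(
            "need >= 4 distinct titrant concentrations; the model is "
            "unidentifiable on this design"
        )
    x, y = t.conc, t.signal
    span = float(y.max() - y.min())
    p0 = np.array([span if span > 0 else 1.0, max(np.median(x[x > 0]), 1e-3), float(y.min())])
    lo = np.array([-np.inf, 1e-12, -np.inf])
    hi = np.array([np.inf, np.inf, np.inf])

    def residual(p):
        return p[0] * x / (p[1] + x) + p[2] - y

    sol = _multistart_lsq(residual, p0, (lo, hi), n_starts, seed)
    if sol is None or not sol.success:
        return FitResult(None, {}, math.inf, x.size, False, "optimizer failed")
    se = _stderr_from_jac(sol, 3)
    params = HyperbolicParams(b_max=float(sol.x[0]), k_d=float(sol.x[1]), c=float(sol.x[2]))
    return FitResult(
        params,
        {"b_max": se[0], "k_d": se[1], "c": se[2]},
        float(2.0 * sol.cost),
        int(x.size),
        True,
    )


def fit_ic50(t: Titration, n_starts: int = 5, seed: int = 0) -> FitResult:
    """Fit the hyperbolic decay (c, ic50, b_ini) to a competition titration.

    A fitted amplitude indistinguishable from zero leaves the IC50
    unidentifiable; the result is then flagged ``converged=False``.
    """
    if t.mode != "competition":
        raise ValueError("fit_ic50 requires a competition-mode titration")
    if t.n_distinct < 4:
        raise ValueError("need >= 4 distinct competitor concentrations")
    x, y = t.conc, t.signal
    span = float(y.max() - y.min())
    p0 = np.array([span if span > 0 else 1.0, max(np.median(x[x > 0]), 1e-3), float(y.max())])
    lo = np.array([0.0, 1e-12, -np.inf])
    hi = np.array([np.inf, np.inf, np.inf])

    def residual(p):
        return p[2] - p[0] * x / (p[1] + x) - y

    sol = _multistart_lsq(residual, p0, (lo, hi), n_starts, seed)
    if sol is None or not sol.success:
        return FitResult(None, {}, math.inf, x.size, False, "optimizer failed")
    se = _stderr_from_jac(sol, 3)
    scale = max(float(np.max(np.abs(y))), 1.0)
    amp_zero = sol.x[0] < 1e-6 * scale
    params = Ic50Params(c=float(sol.x[0]), ic50=float(max(sol.x[1], 1e-12)), b_ini=float(sol.x[2]))
    res = FitResult(
        params,
        {"c": se[0], "ic50": se[1], "b_ini": se[2]},
        float(2.0 * sol.cost),
        int(x.size),
        not amp_zero,
    )
    if amp_zero:
        res.message = "amplitude ~ 0: no competition signal, ic50 unidentifiable"
    return res


def fit_stoichiometry_global(
    datasets: Sequence[Titration],
    fixed_kd: float,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Global tight-binding fit sharing the stoichiometry n across datasets.

    Each dataset (one probe-DNA concentration, well above ``fixed_kd``)
    contributes its own amplitude ``b_max`` and offset ``b_ini``; ``k_d`` is
    held at the independently measured value and a single ``n`` is shared.
    The derived DNA-per-binding-unit ratio 1/n is reported in ``extra``.
    """
    if fixed_kd <= 0:
        raise ValueError("fixed_kd must be positive")
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets")
    for t in datasets:
        if t.mode != "tight_binding":
            raise ValueError("all datasets must be tight_binding mode")
    probes = np.array([t.probe_conc for t in datasets])
    message = ""
    if len(datasets) >= 2 and np.unique(probes).size == 1:
        warnings.warn(
            "all datasets share one probe concentration: n is weakly identified",
            RuntimeWarning,
        )
        message = "identical probe concentrations: n weakly identified"

    xs = [t.conc for t in datasets]
    ys = [t.signal for t in datasets]
    m = len(datasets)
    # parameter vector: [n, b_max_1..m, b_ini_1..m]
    spans = [max(float(y.max() - y.min()), 1e-6) for y in ys]
    p0 = np.concatenate([[1.0], spans, [float(y.min()) for y in ys]])
    lo = np.concatenate([[1e-6], np.full(m, -np.inf), np.full(m, -np.inf)])
    hi = np.full(1 + 2 * m, np.inf)

    def residual(p):
        n = p[0]
        out = []
        for i in range(m):
            pp = TightBindingParams(b_max=1.0, k_d=fixed_kd, n=n, b_ini=0.0)
            bound = tight_binding_model(xs[i], datasets[i].probe_conc, pp)
            out.append(p[1 + i] * bound + p[1 + m + i] - ys[i])
        return np.concatenate(out)

    sol = _multistart_lsq(residual, p0, (lo, hi), n_starts, seed)
    n_total = int(sum(x.size for x in xs))
    if sol is None or not sol.success:
        return FitResult(None, {}, math.inf, n_total, False, "optimizer failed")
    n_par = 1 + 2 * m
    se = _stderr_from_jac(sol, n_par)
    n_hat = float(sol.x[0])
    params = TightBindingParams(
        b_max=float(sol.x[1]), k_d=fixed_kd, n=n_hat, b_ini=float(sol.x[1 + m])
    )
    stderr = {"n": float(se[0])}
    for i in range(m):
        stderr[f"b_max_{i}"] = float(se[1 + i])
        stderr[f"b_ini_{i}"] = float(se[1 + m + i])
    res = FitResult(params, stderr, float(2.0 * sol.cost), n_total, True, message)
    res.extra["dna_per_tetramer"] = 1.0 / n_hat
    res.extra["b_max_per_dataset"] = [float(v) for v in sol.x[1 : 1 + m]]
    res.extra["b_ini_per_dataset"] = [float(v) for v in sol.x[1 + m :]]
    if len(datasets) == 1 or se[0] > 0.5 * abs(n_hat):
        res.message = (res.message + "; " if res.message else "") + (
            "n poorly constrained (wide stderr); add probe concentrations "
            "well above K_d"
        )
    return res


# --------------------------------------------------------------------------
# Normalisation helpers and I/O
# --------------------------------------------------------------------------

def normalize_titration(t: Titration, mode: str = "observed") -> Titration:
    """Return a copy of ``t`` with the signal on the 0-100% scale.

    ``observed``: extremes from the data. ``fitted``: plateaus from a model
    fit (hyperbola for direct, decay for competition), which is robust to
    noise at the endpoints of the titration.
    """
    if mode == "observed":
        a_min, a_max = float(t.signal.min()), float(t.signal.max())
    elif mode == "fitted":
        if t.mode == "direct":
            fr = fit_hyperbolic(t)
            if not fr.converged:
                raise RuntimeError("plateau fit failed; use observed mode")
            a_min = fr.params.c
            a_max = fr.params.c + fr.params.b_max
        elif t.mode == "competition":
            fr = fit_ic50(t)
            if not fr.converged:
                raise RuntimeError("plateau fit failed; use observed mode")
            a_max = fr.params.b_ini
            a_min = fr.params.b_ini - fr.params.c
        else:
            raise ValueError("fitted-mode normalisation supports direct/competition")
    else:
        raise ValueError("mode must be 'observed' or 'fitted'")
    return Titration(
        conc=t.conc.copy(),
        signal=np.asarray(normalize_signal(t.signal, a_min, a_max)),
        probe_conc=t.probe_conc,
        mode=t.mode,
        replicate=t.replicate,
    )


def read_titration_csv(path, probe_conc: float, mode: TitrationMode) -> list[Titration]:
    """Read titrations from a CSV with header ``conc_nM,signal,replicate``."""
    df = pd.read_csv(path)
    required = {"conc_nM", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    if df[["conc_nM", "signal"]].isna().any().any():
        bad = df[df[["conc_nM", "signal"]].isna().any(axis=1)].index[0]
        raise ValueError(f"titration CSV has a missing/non-numeric value at row {bad + 2}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        out.append(
            Titration(
                conc=grp["conc_nM"].to_numpy(float),
                signal=grp["signal"].to_numpy(float),
                probe_conc=probe_conc,
                mode=mode,
                replicate=int(rep),
            )
        )
    return out


def write_titration_csv(path, titrations: Sequence[Titration]) -> None:
    frames = [
        pd.DataFrame(
            {"conc_nM": t.conc, "signal": t.signal, "replicate": t.replicate}
        )
        for t in titrations
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
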