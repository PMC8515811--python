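"""Absorption-spectrum construction and statistically optimal broadening.

A nuclear-ensemble spectrum is a per-snapshot average of Gaussian
kernels placed at the stick excitations:

    s(x) = (1/N_snap) · Σ_i Y_i · K_Δ(x − X_i),

with K_Δ a unit-area Gaussian density of standard deviation Δ, so the
curve integral equals the per-snapshot mean total oscillator strength
for any Δ.

The kernel width is selected without reference to experiment.  For a
candidate Δ, a global amplitude a(Δ) is fit by least squares between
the sticks Y_i and the kernel sum evaluated at the X_i; the width is
then scored by leave-one-out cross-validation,

    L_cv(Δ) = Σ_i ( Y_i − a(Δ)·ŝ_{−i}(X_i) )²,

where ŝ_{−i} omits record i, and the Δ minimizing L_cv is used.  As
the ensemble grows the optimal Δ shrinks (Δ → 0 as N → ∞): the
physical broadening lives in the ensemble, not in the kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import HC_EV_NM, KB_EV
from .io_formats import StickTable

#: single-geometry default width, eV — an empirical literature value for
#: solvated organic chromophores, not computed by this package
SINGLE_POINT_DELTA_EV = 0.14


@dataclass
class SpectrumCurve:
    """Continuous intensity-vs-axis curve with broadening metadata."""

    axis_kind: str            # 'energy-eV' | 'wavelength-nm'
    grid: np.ndarray
    values: np.ndarray
    delta: float | None = None
    n_snapshots: int | None = None
    normalization: str = "none"
    window: tuple | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.axis_kind not in ("energy-eV", "wavelength-nm"):
            raise ValueError(f"unknown axis kind {self.axis_kind!r}")


# ---------------------------------------------------------------------------
# kernel machinery
# ---------------------------------------------------------------------------

def _gauss(x, delta):
    return np.exp(-0.5 * (x / delta) ** 2) / (delta * math.sqrt(2.0 * math.pi))


def kernel_regression_estimate(sticks: StickTable, delta: float, x):
    """Raw kernel sum ŝ(x) = Σ_i Y_i·K_Δ(x − X_i) (no snapshot averaging)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(x, dtype=float)
    out = _gauss(x[..., None] - sticks.energies, delta) @ sticks.strengths
    return float(out) if out.ndim == 0 else out


def broaden_sticks(sticks: StickTable, delta: float,
                   grid: np.ndarray) -> SpectrumCurve:
    """Per-snapshot-averaged Gaussian broadening of a stick table."""
    if len(sticks) == 0:
        raise ValueError("empty stick table")
    n_snap = sticks.n_snapshots
    values = kernel_regression_estimate(sticks, delta, np.asarray(grid)) / n_snap
    return SpectrumCurve("energy-eV", grid, values, delta=delta,
                         n_snapshots=n_snap)


def single_point_spectrum(sticks: StickTable,
                          delta: float = SINGLE_POINT_DELTA_EV,
                          grid: np.ndarray | None = None) -> SpectrumCurve:
    """Spectrum from the sticks of one geometry (single-point approach)."""
    if sticks.n_snapshots != 1:
        raise ValueError("single-point spectrum requires exactly one snapshot")
    if grid is None:
        lo = sticks.energies.min() - 5 * delta
        hi = sticks.energies.max() + 5 * delta
        grid = np.linspace(lo, hi, 2001)
    return broaden_sticks(sticks, delta, grid)


def default_grid(sticks: StickTable, delta: float,
                 points: int = 2001) -> np.ndarray:
    """Energy grid covering [min X − 5Δ, max X + 5Δ]."""
    return np.linspace(sticks.energies.min() - 5 * delta,
                       sticks.energies.max() + 5 * delta, points)


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def _pairwise_sq(sticks: StickTable) -> np.ndarray:
    d = sticks.energies[:, None] - sticks.energies[None, :]
    return d * d


def _self_estimates(sticks, delta, d2=None):
    """ŝ(X_i) for all i, including the self term; O(N²) vectorized."""
    if d2 is None:
        d2 = _pairwise_sq(sticks)
    k = np.exp(-0.5 * d2 / (delta * delta)) / (delta * math.sqrt(2 * math.pi))
    return k @ sticks.strengths


def fit_amplitude(sticks: StickTable, delta: float, _d2=None) -> float:
    """Least-squares global amplitude a(Δ) = Σ Y_i ŝ(X_i) / Σ ŝ(X_i)²."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not np.any(sticks.strengths > 0):
        raise ValueError("degenerate fit: all oscillator strengths are zero")
    s_hat = _self_estimates(sticks, delta, _d2)
    return float(sticks.strengths @ s_hat / (s_hat @ s_hat))


def loo_cv_loss(sticks: StickTable, delta: float, _d2=None) -> float:
    """Leave-one-out loss L_cv(Δ) = Σ_i (Y_i − a(Δ)·ŝ_{−i}(X_i))².

    a(Δ) is the full-data amplitude; ŝ_{−i} drops record i, which for a
    Gaussian kernel is simply ŝ(X_i) − Y_i·K_Δ(0).
    """
    if len(sticks) < 2:
        raise ValueError("leave-one-out needs at least two records")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if _d2 is None:
        _d2 = _pairwise_sq(sticks)
    s_hat = _self_estimates(sticks, delta, _d2)
    a = float(sticks.strengths @ s_hat / (s_hat @ s_hat))
    k0 = 1.0 / (delta * math.sqrt(2 * math.pi))
    s_loo = s_hat - sticks.strengths * k0
    resid = sticks.strengths - a * s_loo
    return float(resid @ resid)


@dataclass
class BandwidthScan:
    """LOO-CV scan over kernel widths with the refined optimum."""

    deltas: np.ndarray
    cv_losses: np.ndarray
    optimum: float
    amplitude: float
    boundary_warning: bool = False

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.cv_losses = np.asarray(self.cv_losses, dtype=float)
        if np.any(self.deltas <= 0) or np.any(np.diff(self.deltas) <= 0):
            raise ValueError("delta grid must be positive and ascending")


def optimize_bandwidth(sticks: StickTable, delta_min: float = 5e-3,
                       delta_max: float = 0.5, n_grid: int = 25,
                       rel_tol: float = 1e-3) -> BandwidthScan:
    """Select Δ* by LOO-CV: log-spaced scan plus golden-section refinement.

    Ties are broken toward smaller Δ (less artificial smoothing).  A
    minimum on the scan boundary sets ``boundary_warning`` — the search
    range is then probably wrong for the data (or L_cv is flat, as for
    degenerate coincident sticks).
    """
    if not (0 < delta_min < delta_max):
        raise ValueError("need 0 < delta_min < delta_max")
    if n_grid < 10:
        raise ValueError("n_grid must be >= 10")
    d2 = _pairwise_sq(sticks)
    deltas = np.geomspace(delta_min, delta_max, n_grid)
    losses = np.array([loo_cv_loss(sticks, d, d2) for d in deltas])
    # tie-break toward smaller delta within 1 part in 1e12
    best = int(np.flatnonzero(losses <= losses.min() * (1 + 1e-12))[0])
    boundary = best in (0, n_grid - 1)
    if boundary:
        warnings.warn("L_cv minimum on the scan boundary; widen the range "
                      "or the loss is flat")
        optimum = float(deltas[best])
    else:
        lo, hi = math.log(deltas[best - 1]), math.log(deltas[best + 1])
        res = minimize_scalar(
            lambda t: loo_cv_loss(sticks, math.exp(t), d2),
            bracket=None, bounds=(lo, hi), method="bounded",
            options={"xatol": rel_tol})
        optimum = float(math.exp(res.x))
        if loo_cv_loss(sticks, float(deltas[best]), d2) < res.fun:
            optimum = float(deltas[best])
    return BandwidthScan(deltas, losses, optimum,
                         fit_amplitude(sticks, optimum, d2),
                         boundary_warning=boundary)


# ---------------------------------------------------------------------------
# simple broadening models and axis handling
# ---------------------------------------------------------------------------

def marcus_broadening(reorganization_energy: float,
                      temperature: float) -> float:
    """Gaussian solvent broadening σ = sqrt(2·k_B·T·E_r) (Marcus theory), eV."""
    if reorganization_energy < 0:
        raise ValueError("reorganization energy must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.sqrt(2.0 * KB_EV * temperature * reorganization_energy)


def convert_axis(curve: SpectrumCurve, target: str,
                 jacobian: bool = False) -> SpectrumCurve:
    """Convert between energy (eV) and wavelength (nm) axes.

    λ[nm] = 1239.84198 / E[eV] pointwise; the grid is re-sorted
    ascending.  With ``jacobian`` the intensities are multiplied by
    |dE/dλ| so that area is conserved; the default is a plain re-plot,
    appropriate when only area-normalized shapes are compared.
    """
    if target == curve.axis_kind:
        return curve
    if target not in ("energy-eV", "wavelength-nm"):
        raise ValueError(f"unknown target axis {target!r}")
    if np.any(curve.grid <= 0):
        raise ValueError("axis values must be positive for conversion")
    new_grid = HC_EV_NM / curve.grid
    values = curve.values.copy()
    if jacobian:
        # |d(source)/d(target)| = source²/hc for E·λ = hc, either direction
        values = values * curve.grid ** 2 / HC_EV_NM
    order = np.argsort(new_grid)
    return SpectrumCurve(target, new_grid[order], values[order],
                         delta=curve.delta, n_snapshots=curve.n_snapshots,
                         normalization=curve.normalization,
                         window=curve.window)


def normalize_window(curve: SpectrumCurve,
                     window: tuple = (300.0, 700.0)) -> SpectrumCurve:
    """Scale the curve so its trapezoidal area over ``window`` is 1."""
    lo, hi = window
    mask = (curve.grid >= lo) & (curve.grid <= hi)
    if mask.sum() < 2:
        raise ValueError(f"curve does not overlap the window [{lo}, {hi}]")
    area = np.trapezoid(curve.values[mask], curve.grid[mask])
    if area <= 0:
        raise ValueError("zero area in the normalization window")
    return SpectrumCurve(curve.axis_kind, curve.grid, curve.values / area,
                         delta=curve.delta, n_snapshots=curve.n_snapshots,
                         normalization="unit-area-window", window=(lo, hi))


def unit_area(curve: SpectrumCurve) -> SpectrumCurve:
    """Scale the curve to unit trapezoidal area over its whole grid."""
    area = np.trapezoid(curve.values, curve.grid)
    if area <= 0:
        raise ValueError("zero-area curve")
    return SpectrumCurve(curve.axis_kind, curve.grid, curve.values / area,
                         delta=curve.delta, n_snapshots=curve.n_snapshots,
                         normalization="unit-area", window=None)


# ---------------------------------------------------------------------------
# convergence with ensemble size
# ---------------------------------------------------------------------------

def convergence_profile(sticks: StickTable, subset_sizes, delta: float,
                        distance: str = "max-abs", n_random: int = 0,
                        seed: int = 0, grid: np.ndarray | None = None):
    """Distance of k-snapshot spectra to the full-ensemble spectrum.

    For each size k the spectrum is built from the first k snapshots
    (by id order of appearance) and, optionally, from ``n_random``
    random k-subsets.  All curves are normalized to unit area before
    comparison so only shapes are measured.

    Returns a dict: size -> {'first': d, 'random': [d, ...]}.
    """
    if distance not in ("max-abs", "L1"):
        raise ValueError("distance must be 'max-abs' or 'L1'")
    ids = list(dict.fromkeys(sticks.snapshots.tolist()))  # order of appearance
    n_ids = len(ids)
    if grid is None:
        grid = default_grid(sticks, delta)
    full = unit_area(broaden_sticks(sticks, delta, grid))

    def dist(curve):
        diff = np.abs(curve.values - full.values)
        if distance == "max-abs":
            return float(diff.max())
        return float(np.trapezoid(diff, grid))

    rng = np.random.default_rng(seed)
    out = {}
    for k in subset_sizes:
        if k > n_ids:
            raise ValueError(f"subset size {k} exceeds {n_ids} snapshots")
        first = unit_area(broaden_sticks(sticks.restrict(ids[:k]), delta, grid))
        entry = {"first": dist(first), "random": []}
        for _ in range(n_random):
            pick = rng.choice(n_ids, size=k, replace=False)
            sub = sticks.restrict([ids[i] for i in pick])
            entry["random"].append(dist(unit_area(broaden_sticks(sub, delta,
                                                                 grid))))
        out[int(k)] = entry
    return out
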