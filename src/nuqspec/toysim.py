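"""Toy chromophore models with closed-form oracles.

These stand in for the expensive stages of a real nuclear-ensemble
workflow (ab initio MD for sampling, excited-state calculations for the
sticks) with models whose spectra are known exactly:

* a displaced harmonic oscillator (DHO) chromophore — two identical
  harmonic surfaces offset by a Huang–Rhys displacement S and an
  adiabatic energy E00.  Its vertical excitation gap is linear in the
  nuclear coordinate, its Franck–Condon spectrum at T = 0 is a Poisson
  progression, and its exact spectral moments are

      mean = E00 + S·ħω,   var = S·(ħω)²·coth(βħω/2);

* a Morse oscillator, the minimal anharmonic surface, used to show how
  harmonic samplers over-stretch soft bonds;
* Langevin (BAOAB) dynamics on these surfaces, a seed-reproducible
  replacement for thermostated MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (ACC_PREF, HC_EV_CM, KB_EV, ev_to_wavenumber,
                        force_constant, vibrational_period_fs)
from .gsta import quantum_weight
from .io_formats import NormalModeSet, StickTable, Trajectory
from .sampling import classical_coordinate_sigma, wigner_coordinate_sigma


@dataclass
class DHOModel:
    """Displaced harmonic oscillator chromophore (Condon approximation)."""

    vib_energy_ev: float      # ħω
    huang_rhys: float         # S
    e00_ev: float             # adiabatic 0-0 energy
    osc_strength: float = 1.0
    reduced_mass_amu: float = 1.0

    def __post_init__(self):
        if self.vib_energy_ev <= 0:
            raise ValueError("vibrational quantum must be positive")
        if self.huang_rhys < 0 or self.osc_strength < 0:
            raise ValueError("S and f0 must be non-negative")
        if self.reduced_mass_amu <= 0:
            raise ValueError("reduced mass must be positive")

    @property
    def frequency_cm(self) -> float:
        return ev_to_wavenumber(self.vib_energy_ev)

    @property
    def force_constant_ev_ang2(self) -> float:
        return force_constant(self.frequency_cm, self.reduced_mass_amu)

    @property
    def displacement_ang(self) -> float:
        """Surface offset d with relaxation energy k·d²/2 = S·ħω."""
        return math.sqrt(2.0 * self.huang_rhys * self.vib_energy_ev
                         / self.force_constant_ev_ang2)

    @property
    def vertical_energy_ev(self) -> float:
        return self.e00_ev + self.huang_rhys * self.vib_energy_ev


@dataclass
class MorseModel:
    """Morse potential V(x) = D·(1 − exp(−a(x − x0)))²."""

    well_depth_ev: float
    range_inv_ang: float
    equilibrium_ang: float = 0.0
    reduced_mass_amu: float = 1.0

    def __post_init__(self):
        if self.well_depth_ev <= 0 or self.range_inv_ang <= 0:
            raise ValueError("well depth and range parameter must be positive")
        if self.reduced_mass_amu <= 0:
            raise ValueError("reduced mass must be positive")

    @property
    def force_constant_ev_ang2(self) -> float:
        """Curvature at the minimum, k = 2Da²."""
        return 2.0 * self.well_depth_ev * self.range_inv_ang ** 2

    @property
    def frequency_cm(self) -> float:
        from .constants import FORCE_CONST_PREF
        return math.sqrt(self.force_constant_ev_ang2
                         / (FORCE_CONST_PREF * self.reduced_mass_amu))


@dataclass
class ToyMDConfig:
    """Langevin run parameters (BAOAB splitting)."""

    temperature: float        # K
    dt: float                 # fs
    steps: int
    friction: float = 0.05    # fs⁻¹
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def _model_arrays(model):
    """(masses[amu], force(x)->eV/Å, x0[Å], fastest ν̃[cm⁻¹]) per model kind."""
    if isinstance(model, DHOModel):
        k = model.force_constant_ev_ang2
        m = np.array([model.reduced_mass_amu])

        def force(x):
            return -k * x

        return m, force, np.zeros((1, 3)), model.frequency_cm
    if isinstance(model, MorseModel):
        d, a, x0 = model.well_depth_ev, model.range_inv_ang, model.equilibrium_ang
        m = np.array([model.reduced_mass_amu])

        def force(x):
            e = np.exp(-a * (x - x0))
            return -2.0 * d * a * e * (1.0 - e)

        return m, force, np.array([[x0, 0.0, 0.0]]), model.frequency_cm
    if isinstance(model, NormalModeSet):
        k = force_constant(model.frequencies, 1.0)
        masses = model.masses
        flat_modes = model.displacements.reshape(model.n_modes, -1)
        sqm = np.sqrt(masses)

        def force(x):
            # x: (atoms, 3) displacement from reference
            mw = (x * sqm[:, None]).ravel()
            q = flat_modes @ mw
            f_mw = -(k * q) @ flat_modes
            return (f_mw.reshape(-1, 3)) * sqm[:, None]

        x0 = model.reference_geometry
        return masses, force, x0, float(model.frequencies.max())
    raise TypeError(f"unsupported model type {type(model).__name__}")


def simulate_langevin(model, cfg: ToyMDConfig,
                      elements=None) -> Trajectory:
    """BAOAB-discretized Langevin dynamics on a toy potential surface.

    Coordinates are recorded every step.  1-D models move a single
    particle along x.  dt must resolve the fastest vibrational period:
    above period/5 the run is refused, above period/10 a warning is
    issued.
    """
    import warnings

    masses, force_fn, x0, nu_max = _model_arrays(model)
    period = vibrational_period_fs(nu_max)
    if cfg.dt > period / 5.0:
        raise ValueError(
            f"dt = {cfg.dt} fs exceeds period/5 = {period / 5.0:.3f} fs for "
            f"the fastest mode ({nu_max:.0f} cm⁻¹)")
    if cfg.dt > period / 10.0:
        warnings.warn(f"dt = {cfg.dt} fs is above period/10 = "
                      f"{period / 10.0:.3f} fs; integration may be inaccurate")

    one_d = not isinstance(model, NormalModeSet)
    n_atoms = 1 if one_d else len(masses)
    rng = np.random.default_rng(cfg.seed)
    x = np.zeros((n_atoms, 3))
    v = np.zeros((n_atoms, 3))
    active = np.zeros((n_atoms, 3), bool)
    if one_d:
        active[0, 0] = True
    else:
        active[:] = True

    kT = KB_EV * cfg.temperature
    m3 = masses[:, None]
    c1 = math.exp(-cfg.friction * cfg.dt)
    # OU noise amplitude in velocity units (Å/fs)
    sig_v = np.sqrt((1.0 - c1 * c1) * kT * ACC_PREF / m3)
    if cfg.temperature > 0:
        v = rng.standard_normal((n_atoms, 3)) * np.sqrt(kT * ACC_PREF / m3)
        v[~active] = 0.0

    def accel(xd):
        if one_d:
            f = np.zeros((n_atoms, 3))
            f[0, 0] = force_fn(xd[0, 0] + x0[0, 0])
            return ACC_PREF * f / m3
        return ACC_PREF * force_fn(xd) / m3

    half = 0.5 * cfg.dt
    frames = np.empty((cfg.steps, n_atoms, 3))
    a = accel(x)
    for step in range(cfg.steps):
        v += half * a
        x += half * v
        if cfg.temperature > 0:
            noise = rng.standard_normal((n_atoms, 3)) * sig_v
            v = c1 * v + np.where(active, noise, 0.0)
        else:
            v = c1 * v
        x += half * v
        a = accel(x)
        v += half * a
        frames[step] = x
    frames += x0[None]  # x evolved as displacement from the minimum/reference
    if elements is None:
        elements = ["X"] * n_atoms
    return Trajectory(elements=list(elements), coords=frames, dt=cfg.dt,
                      provenance=f"langevin T={cfg.temperature}K "
                                 f"gamma={cfg.friction}/fs seed={cfg.seed}")


def dho_vertical_excitation(model: DHOModel, coordinate: float):
    """Vertical excitation (energy eV, strength) at displacement x from the minimum.

    The gap of two identical displaced parabolas is linear in x:
    E(x) = E00 + S·ħω − (mω²d)·x, with constant Condon strength f0.
    """
    slope = model.force_constant_ev_ang2 * model.displacement_ang
    energy = model.vertical_energy_ev - slope * np.asarray(coordinate, dtype=float)
    strength = np.broadcast_to(model.osc_strength, np.shape(energy))
    if np.ndim(energy) == 0:
        return float(energy), float(model.osc_strength)
    return energy, np.array(strength, dtype=float)


def excite_trajectory(model: DHOModel, traj: Trajectory,
                      every: int = 100) -> StickTable:
    """Vertical excitations for every ``every``-th frame of a 1-D trajectory."""
    if every < 1:
        raise ValueError("every must be >= 1")
    coords = traj.coords[::every, 0, 0]
    energies, strengths = dho_vertical_excitation(model, coords)
    ids = np.arange(len(coords))
    return StickTable(ids, energies, strengths)


@dataclass
class FCResult:
    """Franck–Condon oracle output for the DHO model."""

    stick_energies_ev: np.ndarray   # T = 0 Poisson progression
    stick_intensities: np.ndarray   # e^{-S}·Sⁿ/n!, normalized weights
    mean_ev: float
    std_ev: float


def fc_dho_oracle(model: DHOModel, temperature: float = 0.0,
                  tail: float = 1e-10) -> FCResult:
    """Exact FC progression (T = 0 sticks) and spectral moments at any T.

    The sticks follow the Poisson progression at E00 + n·ħω with weights
    e^{-S}·Sⁿ/n!, truncated once the cumulative intensity reaches
    1 − ``tail``.  The moments are closed-form (not from the truncated
    sticks): mean = E00 + S·ħω, var = S·(ħω)²·coth(βħω/2).
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    s, hw = model.huang_rhys, model.vib_energy_ev
    weights = [math.exp(-s)]
    total = weights[0]
    n = 0
    n_max = 10000
    while total < 1.0 - tail:
        n += 1
        if n > n_max:
            raise RuntimeError("FC progression failed to converge")
        weights.append(weights[-1] * s / n)
        total += weights[-1]
    weights = np.array(weights)
    energies = model.e00_ev + np.arange(len(weights)) * hw
    mean = model.vertical_energy_ev
    if s == 0:
        std = 0.0
    elif temperature == 0:
        std = math.sqrt(s) * hw
    else:
        coth = quantum_weight(model.frequency_cm, temperature) / (
            hw / (2.0 * KB_EV * temperature))
        std = math.sqrt(s * hw * hw * coth)
    return FCResult(energies, weights, mean, std)


def synthetic_envelope_sticks(n: int, seed: int, x_range=(2.4, 3.6),
                              center: float = 3.0,
                              width: float = 0.15) -> StickTable:
    """Sticks whose strengths follow a smooth Gaussian envelope of energy.

    Excitation energies are uniform over ``x_range`` (eV) and strengths
    are exp(−(X−center)²/2·width²) — the noiseless kernel-regression
    setting in which leave-one-out bandwidth selection has an interior
    optimum that shrinks as the ensemble grows.  (With strictly
    constant strengths the LOO loss is minimized by arbitrarily wide
    kernels; see the bandwidth docs.)
    """
    if n < 2:
        raise ValueError("need at least two sticks")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], n)
    y = np.exp(-0.5 * ((x - center) / width) ** 2)
    return StickTable(np.arange(n), x, y)


def morse_overextension_fraction(model: MorseModel, sampler: str,
                                 threshold: float, temperature: float,
                                 n: int, seed: int) -> float:
    """Fraction of harmonic-model samples stretched past ``threshold``.

    Samples the harmonic approximation at the Morse minimum (frequency
    from the well curvature) with the requested sampler and reports the
    fraction displaced beyond ``threshold`` Å on the dissociative
    (positive-x) side — the mechanism by which Wigner sampling of an
    anharmonic bond produces unphysically stretched structures.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sampler not in ("wigner", "classical"):
        raise ValueError("sampler must be 'wigner' or 'classical'")
    nu = model.frequency_cm
    if sampler == "wigner":
        sig = wigner_coordinate_sigma(nu, model.reduced_mass_amu, temperature)
    else:
        sig = classical_coordinate_sigma(nu, model.reduced_mass_amu, temperature)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * sig
    return float(np.mean(x > threshold))
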