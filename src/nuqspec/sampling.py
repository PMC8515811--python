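"""Harmonic configurational samplers and energy diagnostics.

Two ways to draw ground-state nuclear ensembles from a normal-mode
model:

* ``sample_wigner`` — coordinate marginal of the harmonic Wigner
  distribution, a zero-mean Gaussian per mode with variance
  (ħ/2mω)·coth(βħω/2).  At T = 0 this is the vibrational ground state
  and carries the zero-point spread; it is the quantum reference that
  GSTA-filtered MD should reproduce for harmonic modes.
* ``sample_classical`` — classical Boltzmann coordinate marginal,
  variance k_BT/mω², the distribution an (unfiltered) thermostated MD
  run samples.

The ratio of the two variances is exactly the GSTA weighting function
w(ν), which is what makes the potential-energy histograms of the two
ensembles (a χ²-type/gamma law for the classical one) a useful
diagnostic of how much quantum broadening a system carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import EV_TO_KCAL_MOL, HC_EV_CM, KB_EV, force_constant
from .gsta import quantum_weight
from .io_formats import NormalModeSet


def classical_coordinate_sigma(frequency_cm: float, reduced_mass: float,
                               temperature: float) -> float:
    """Std dev (Å) of the classical thermal coordinate, sqrt(k_BT/mω²)."""
    if frequency_cm <= 0 or reduced_mass <= 0:
        raise ValueError("frequency and mass must be positive")
    if temperature <= 0:
        raise ValueError("classical sampling is undefined at T <= 0")
    k = force_constant(frequency_cm, reduced_mass)
    return math.sqrt(KB_EV * temperature / k)


def wigner_coordinate_sigma(frequency_cm: float, reduced_mass: float,
                            temperature: float) -> float:
    """Std dev (Å) of the harmonic Wigner coordinate marginal.

    sigma² = (ħ/2mω)·coth(βħω/2); the T = 0 limit is the zero-point
    spread sqrt(ħ/2mω).
    """
    if frequency_cm <= 0 or reduced_mass <= 0:
        raise ValueError("frequency and mass must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    k = force_constant(frequency_cm, reduced_mass)
    hw = HC_EV_CM * frequency_cm
    var0 = hw / (2.0 * k)  # ħω/2 / (mω²) = ħ/2mω, in Å²
    if temperature == 0:
        return math.sqrt(var0)
    x = hw / (2.0 * KB_EV * temperature)
    coth = quantum_weight(frequency_cm, temperature) / x
    return math.sqrt(var0 * coth)


def amplitude_ratio_lower_estimate(frequency_cm: float,
                                   temperature: float) -> float:
    """Lower estimate of the quantum/classical amplitude ratio.

    sqrt(E_ZPV / E_th) = sqrt( (hν/2) / k_BT ): the zero-point energy of
    the mode over the classical thermal energy per oscillator.  For X–H
    stretches (ν ≈ 3000 cm⁻¹) at room temperature this is 2–3,
    which is why high-frequency modes dominate quantum broadening.
    """
    if frequency_cm <= 0:
        raise ValueError("frequency must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e_zpv = 0.5 * HC_EV_CM * frequency_cm
    return math.sqrt(e_zpv / (KB_EV * temperature))


@dataclass
class ModeSampleSet:
    """Cartesian configurations drawn from a normal-mode sampler."""

    configurations: np.ndarray  # (samples, atoms, 3) Å
    origin: str                 # 'wigner' | 'classical'
    temperature: float
    seed: int

    def __post_init__(self):
        self.configurations = np.asarray(self.configurations, dtype=float)
        if self.configurations.ndim != 3 or len(self.configurations) < 1:
            raise ValueError("need >= 1 configuration of shape (atoms, 3)")
        if not np.all(np.isfinite(self.configurations)):
            raise ValueError("non-finite configuration")

    @property
    def n_samples(self) -> int:
        return len(self.configurations)


def _mode_sigmas(modes: NormalModeSet, temperature: float,
                 origin: str) -> np.ndarray:
    # mass-weighted normal coordinates have unit (amu) effective mass
    if origin == "wigner":
        return np.array([wigner_coordinate_sigma(f, 1.0, temperature)
                         for f in modes.frequencies])
    return np.array([classical_coordinate_sigma(f, 1.0, temperature)
                     for f in modes.frequencies])


def _assemble(modes: NormalModeSet, q: np.ndarray) -> np.ndarray:
    # Cartesian displacement = M^{-1/2} · Σ_i L_i q_i
    disp = np.tensordot(q, modes.displacements, axes=(1, 0))
    disp /= np.sqrt(modes.masses)[None, :, None]
    return modes.reference_geometry[None] + disp


def sample_wigner(modes: NormalModeSet, temperature: float, n: int,
                  seed: int) -> ModeSampleSet:
    """Draw n configurations from the harmonic Wigner coordinate marginal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = np.random.default_rng(seed)
    sig = _mode_sigmas(modes, temperature, "wigner")
    q = rng.standard_normal((n, modes.n_modes)) * sig[None, :]
    return ModeSampleSet(_assemble(modes, q), "wigner", temperature, seed)


def sample_classical(modes: NormalModeSet, temperature: float, n: int,
                     seed: int) -> ModeSampleSet:
    """Draw n configurations from the classical Boltzmann coordinate marginal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if temperature <= 0:
        raise ValueError("classical sampling is undefined at T <= 0")
    rng = np.random.default_rng(seed)
    sig = _mode_sigmas(modes, temperature, "classical")
    q = rng.standard_normal((n, modes.n_modes)) * sig[None, :]
    return ModeSampleSet(_assemble(modes, q), "classical", temperature, seed)


def normal_coordinates(samples: ModeSampleSet,
                       modes: NormalModeSet) -> np.ndarray:
    """Project configurations back onto mass-weighted normal coordinates."""
    disp = samples.configurations - modes.reference_geometry[None]
    mw = disp * np.sqrt(modes.masses)[None, :, None]
    return np.tensordot(mw, modes.displacements, axes=([1, 2], [1, 2]))


@dataclass
class EnergyDistributionSummary:
    """Moments and moment-matched gamma fit of a harmonic PE sample."""

    mean_kcal_mol: float
    std_kcal_mol: float
    gamma_shape: float
    gamma_scale_kcal_mol: float


def potential_energy_distribution(samples: ModeSampleSet,
                                  modes: NormalModeSet
                                  ) -> EnergyDistributionSummary:
    """Harmonic potential energy per sample, with a moment-matched gamma fit.

    For a classical ensemble of M modes the PE is gamma-distributed with
    shape M/2 and scale k_BT (a scaled χ²(M)); mean M·k_BT/2 and std
    sqrt(M/2)·k_BT.  The fit is by moment matching, which is
    deterministic and adequate for a diagnostic.  Reported "width" is
    the standard deviation (not FWHM).
    """
    if samples.n_samples < 2:
        raise ValueError("need >= 2 samples for a distribution summary")
    q = normal_coordinates(samples, modes)
    k = force_constant(modes.frequencies, 1.0)  # eV per (amu-weighted Å)²
    pe_ev = 0.5 * (q * q) @ k
    pe = pe_ev * EV_TO_KCAL_MOL
    mean = float(pe.mean())
    var = float(pe.var(ddof=1))
    if var <= 0:
        raise ValueError("degenerate potential-energy sample")
    shape = mean * mean / var
    scale = var / mean
    return EnergyDistributionSummary(mean, math.sqrt(var), shape, scale)
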