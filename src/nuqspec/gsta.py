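"""Generalized smoothed trajectory analysis (GSTA).

A classical MD trajectory samples harmonic modes with the classical
thermal variance k_BT/mω²; the quantum oscillator at the same
temperature has variance (ħ/2mω)·coth(βħω/2).  The ratio of the two
energies is the weighting function

    w(ν) = (βhν/2) · coth(βhν/2) ,   w(0) = 1,  w ≥ 1,

and GSTA corrects the trajectory by convolving each Cartesian
coordinate with a finite, symmetric kernel whose frequency response is
√w(ν): energy is quadratic in amplitude, so the amplitude gain √w turns
classical coordinate variances into their quantum counterparts.  The
kernel is realized as the inverse DFT of √w sampled on the discrete
frequency grid of a centered moving window (default 241 frames at
dt = 0.5 fs, i.e. a 120 fs span).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve

from .constants import CM_PER_CYCFS, HC_EV_CM, KB_EV
from .io_formats import Trajectory


def quantum_weight(frequency_cm, temperature: float):
    """Quantum/classical harmonic energy ratio w(ν) = (βhν/2)·coth(βhν/2).

    Parameters
    ----------
    frequency_cm : float or ndarray
        Vibrational wavenumber ν̃ ≥ 0 in cm⁻¹.
    temperature : float
        Temperature in K, > 0.

    Returns
    -------
    float or ndarray
        Dimensionless ratio, ≥ 1; the ν → 0 limit is 1.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(frequency_cm, dtype=float)
    if np.any(nu < 0):
        raise ValueError("frequency must be non-negative")
    x = HC_EV_CM * nu / (2.0 * KB_EV * temperature)
    # x·coth(x): series below 1e-4 avoids 0/0; beyond ~350 coth ≡ 1 and
    # x·coth(x) → x (also dodges overflow in expm1(2x)).
    small = x < 1e-4
    large = x > 350.0
    mid = ~(small | large)
    out = np.empty_like(x)
    out[small] = 1.0 + x[small] ** 2 / 3.0
    xm = x[mid]
    out[mid] = xm * (1.0 + 2.0 / np.expm1(2.0 * xm))
    out[large] = x[large]
    return out if out.ndim else float(out)


@dataclass
class FilterKernel:
    """Discrete real symmetric convolution taps realizing the GSTA filter."""

    taps: np.ndarray
    dt: float
    temperature: float

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=float)
        n = len(self.taps)
        if n % 2 == 0 or n < 3:
            raise ValueError("kernel length must be odd and >= 3")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("non-finite kernel tap")
        if np.abs(self.taps - self.taps[::-1]).max() > 1e-12:
            raise ValueError("kernel taps must be symmetric")
        if abs(self.taps.sum() - 1.0) > 1e-10:
            raise ValueError("kernel DC gain must be 1")

    @property
    def window_frames(self) -> int:
        return len(self.taps)

    def frequency_grid_cm(self) -> np.ndarray:
        """Resolvable wavenumbers ν_k = k/(W·dt), k = 0..W//2, in cm⁻¹."""
        w = self.window_frames
        k = np.arange(w // 2 + 1)
        return k / (w * self.dt) * CM_PER_CYCFS

    def gain(self) -> np.ndarray:
        """Discrete amplitude response at :meth:`frequency_grid_cm` bins."""
        w = self.window_frames
        resp = np.fft.rfft(np.fft.ifftshift(self.taps), n=w)
        return np.abs(resp)


def build_gsta_kernel(window_frames: int, dt: float,
                      temperature: float) -> FilterKernel:
    """Construct the GSTA kernel for a centered window.

    The taps are the inverse DFT of √w(ν_k) over the window's discrete
    frequency grid; by construction the response at every resolvable
    frequency is exactly √w(ν_k) and the DC gain is exactly 1.
    """
    if window_frames % 2 == 0 or window_frames < 3:
        raise ValueError("window_frames must be odd and >= 3")
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = window_frames
    nu = np.arange(w // 2 + 1) / (w * dt) * CM_PER_CYCFS
    resp = np.sqrt(quantum_weight(nu, temperature))
    taps = np.fft.irfft(resp, n=w)
    taps = np.fft.fftshift(taps)  # center the peak
    # symmetrize away last-bit FFT asymmetry and pin the DC gain
    taps = 0.5 * (taps + taps[::-1])
    taps /= taps.sum()
    return FilterKernel(taps=taps, dt=dt, temperature=temperature)


def apply_gsta(traj: Trajectory, kernel: FilterKernel) -> Trajectory:
    """Filter a trajectory with a GSTA kernel (valid convolution).

    The half-window at each end is discarded: the output has
    ``frames - (window - 1)`` frames.  Elements and dt are preserved;
    the filter acts independently on every Cartesian component.
    """
    w = kernel.window_frames
    if traj.n_frames < w:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames; kernel needs >= {w}")
    if abs(traj.dt - kernel.dt) > 1e-9:
        raise ValueError(
            f"trajectory dt {traj.dt} fs != kernel dt {kernel.dt} fs")
    filtered = oaconvolve(traj.coords, kernel.taps[:, None, None],
                          mode="valid", axes=0)
    return Trajectory(elements=list(traj.elements), coords=filtered,
                      dt=traj.dt,
                      provenance=(traj.provenance + " | gsta-filtered").strip(" |"))


def gain_table(kernel: FilterKernel) -> np.ndarray:
    """(ν_k [cm⁻¹], measured gain, √w target) rows for reporting."""
    nu = kernel.frequency_grid_cm()
    return np.column_stack([nu, kernel.gain(),
                            np.sqrt(quantum_weight(nu, kernel.temperature))])
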