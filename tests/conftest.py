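import math

import numpy as np
import pytest

from nuqspec.gsta import apply_gsta, build_gsta_kernel
from nuqspec.io_formats import NormalModeSet, StickTable, Trajectory
from nuqspec.toysim import DHOModel, ToyMDConfig, excite_trajectory, \
    simulate_langevin

# study conditions for the DHO closure pipeline: room temperature, the
# 0.5 fs step and 241-frame GSTA window of a production run, a single
# bright vibronic mode (ħω = 0.2 eV ≈ 1600 cm⁻¹, S = 1) plus a weaker
# second state for bandwidth-selection tests
TEMPERATURE = 300.0
DT_FS = 0.5
WINDOW = 241
FRICTION = 0.05
STEPS = 200_000
BURN_IN = 2_000  # ~5 position-decorrelation times at friction 0.05/fs


def make_modes(frequencies_cm, seed=0, masses=None):
    """Normal-mode set with random orthonormal mass-weighted vectors."""
    freqs = np.sort(np.asarray(frequencies_cm, dtype=float))
    n_modes = len(freqs)
    n_atoms = max(2, math.ceil((n_modes + 5) / 3))
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3 * n_atoms, n_modes)))
    disp = q.T.reshape(n_modes, n_atoms, 3)
    if masses is None:
        masses = np.ones(n_atoms)
    return NormalModeSet(np.zeros((n_atoms, 3)), masses, freqs, disp)


@pytest.fixture(scope="session")
def dho_model():
    return DHOModel(vib_energy_ev=0.2, huang_rhys=1.0, e00_ev=3.0,
                    osc_strength=1.0)


@pytest.fixture(scope="session")
def dho_pipeline(dho_model):
    """One long Langevin run pushed through the full spectrum pipeline.

    Provides burn-in-stripped classical and GSTA-filtered trajectories,
    per-frame vertical-excitation energies for moment checks, and
    every-100th-frame stick tables pooled over two electronic states
    (bright + weak) for bandwidth-selection checks.
    """
    state2 = DHOModel(vib_energy_ev=0.2, huang_rhys=1.0, e00_ev=3.5,
                      osc_strength=0.2)
    cfg = ToyMDConfig(temperature=TEMPERATURE, dt=DT_FS, steps=STEPS,
                      friction=FRICTION, seed=11)
    traj = simulate_langevin(dho_model, cfg)
    kernel = build_gsta_kernel(WINDOW, DT_FS, TEMPERATURE)
    qtraj = apply_gsta(traj, kernel)

    def strip(t):
        return Trajectory(list(t.elements), t.coords[BURN_IN:], t.dt)

    tr_cl, tr_qu = strip(traj), strip(qtraj)

    def pooled(t):
        return StickTable.concat(excite_trajectory(dho_model, t, every=100),
                                 excite_trajectory(state2, t, every=100))

    return {
        "model": dho_model,
        "state2": state2,
        "kernel": kernel,
        "traj_cl": tr_cl,
        "traj_qu": tr_qu,
        "e_cl": excite_trajectory(dho_model, tr_cl, every=1).energies,
        "e_qu": excite_trajectory(dho_model, tr_qu, every=1).energies,
        "sticks_cl": pooled(tr_cl),
        "sticks_qu": pooled(tr_qu),
        "temperature": TEMPERATURE,
    }
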