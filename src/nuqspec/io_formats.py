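"""Readers/writers for the file formats the toolkit touches.

Formats
-------
* multi-frame XYZ trajectories (Å; the timestep is not stored in the
  file and must be supplied by the caller),
* stick-spectrum tables: tab- or comma-separated with header
  ``snapshot, energy_eV, osc_strength``, ``#`` comments allowed,
* a plain-text normal-mode format (masses, wavenumbers, one
  mass-weighted displacement block per mode, reference geometry),
* YAML run configuration.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when a file violates its documented layout."""


class ValidationError(ValueError):
    """Raised when parsed content violates a physical invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates with a fixed timestep.

    Attributes
    ----------
    elements : list of str
        Chemical symbols, one per atom (``X`` for toy particles).
    coords : ndarray, shape (frames, atoms, 3)
        Cartesian coordinates in Å.
    dt : float
        Timestep between consecutive frames, fs.
    provenance : str
        Free-text metadata carried into output comment lines.
    """

    elements: list
    coords: np.ndarray
    dt: float
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if self.n_frames < 1 or self.n_atoms < 1:
            raise ValidationError("trajectory needs >= 1 frame and >= 1 atom")
        if len(self.elements) != self.n_atoms:
            raise ValidationError(
                f"{len(self.elements)} element symbols for {self.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in trajectory")
        if not self.dt > 0:
            raise ValidationError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class StickTable:
    """Pooled (snapshot, excitation energy, oscillator strength) records."""

    snapshots: np.ndarray  # int ids
    energies: np.ndarray   # eV, > 0
    strengths: np.ndarray  # dimensionless, >= 0

    def __post_init__(self):
        self.snapshots = np.asarray(self.snapshots, dtype=int)
        self.energies = np.asarray(self.energies, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        n = len(self.snapshots)
        if n < 1:
            raise ValidationError("stick table needs at least one record")
        if len(self.energies) != n or len(self.strengths) != n:
            raise ValidationError("stick table columns have unequal length")
        if not (np.all(np.isfinite(self.energies)) and np.all(self.energies > 0)):
            raise ValidationError("excitation energies must be finite and positive")
        if not (np.all(np.isfinite(self.strengths)) and np.all(self.strengths >= 0)):
            raise ValidationError("oscillator strengths must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.energies)

    @property
    def n_snapshots(self) -> int:
        return len(np.unique(self.snapshots))

    @staticmethod
    def concat(*tables: "StickTable") -> "StickTable":
        """Pool several stick tables (e.g., one per electronic state)."""
        return StickTable(
            np.concatenate([t.snapshots for t in tables]),
            np.concatenate([t.energies for t in tables]),
            np.concatenate([t.strengths for t in tables]))

    def restrict(self, snapshot_ids) -> "StickTable":
        mask = np.isin(self.snapshots, np.asarray(snapshot_ids, dtype=int))
        if not mask.any():
            raise ValidationError("no records for the requested snapshots")
        return StickTable(self.snapshots[mask], self.energies[mask],
                          self.strengths[mask])


@dataclass
class NormalModeSet:
    """Harmonic normal modes with mass-weighted orthonormal displacements."""

    reference_geometry: np.ndarray  # (atoms, 3) Å
    masses: np.ndarray              # amu per atom
    frequencies: np.ndarray         # cm⁻¹ per mode, ascending, > 0
    displacements: np.ndarray       # (modes, atoms, 3), mass-weighted
    ortho_tol: float = field(default=1e-6, repr=False)

    def __post_init__(self):
        self.reference_geometry = np.asarray(self.reference_geometry, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        n_atoms = self.reference_geometry.shape[0]
        n_modes = len(self.frequencies)
        if self.displacements.shape != (n_modes, n_atoms, 3):
            raise ValidationError("displacement block shape mismatch")
        if len(self.masses) != n_atoms or np.any(self.masses <= 0):
            raise ValidationError("need one positive mass per atom")
        if np.any(self.frequencies <= 0):
            raise ValidationError(
                "non-positive frequency: imaginary modes are unsupported")
        if np.any(np.diff(self.frequencies) < 0):
            raise ValidationError("frequencies must be sorted ascending")
        if n_modes > 3 * n_atoms - 5 and n_atoms > 1:
            raise ValidationError("more modes than internal degrees of freedom")
        flat = self.displacements.reshape(n_modes, -1)
        gram = flat @ flat.T
        dev = np.abs(gram - np.eye(n_modes))
        if dev.max() > self.ortho_tol:
            i, j = np.unravel_index(int(dev.argmax()), dev.shape)
            raise ValidationError(
                "mass-weighted modes not orthonormal: worst overlap "
                f"|<{i}|{j}> - δ| = {dev.max():.3e}")

    @property
    def n_atoms(self) -> int:
        return self.reference_geometry.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def read_xyz_trajectory(path, dt: float) -> Trajectory:
    """Read a concatenated-frame XYZ file (Å) into a :class:`Trajectory`.

    The timestep is not an XYZ field; it must be supplied here.
    """
    frames = []
    elements = None
    comment = ""
    with open(path) as fh:
        lineno = 0
        frame_idx = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if header == "":
                    break
                continue
            try:
                n_atoms = int(header.split()[0])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: expected atom count, got "
                    f"{header.strip()!r}") from None
            comment_line = fh.readline()
            lineno += 1
            if frame_idx == 0:
                comment = comment_line.strip()
            symbols, xyz = [], []
            for _ in range(n_atoms):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(
                        f"{path}: line {lineno}: truncated atom line in "
                        f"frame {frame_idx}")
                symbols.append(parts[0])
                try:
                    xyz.append([float(p) for p in parts[1:4]])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric coordinate "
                        f"{parts[1:4]}") from None
            if elements is None:
                elements = symbols
            elif symbols != elements or n_atoms != len(elements):
                raise FormatError(
                    f"{path}: frame {frame_idx} lists different atoms/order "
                    "than frame 0")
            frames.append(xyz)
            frame_idx += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return Trajectory(elements=elements, coords=np.array(frames, dtype=float),
                      dt=dt, provenance=comment)


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-frame XYZ file re-readable by :func:`read_xyz_trajectory`."""
    buf = io.StringIO()
    n = traj.n_atoms
    for f in range(traj.n_frames):
        buf.write(f"{n}\n")
        buf.write(f"frame {f} dt_fs={traj.dt:g} {traj.provenance}\n".rstrip() + "\n")
        for a in range(n):
            x, y, z = traj.coords[f, a]
            buf.write(f"{traj.elements[a]} {x:.8f} {y:.8f} {z:.8f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# stick tables
# ---------------------------------------------------------------------------

_STICK_COLUMNS = ["snapshot", "energy_eV", "osc_strength"]


def read_stick_table(path) -> StickTable:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _STICK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; "
                          f"expected header {_STICK_COLUMNS}")
    return StickTable(df["snapshot"].to_numpy(),
                      df["energy_eV"].to_numpy(),
                      df["osc_strength"].to_numpy())


def write_stick_table(sticks: StickTable, path, header_meta: str = "") -> None:
    with open(path, "w") as fh:
        if header_meta:
            fh.write(f"# {header_meta}\n")
        fh.write("\t".join(_STICK_COLUMNS) + "\n")
        for s, e, f in zip(sticks.snapshots, sticks.energies, sticks.strengths):
            fh.write(f"{s}\t{e:.10g}\t{f:.10g}\n")


# ---------------------------------------------------------------------------
# normal modes
# ---------------------------------------------------------------------------

def read_normal_modes(path) -> NormalModeSet:
    """Parse the plain-text normal-mode format.

    Layout (``#`` comments and blank lines ignored)::

        natoms 2
        nmodes 1
        reference        # natoms lines: x y z (Å)
        0.0 0.0 0.0
        1.0 0.0 0.0
        masses           # natoms values (amu), any line breaking
        1.0 1.0
        frequencies_cm   # nmodes values, ascending
        1500.0
        mode 1           # natoms lines: mass-weighted displacement
        0.70710678 0 0
        -0.70710678 0 0
    """
    tokens = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    pos = 0

    def take(n):
        nonlocal pos
        if pos + n > len(tokens):
            raise FormatError(f"{path}: unexpected end of file")
        out = tokens[pos:pos + n]
        pos += n
        return out

    def expect(word):
        got = take(1)[0]
        if got.lower() != word:
            raise FormatError(f"{path}: expected '{word}', got {got!r}")

    expect("natoms")
    n_atoms = int(take(1)[0])
    expect("nmodes")
    n_modes = int(take(1)[0])
    expect("reference")
    ref = np.array([float(v) for v in take(3 * n_atoms)]).reshape(n_atoms, 3)
    expect("masses")
    masses = np.array([float(v) for v in take(n_atoms)])
    expect("frequencies_cm")
    freqs = np.array([float(v) for v in take(n_modes)])
    disp = np.empty((n_modes, n_atoms, 3))
    for m in range(n_modes):
        expect("mode")
        take(1)  # mode index, informational
        disp[m] = np.array([float(v) for v in take(3 * n_atoms)]
                           ).reshape(n_atoms, 3)
    return NormalModeSet(ref, masses, freqs, disp)


def write_normal_modes(modes: NormalModeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"natoms {modes.n_atoms}\nnmodes {modes.n_modes}\n")
        fh.write("reference\n")
        for row in modes.reference_geometry:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("masses\n")
        fh.write(" ".join(f"{v:.10g}" for v in modes.masses) + "\n")
        fh.write("frequencies_cm\n")
        fh.write(" ".join(f"{v:.10g}" for v in modes.frequencies) + "\n")
        for m in range(modes.n_modes):
            fh.write(f"mode {m + 1}\n")
            for row in modes.displacements[m]:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def ensure_writable(path) -> None:
    d = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(d):
        raise IOError(f"output directory does not exist: {d}")
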