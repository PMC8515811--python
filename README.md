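# nuqspec

Nuclear-ensemble absorption spectra with quantum-corrected classical
trajectories and statistically optimal Gaussian broadening.

## The problem

The absorption spectrum of a solvated chromophore can be estimated by
the *nuclear ensemble method*: sample ground-state nuclear
configurations **R**, compute the vertical excitation energies and
oscillator strengths at each one, and average the resulting stick
spectra,

```
s(x) = (1/N) Σ_i Y_i · K_Δ(x − X_i),
```

where `X_i` are excitation energies, `Y_i` oscillator strengths and
`K_Δ` a unit-area Gaussian of standard deviation Δ.  Two practical
questions dominate the quality of such spectra, and this package
implements an answer to both:

1. **Nuclear quantum effects.**  Classical MD samples each vibration
   with thermal variance `k_BT/mω²`, but the quantum oscillator has
   variance `(ħ/2mω)·coth(βħω/2)` — larger by the factor
   `w(ν) = (βhν/2)·coth(βhν/2)`, which reaches 7 for a C–H stretch at
   room temperature.  *Generalized smoothed trajectory analysis*
   (GSTA) corrects this after the fact: each Cartesian coordinate is
   convolved with a finite symmetric kernel whose frequency response is
   `√w(ν)` (energy is quadratic in amplitude), turning classical
   coordinate variances into their quantum counterparts while keeping
   the anharmonic, solvated dynamics that harmonic Wigner sampling
   cannot describe.
2. **The broadening width Δ.**  Rather than fitting Δ to an
   experimental spectrum, it is selected by leave-one-out
   cross-validation: a global amplitude `a(Δ)` is fit by least squares
   between the sticks and the kernel sum, and Δ minimizes
   `L_cv(Δ) = Σ_i (Y_i − a(Δ)·ŝ_{−i}(X_i))²`, where `ŝ_{−i}` omits
   record *i*.  The optimal Δ shrinks as the ensemble grows, cleanly
   separating kernel artifacts from the physical (ensemble) broadening.

The expensive stages of a production workflow (ab initio MD,
excited-state calculations) are replaced here by toy models with exact
oracles — Langevin dynamics on harmonic/Morse surfaces and a displaced
harmonic oscillator (DHO) chromophore whose Franck–Condon spectrum has
closed-form moments — so every stage of the machinery can be validated
quantitatively on a desktop.

## Worked example

A bright DHO chromophore (`ħω = 0.2 eV`, Huang–Rhys factor `S = 1`,
`E00 = 3.0 eV`) at 300 K, through the full pipeline:

```sh
cat > dho.yaml <<EOF
kind: dho
vib_energy_ev: 0.2
huang_rhys: 1.0
e00_ev: 3.0
osc_strength: 1.0
EOF
nuqspec simulate    --model dho.yaml --temperature 300 --dt 0.5 \
                    --steps 200000 --seed 1 --out traj.xyz
nuqspec gsta-filter --in traj.xyz --dt 0.5 --window 241 \
                    --temperature 300 --out traj_q.xyz
nuqspec excite      --model dho.yaml --in traj_q.xyz --every 100 \
                    --out sticks.tsv
nuqspec spectrum    --sticks sticks.tsv --delta 0.05 --out spec.tsv
```

which prints

```
wrote 200000 frames to traj.xyz
filtered 200000 -> 199760 frames
wrote 1998 sticks to sticks.tsv
wrote spectrum (2001 points, delta = 0.05 eV) to spec.tsv
```

The 241-frame window spans 120 fs, so the filter discards half a window
at each trajectory end.  Comparing the quantized ensemble against the
exact DHO moments (`mean = E00 + S·ħω`, `std = √(S·(ħω)²·coth(βħω/2))`):

```
ensemble mean = 3.2027 eV   exact = 3.2000 eV
ensemble std  = 0.1941 eV   exact = 0.2001 eV
```

The *unfiltered* (classical) ensemble would give a standard deviation
smaller by `√w(ω) ≈ 1.97` — the quantum broadening the filter restores.
`nuqspec bandwidth` scans Δ by cross-validation, `nuqspec convergence`
tracks spectrum convergence with ensemble size, and `nuqspec pipeline`
chains all stages under one seed with a run manifest.

## Layout

| module | contents |
| --- | --- |
| `nuqspec.io_formats` | XYZ trajectories, stick tables, normal modes, YAML config |
| `nuqspec.gsta` | `w(ν)`, kernel construction, trajectory filtering |
| `nuqspec.sampling` | Wigner / classical harmonic samplers, PE diagnostics |
| `nuqspec.toysim` | Langevin dynamics, DHO chromophore, FC oracle, Morse tests |
| `nuqspec.spectra` | broadening, LOO-CV bandwidth, Marcus width, axis tools |
| `nuqspec.cli` | `nuqspec` subcommands chaining the stages |

See `docs/methods.md` for the model details, parameter choices and
known limitations.
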