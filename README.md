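# memsteer

Rigid-body Brownian dynamics of a charged protein diffusing over model lipid
bilayers, with the positional/orientational steering statistics needed to
study how a protein finds a single target lipid charge against a background
of anionic "decoy" lipids.

The pipeline:

1. **`memsteer.synthetic_systems`** — builds a planar two-leaflet lattice of
   headgroup charge sites with one target (PIP₃-like) charge at the patch
   centre, applies decoy-charge schemes to the upper leaflet (uniform
   fractional charges, random −1 e subsets, spatially clustered subsets),
   and generates dipolar toy proteins with exact net charge and dipole.
2. **`memsteer.protein_model`** — rigid-body protein from PDB (formal
   charges on ionisable groups) or PQR-like text; dipole, Stokes–Einstein
   diffusion constants, diffusion timescales, single-residue charge mutants.
3. **`memsteer.electrostatics`** — screened-Coulomb (Debye–Hückel)
   superposition potential grids in kT/e (exact for the point-charge
   membrane), optional desolvation penalty grids, trilinear interaction
   energies; OpenDX read/write (APBS-compatible).
4. **`memsteer.bd_engine`** — Ermak–McCammon translation + rotation with
   finite-difference grid forces/torques, truncated-b-sphere start sampling,
   q-surface/encounter termination, reflecting wall at the membrane plane,
   deterministic per-trajectory RNG streams, and a numba kernel for
   ensembles (a pure-python reference `step` is kept for verification).
5. **`memsteer.steering_analysis`** — (r, d, θ) steering coordinates,
   Jacobian-reweighted radial/angular/2D histograms, Gaussian HWHM,
   first-encounter distributions, optimal-pose search, residue–phosphorus
   contact fingerprints.
6. **`memsteer.cli`** — YAML-configured orchestration.

## Tests

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, whose scaled-down steering
sweep (500 trajectories × 4 charge schemes × 3 seeds) takes ~6 minutes on
one CPU; everything else runs in ~2 minutes.

## CLI

All commands read a single YAML config (see `memsteer.cli.RunConfig` for the
schema; unknown keys are rejected) and chain through files in its
`output_dir`:

```sh
memsteer build    -c run.yaml    # bilayer.pqr / bilayer.pdb
memsteer field    -c run.yaml    # potential.dx (+ desolvation.dx)
memsteer simulate -c run.yaml    # ensemble.csv, first_encounters.csv, run_manifest.json
memsteer analyze  -c run.yaml    # hist_*.csv (+ .json sidecars), analysis.json
memsteer sweep    -c run.yaml    # the above per fractional-charge scheme
memsteer fingerprint complex.pdb -l IP4 -o fingerprint.csv
```

Minimal config:

```yaml
output_dir: out
bilayer:
  scheme: {kind: fractional, fractional_charge: -0.2}
protein: {kind: toy, n_beads: 12, radius: 14.0, net_charge: 8.0}
bd: {n_trajectories: 500, max_time: 3.0e5, seed: 1}
```

Identical config + seeds ⇒ bit-identical outputs; `run_manifest.json`
records parameters, input hashes, seeds and termination counts.

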