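# crossres

Cross-resolution comparison of molecular conformational ensembles.

`crossres` implements a single-molecule analysis chain for comparing
simulations of the same molecule at different resolutions (all-atom vs
coarse-grained) or under different conditions:

- **trajio** — PDB/GRO structures, XTC/DCD/multi-model-PDB/plain-text
  trajectories, a declarative atoms-to-beads mapping dialect, and pooled
  per-molecule ensemble extraction (copy-major, bit-reproducible order).
  Internal unit is the angstrom everywhere.
- **superpose** — non-mass-weighted least-squares superposition with a
  reflection guard, and the two-pass average-reference construction
  (align to an arbitrary seed, average, realign to the average).
- **cgmap** — mapping-matrix algebra: coarse-grain coordinates,
  displacement vectors and covariances; per-mode motion-conservation
  ratio α ∈ [0, 1]; kernel (null-space) analysis; hypothetical uniform
  n:1 mapping ladders.
- **pca** — positional covariance (divisor K), eigendecomposition with a
  deterministic sign convention, projections, normalized eigenvalues,
  cumulative variance, covariance-element Pearson correlation, and
  dot-product matrices between eigenvector bases (with optional mapping
  of one basis into bead space).
- **compare** — projection densities and Boltzmann-inverted effective
  potentials, intra-/inter-molecular radial distribution functions,
  RMSD-vs-lag curves with power-law fits of the normalized curve
  (fit region NRMSD < 0.7), projection autocorrelation with e⁻²
  characteristic times (interpolated/extrapolated crossing), and
  eigenvalue-weighted geometric-mean speedup ratios.
- **synthgen** — synthetic multi-copy "pseudo-lipid" trajectories with
  planted orthonormal collective modes, exact stationary
  Ornstein–Uhlenbeck temporal correlation, an isotropic noise floor in
  the non-planted directions, and optional per-frame rigid motion —
  every pipeline stage is testable against known ground truth.
- **pipeline** — YAML-config-driven orchestration: per simulation
  extract → two-pass reference → align → (AA) map → covariance → PCA,
  then pairwise PCC matrices, both cross-resolution dot-product routes
  (map-the-trajectory vs map-the-eigenvectors), conservation profiles,
  densities/potentials, RMSD-lag fits, joint-basis timescales and the
  speedup matrix, all as CSV with a run MANIFEST.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(oracle equivalence, conservation bounds, linear-mapping identities,
ground-truth recovery of eigenvalues/subspaces/timescales/speedups,
Boltzmann inversion, RDF sanity, alignment invariances, monotone
information loss along uniform mapping ladders).

## CLI

```sh
# generate a synthetic two-resolution test system
crossres synth --spec spec.yml --out data/

# full analysis graph from a config
crossres run --config config.yml

# individual stages
crossres align|pca|map|conserve|timescales|rdf ...
```

Exit codes: 0 success, 2 configuration/validation error, 1 stage failure.

A minimal run config:

```yaml
seed: 1
output_dir: out
analysis:
  modes: 5
  lags: [1, 2, 5, 10, 20]
simulations:
  - label: aa
    structure: aa/system.gro
    trajectory: aa/traj.txt
    residue_name: DOPC
    temperature: 310
    resolution: AA
    mapping: aa/scheme.map
  - label: cg
    structure: cg/system.gro
    trajectory: cg/traj.txt
    residue_name: DOPC
    temperature: 310
    resolution: CG
```

The mapping dialect lists atom names, then one line per bead
(`;` comments, optional `*weight` factors, rows renormalized to 1):

```
[atoms]
C1 C2 C3 C4
B1: C1 C2
B2: C3 C4*0.5
```

An illustrative (non-authoritative) DOPC-like mapping ships in
`src/crossres/data/dopc_illustrative.map`.

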