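# mdpost

Post-processing of protein–ligand MD trajectories for glycolipid ligands
buried in receptor pockets, exercised end-to-end on synthetic data (no MD
engine required):

* **contacts** — per-frame hydrogen bonds (donor–acceptor < 0.35 nm and
  D–H–A angle > 150°, strict) and salt bridges (central P to Arg CZ / Lys NZ,
  ≤ 0.7 nm inclusive), with occupancy statistics and block-averaged errors;
* **energetics** — ligand–surrounding Lennard-Jones + Coulomb interaction
  energies with a 1.0/1.2 nm cubic-in-r² switching function, linear
  interaction energy (LIE) binding free energies (α = 0.18, β = 0.09),
  Boltzmann pose combination, Kd fold-ratios and pose preferences;
* **noe** — ⟨r⁻³⟩⁻¹/³ effective inter-proton distances over ensembles,
  compared against NMR upper bounds (equality counts as satisfied);
* **conformation** — an idealized β,α(1↔1)-linked diglucosamine builder
  (exact 4C1 chairs, NeRF linkage placement) with glycosidic-torsion
  measurement, syn-exo/syn-exo classification and seeded Gaussian torsion
  ensembles;
* **geometry / stats** — Kabsch superposition with fit/measure selections,
  dihedrals, RMSD time series, and contiguous-block error estimation;
* **synthetic** — generators with exact ground truth: toy receptor–ligand
  complexes with planted contacts, AR(1) energy series with prescribed
  means, and a deterministic fixture bundle;
* **pipeline / CLI** — YAML-config-driven runs producing contact, LIE and
  NOE reports (TSV + JSON, parameters embedded).

Units: nm, kcal/mol, degrees, elementary charges. PDB files are converted
Å↔nm at the I/O boundary. No periodic-boundary imaging is applied; frames
must contain whole complexes.

## CLI

Generate the synthetic fixture bundle, then run the stages:

```bash
mdpost synth --out fixtures/
mdpost contacts --config run.yaml
mdpost lie --config run.yaml
mdpost noe --config run.yaml
mdpost all --config run.yaml --out outdir/
```

Minimal config (paths resolved relative to the config file):

```yaml
seed: 1
n_blocks: 5
discard_initial_ps: 0
output_dir: out
topology: toy_complex.pdb          # single-model PDB
parameters: toy_parameters.tsv     # residue_name atom_name charge_e epsilon_kcal_mol rmin_half_nm
infer_bonds: true                  # opt-in H-heavy bond fallback (0.18 nm)
selections:
  ligand: 'chain == "L"'
  receptor: 'chain == "R"'
contacts:
  trajectory: toy_trajectory.tsv   # flat xyz table or multi-MODEL PDB
  scope: ligand-all
lie:
  poses:
    A: {bound_series: bound_A.tsv, unbound_series: unbound_A.tsv}
  reference_ligands: {lipid_ref: -1.5}
noe:
  trajectory: disaccharide_ensemble.pdb
  restraints: noe_restraints.tsv   # atom_a atom_b upper_bound_nm
```

Exit codes: 0 success, 2 configuration error, 3 data error.

## Layout

```
src/mdpost/
  io_structures.py   PDB / xyz-table / parameter & restraint tables, selections
  geometry.py        dihedrals, Kabsch superposition, RMSD series
  stats.py           block-average error estimation
  contacts.py        hydrogen-bond / salt-bridge detection + occupancy
  energetics.py      nonbonded energies, LIE, pose combination, Kd ratios
  noe.py             effective distances and violation reports
  conformation.py    disaccharide builder, torsion sampling/classification
  synthetic.py       ground-truth generators and fixture bundle
  pipeline.py, cli.py
tests/               pytest suite incl. test_acceptance.py
scripts/acceptance.py
```
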