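# bvfit

Bond-valence machinery for metal coordination sites: bond-valence sums
(BVS), data-driven fitting of bond-valence `R0` parameters over homoleptic
*and* heteroleptic sites, site curation and oxidation-state assignment,
low-spin/high-spin population splitting for Fe–N bonds, and BVS-based
validation of metal-binding-site geometry in macromolecular structures.

The bond length–valence law is `v = exp[(R0 − d)/b]` with global softness
`b = 0.37 Å`. Under the sum rule a site's BVS should equal its metal's
oxidation state `S`; `R0` values are fitted by minimizing the summed
squared deviation `σ² = Σᵢ (Vᵢ − Sᵢ)²` with nonlinear conjugate gradients
and an analytic gradient, pruning sites whose BVS leaves `(0, 2S)` between
optimizer restarts. Per-type uncertainties are the RMS of the
single-parameter shifts `ΔR0` that would make each supporting site exact.

Because the curated small-molecule database used to derive the shipped
reference values is proprietary, the package includes a synthetic site
generator that emulates its statistical structure (coordination numbers,
heteroleptic mixes, distance noise, two-spin Fe–N populations, planted
outliers), so the entire pipeline is testable end to end with known ground
truth.

## Layout

| module | contents |
| --- | --- |
| `bvfit.core` | domain types; bond valence, BVS, closed-form homoleptic `R0`, `ΔR0`, typical and cutoff distances |
| `bvfit.curation` | entry/site filters (criteria i–iv), first-sphere trimming, oxidation-state assignment cascade |
| `bvfit.fitting` | simultaneous `R0` optimization, in-loop pruning, uncertainties, LS/HS bimodal splitting |
| `bvfit.synthetic` | seeded synthetic population generator with ground-truth ledger |
| `bvfit.site_io` | site-table and parameter-table CSV I/O; PDB/mmCIF coordination-sphere extraction |
| `bvfit.reference` | bundled literature and fitted parameter sets, typical-distance tables |
| `bvfit.cli` | `bvfit` command-line front end |

## CLI

```sh
# generate a deterministic synthetic site table (+ truth ledger, manifest)
bvfit simulate --config examples/sim.yaml -o out/sim

# curate + assign oxidation states + fit R0 parameters; optional spin split
bvfit fit out/sim/sites.csv -o out/fit --split-spin FE:N

# score sites (CSV site table or PDB/mmCIF structure) under a parameter set
bvfit validate structure.pdb --params fitted --metal Fe
bvfit validate sites.csv --params out/fit/parameters.csv

# typical metal-ligand distance grid
bvfit distances --metal Fe
```

`--params` accepts `fitted` (the bundled optimized values, spin-split
Fe–N), `brese` (classic literature values), `liu`, or a parameter-table
CSV. Every run writes a `manifest.json` with the config snapshot, input
digests, seed and per-stage counts. Exit codes: 0 ok, 1 user error, 2
internal error.

A minimal simulate config:

```yaml
n_sites: 200
metal_element: Fe
oxidation_state: 2
ligand_pool: {N: 0.6, O: 0.4}
heteroleptic_fraction: 0.5
partition_jitter: 30.0
distance_noise_sd: 0.0
seed: 7
true_params:
  - {metal_element: Fe, oxidation_state: 2, ligand_element: N, r0: 1.76}
  - {metal_element: Fe, oxidation_state: 2, ligand_element: O, r0: 1.70}
```

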