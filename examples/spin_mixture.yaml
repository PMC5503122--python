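# Two-population Fe(II)-N mixture (30% low-spin). Fit with:
#   bvfit fit out/sim/sites.csv -o out/fit --split-spin FE:N \
#       --config examples/spin_fit.yaml
n_sites: 500
metal_element: Fe
oxidation_state: 2
ligand_pool: {N: 1.0}
cn_distribution: {6: 1.0}
distance_noise_sd: 0.02
spin_populations: {ls_fraction: 0.3}
seed: 7
true_params:
  - {metal_element: Fe, oxidation_state: 2, ligand_element: N,
     spin_class: LS, r0: 1.57}
  - {metal_element: Fe, oxidation_state: 2, ligand_element: N,
     spin_class: HS, r0: 1.76}
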