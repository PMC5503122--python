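# Synthetic iron(II) population: mixed homoleptic/heteroleptic N+O sites,
# noise-free, exact parameter recovery expected from `bvfit fit`.
n_sites: 200
metal_element: Fe
oxidation_state: 2
ligand_pool: {N: 0.6, O: 0.4}
cn_distribution: {5: 0.3, 6: 0.7}
heteroleptic_fraction: 0.5
partition_jitter: 30.0
distance_noise_sd: 0.0
seed: 7
true_params:
  - {metal_element: Fe, oxidation_state: 2, ligand_element: N, r0: 1.76}
  - {metal_element: Fe, oxidation_state: 2, ligand_element: O, r0: 1.70}
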