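# Widened criterion-(iv) window for synthetic spin mixtures: low-spin sites
# generated from R0 = 1.57 read as BVS ~ 4.4 under the literature parameter
# and would otherwise be pruned before the bimodality can be detected.
filter:
  bvs_window_multiplier: 3.0
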