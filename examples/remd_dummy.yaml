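# Restrained-ensemble demo with dummy spin-labels on the label-host fixture.
# First:  molfrag fixtures --kind globular_label_host --out fx --n-sites 2 --site-separation 30
# Write a bimodal target table on the 1 A grid (two columns: bin_center value),
# e.g. with molfrag.make_target_histogram / write_histogram_table, then:
#         molfrag remd examples/remd_dummy.yaml --n-equil 1000 --n-prod 10000
pdb: ../fx/label_host.pdb

nonbonded: {delta: 1.0, switch_on: 10.0, cutoff: 12.0}
grouping: {cutoff: 12.0, max_groups: 255}

fragments:
  - {kind: dummy_label, sites: [1], n_copies: 25}
  - {kind: dummy_label, sites: [9], n_copies: 25}

restraints:
  anchor_k_label: 10.0
  backbone_positional_k: 100.0

histogram:
  K: 500.0     # kcal/mol/A^2
  sigma: 1.1   # A
  delta_r: 1.0 # A
  n_bins: 60

targets:
  - {sites: [1, 9], file: pair_1_9.hist}

protocol:
  seed: 1
  stages: []
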