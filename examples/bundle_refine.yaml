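# Bridge-refinement demo on the four-helix-bundle fixture.
# First write the fixture:  molfrag fixtures --kind four_helix_bundle --out fx --helix-length 12
# Then:                     molfrag refine examples/bundle_refine.yaml
# (run from the repository root; the pdb path below is relative to this file)
pdb: ../fx/bundle.pdb

nonbonded:
  delta: 1.0        # soft-core Delta, A^2
  switch_on: 10.0   # A
  cutoff: 12.0      # A

# sites come from fx/bridge_catalog.tsv (MF-1 and MF-3 of the default catalog)
fragments:
  - {kind: cd_bridge, sites: [106, 406]}
  - {kind: mg_bridge, sites: [208, 308]}

restraints:
  anchor_k_bridge: 50.0   # kcal/mol/A^2
  salt_bridge_k: 10.0
  ramps:
    # bridge restraints gradually turned on over the dynamics stage
    bridge_on: [[0, 3000, 0.0, 1.0]]

protocol:
  seed: 1
  stages:
    - {mode: minimize, n_steps: 500, tol: 1.0e-4}
    - {mode: dynamics, n_steps: 8000, temperature: 300.0, dt: 1.0, friction: 0.01}
    - {mode: minimize, n_steps: 500, tol: 1.0e-4}
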