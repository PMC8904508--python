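# End-to-end demo: simulate a small cohort with known history, call
# pseudo-haploid genotypes from damaged pileups, screen relatedness, and
# run the downstream analyses. `adnakit run --config examples/config_demo.yaml`
seed: 1
out: scratch/demo_run
stages: [simulate, call, relate, fstat, qpadm, dates, scan]

simulate:
  graph:
    edges:
      - [root, O1, 0.10]
      - [root, x1, 0.02]
      - [x1, O2, 0.08]
      - [x1, x2, 0.02]
      - [x2, O3, 0.08]
      - [x2, x3, 0.02]
      - [x3, O4, 0.06]
      - [x3, y, 0.02]
      - [y, O5, 0.05]
      - [y, z, 0.02]
      - [z, S1a, 0.01]
      - [z, w, 0.02]
      - [w, O6, 0.05]
      - [w, S2a, 0.02]
      - [S1a, S1, 0.01]
      - [S2a, S2, 0.01]
      - [T0, T, 0.005]
    admixtures:
      T0: [S1a, S2a, 0.7]
  panel: {n_snps: 800, n_chrom: 10, chrom_length_bp: 50000000}
  cohort:
    groups: {T: 4, S1: 4, S2: 4, O1: 2, O2: 2, O3: 2, O4: 2, O5: 2, O6: 2}
    pedigree:
      - [T0, T1, duplicate]
      - [S10, S11, parent_offspring]
    mean_depth: 2.0
    damage_rate: 0.02
  admixed:
    source1: S1
    source2: S2
    alpha: 0.6
    generations: 30
    n_individuals: 10

call:
  unit: individual

relate:
  min_overlap: 500

fstat:
  stats:
    - [f3, O1, S1, S2]
    - [f4, O1, T, S1, S2]
    - [f2, S1, S2]

qpadm:
  left: [T, S1, S2]
  right: [O1, O2, O3, O4, O5, O6]
  allsnps: true

dates:
  binsize_cM: 0.5
  max_dist_cM: 30.0

scan:
  target: T
  ancient: S1
  outgroup: O1
  window_bp: 5000000
  step_bp: 500000
  min_snps: 20
  min_ancient_individuals: 2
  ancient_coverage: 4
  block_bp: 10000000
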