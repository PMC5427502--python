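# Demonstration study: six paternal strains spanning a range of
# P-element-like and hobo-like copy numbers, quantified at 25x and
# associated with simulated F1 ovarian-atrophy phenotypes.
seed: 7
outdir: runs/demo

simulate:
  background_length: 20000   # bp of single-copy background genome
  depth: 25.0                # sequenced bases = depth x background_length
  read_length: 100
  insert_mean: 300.0
  insert_sd: 30.0
  error_rate: 0.002
  annotation_jitter: 0.05    # SD of insertion-frequency noise
  strains:
    - id: D001
      copies: []             # TE-free strain
    - id: D002
      copies:
        - {family: P, variant: FL, count: 4, frequency: 1.0}
        - {family: hobo, variant: FL, count: 2, frequency: 1.0}
    - id: D003
      copies:
        - {family: P, variant: FL, count: 8, frequency: 1.0}
        - {family: P, variant: KP, count: 3, frequency: 1.0}
    - id: D004
      copies:
        - {family: P, variant: KP, count: 5, frequency: 1.0}
        - {family: P, variant: ND, count: 2, frequency: 0.6}
        - {family: hobo, variant: FL, count: 5, frequency: 1.0}
    - id: D005
      copies:
        - {family: P, variant: FL, count: 12, frequency: 1.0}
        - {family: P, variant: KP, count: 2, frequency: 0.5}
    - id: D006
      copies:
        - {family: P, variant: FL, count: 16, frequency: 1.0}
        - {family: hobo, variant: FL, count: 3, frequency: 1.0}
        - {family: hobo, variant: DEL, count: 2, frequency: 1.0}
  phenotypes:
    beta0: -3.0              # logit of baseline atrophy odds
    beta_P: 0.25             # logits per P copy (per haploid genome)
    beta_H: 0.1              # logits per hobo copy
    sigma_block: 0.5
    sigma_strain: 0.5
    n_blocks: 4
    blocks_per_strain: 2
    females_per_strain_block: 40

quantify:
  k: 15                      # seed k-mer length
  min_overhang: 12           # minimum split-read anchor
  min_support: 2             # split reads required for a novel junction
  min_frac: 0.01             # abundance filter vs the most abundant variant
  kp_junction: [807, 2561]   # guided KP-like deletion junction

associate:
  focal: [P_normalized_coverage, P_assembly_total_cn, P_full_length_cn, P_fp_kp_ratio]
  baseline: []
  exclude: [D004]            # sensitivity rerun without this strain
  min_females: 20
  min_blocks: 2
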