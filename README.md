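# tedosage

Transposable-element dosage and structural variation from short reads,
with mixed-model association to hybrid dysgenesis.

## The problem

Hybrid dysgenesis in *Drosophila melanogaster* is a sterility syndrome
that appears in F1 females when fathers carrying active DNA transposons
(the *P*-element and the *hobo* element) are crossed to mothers that lack
the matching maternally deposited piRNAs. The severity of the syndrome —
the fraction of F1 females with atrophied ovaries — is commonly assumed
to grow with the paternal copy number of the causative element. Testing
that assumption requires (i) accurate per-strain estimates of TE copy
number and of the mixture of full-length elements versus internally
deleted derivatives (such as the repressor-encoding *KP* class), and
(ii) a statistical model linking those estimates to a per-female binary
phenotype scored across experimental blocks.

`tedosage` implements that whole chain for short-read data:

* **Coverage dosage** — reads are aligned to a TE consensus with a
  k-mer seeded aligner; normalized coverage is the mean depth over the
  consensus divided by the mean single-copy (background) depth, a
  haploid copy-number estimate.
* **Structural variants** — internal deletions are discovered as
  split-read junctions, exactly as spliced aligners discover introns: a
  read is placed as two anchors (each ≥ 12 bp) whose gap on the
  consensus is reported as a deletion `(donor, acceptor)` junction,
  normalized to its leftmost equivalent position. Known junctions (the
  KP-like deletion) can be supplied as *guided*, and are then recovered
  even at low support via realignment against the deletion-applied
  derived sequence — a two-pass scheme.
* **Variant abundances** — an expectation–maximization estimator
  fractionally assigns reads to compatible variants (full-length plus
  one variant per retained junction) and normalizes by each variant's
  effective length; variants below 1% of the most abundant variant are
  filtered out. This yields total and full-length copy numbers, class
  proportions, and the pseudocount-stabilized ratio
  `FP/KP = (FL + 0.01) / (KP + 0.01)`.
* **Annotation dosage** — insertion-caller tables (TEMP/TIDAL style)
  give a total insertion count and a frequency-weighted copy number
  `Σ fᵢ` per strain.
* **Association** — ovarian atrophy `yᵢⱼ ∈ {0,1}` of female *i* from
  paternal strain *s(i)* in block *b(i)* is modeled as a binomial GLMM,

  `logit P(y=1) = β₀ + β·x_{s(i)} + u_{b(i)}`,  `u_b ~ N(0, σ²_b)`,

  fitted by Laplace-approximated maximum likelihood (adaptive
  Gauss–Hermite refinement for a single random factor). Each dosage
  estimator *x* is scored by a nested likelihood-ratio test against the
  null model, with ΔAIC and the association sign, and the whole ledger
  can be rerun excluding outlier strains. Strains enter only if they
  contributed ≥ 20 females in each of ≥ 2 blocks.

A first-class synthetic-data module generates diploid strain genomes
(with segregating insertions), paired-end reads, annotation tables and
per-female phenotypes with known truth, so every estimator is validated
against its generative model.

## Worked example

`examples/config.yaml` defines a six-strain study (copy numbers 0–16,
FL/KP/other mixtures) and a simulated phenotype experiment:

```bash
tedosage simulate  -c examples/config.yaml
tedosage quantify  -c examples/config.yaml
tedosage associate -c examples/config.yaml
tedosage dosage --outdir runs/demo --family P
```

The dosage matrix printed for the P-element-like family:

```
strain family  normalized_coverage  assembly_total_cn  full_length_cn  prop_full_length  prop_kp  annotation_weighted
  D001      P             0.000000           0.000000        0.000000               NaN      NaN             0.000000
  D002      P             4.251773           4.396204        4.396204          1.000000      NaN             4.000000
  D003      P             8.948555          11.395665        8.023508          0.704084 0.295916            10.924187
  D004      P             2.849662           7.412752        0.000000               NaN 0.740482             6.497569
  D005      P            12.641133          14.114438       12.488766          0.884822 0.115178            13.301330
  D006      P            17.343694          17.924326       17.924326          1.000000      NaN            15.672825
```

Reading it: strain D003 truly carries 8 full-length + 3 KP-like copies —
the assembly estimates 11.4 total, 8.0 full-length and a 0.70/0.30
class split; D004 carries only deletion derivatives (5 KP + 2 other),
so its full-length copy number is 0 and its normalized coverage (2.8)
sits far below its total copy number (7.4), because deleted copies
contribute less consensus depth. `tedosage report` then shows the
association ledger (simulated with a true positive dosage effect of
0.25 logits per P copy):

```
            estimator            p sign  delta_aic   p_excluded sign_excluded
P_normalized_coverage 1.227767e-15    + -62.026181 7.525791e-15             +
  P_assembly_total_cn 1.278729e-15    + -61.946059 2.136842e-14             +
     P_full_length_cn 1.754534e-14    + -56.789744 7.674881e-15             +
        P_fp_kp_ratio 2.189589e-07    + -24.858063 4.700646e-08             +
```

Every estimator is significantly, positively associated with F1
ovarian atrophy, with and without the configured strain exclusion — as
it should be for data simulated under a dosage-dependent model.

## Layout

| module | role |
| --- | --- |
| `tedosage.synthetic_data` | strain genomes, reads, annotation tables, phenotypes, truth tables |
| `tedosage.consensus_align` | k-mer seeded consensus alignment, junction discovery, depth |
| `tedosage.variant_model` | junction evidence, EM abundances, 1% filter, FL/KP/OTHER classes |
| `tedosage.dosage` | per-strain estimators and the strain × estimator dosage matrix |
| `tedosage.assoc` | binomial GLMM (Laplace/AGQ), LRT, association ledgers, strain filter |
| `tedosage.pipeline_io` | YAML config, FASTA/FASTQ/TSV IO, stage orchestration, manifests |

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
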