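# orthoqa

Comparative quality assessment of protein-coding genome annotations.

When a clade of genomes is annotated by computational pipelines, the
annotations themselves carry the best evidence of their own quality:
orthologous genes should encode proteins with similar sequences, similar
domain architectures, and — more stringently — the same pattern of
protein-coding exons. `orthoqa` implements a protocol that exploits this:

* **Ortholog sets** are built by best-hit protein names confirmed with
  local synteny (≥ 2 of the six flanking genes matching in order and
  orientation, or a shared neighbor for genes single-copy in both
  species), anchored on a designated species.
* **Splice variants** are clustered across species by reciprocal best
  alignment hits merged greedily (never two proteins of one gene in a
  cluster), giving groups of mutually closest isoforms.
* **Splicing orthologs** are detected by mapping CDS exon structures
  through protein alignments: two proteins qualify when all coding exons
  pair one-to-one with ≥ 90% overlap in the lengths of both exons,

  > overlap(eᵢ, eⱼ) ≥ 0.9·|eᵢ| and ≥ 0.9·|eⱼ| for every matched pair,

  with overlap measured in aligned CDS nucleotides. Failures are
  classified as exon split/merge, exon loss, incomplete alignment, or
  pure length variation. Support counts against 12 reference genomes
  define conserved CDS and "core protein" sets.
* **Protein-consistency screens** flag domain-content outliers (Jaccard
  similarity of superfamily sets, Z-scored against references), extra /
  missing / truncated domains, region-aware length outliers, poor
  N-terminal identity, and start codons whose initial Met aligns to a
  downstream Met in the references.
* **Per-organism scorecards** aggregate five flagged-gene fractions
  f₁..f₅ into a negative sum-of-logs quality score
  −Σᵢ log₁₀ max(fᵢ, 1/n): higher is better, independent of assembly
  metrics, and can be correlated against contig N50 or EST counts.

A seeded synthetic-clade generator produces full annotation bundles
(GFF3, protein FASTA, domain/best-hit/signal-peptide tables) with known
ortholog, isoform and exon structure, plus eight classes of injectable
annotation errors with truth labels, so every screen's sensitivity and
false-flag rate is measurable. See `docs/methods.md` for the model and
its assumptions.

## Worked example

Generate an 8-species clade (6 reference species, 40 genes) with a
graded error burden averaging 5% per class, then run the full protocol:

```sh
orthoqa synth --config clade.yaml --errors errors.yaml --seed 4 --out data
orthoqa run-all --data-dir data --out results --seed 4 --config run.yaml
```

where `clade.yaml` holds `n_species: 8`, `n_reference: 6`, `n_genes: 40`,
`errors.yaml` holds `base_rate: 0.05`, and `run.yaml` scales the core
threshold to the clade (`core_min_organisms: 4`). The run prints

```
{"ortholog_sets": 40, "clusters": 50, "conserved_pairs": 872,
 "flagged_proteins": 151, "core_sets": 39, "seed": 4}
```

— all 40 true ortholog sets were recovered, their isoforms fell into 50
clusters, 872 protein pairs are splicing orthologs, and 39 sets qualify
as core. `results/scorecard.tsv` begins

```
tax_id  n_genes  f_domain_z  f_domain_anom  f_length  f_met  f_not_main_cluster  aggregate_score  core_proteins
9001    40       0.000       0.000          0.000     0.000  0.0                 8.010            39
9002    40       0.025       0.025          0.050     0.000  0.0                 7.709            35
9003    40       0.050       0.075          0.050     0.025  0.0                 6.931            37
...
9008    40       0.125       0.325          0.325     0.075  0.0                 4.606            24
```

Species were generated with error rates rising linearly from 0 (tax
9001) to 10% per class (tax 9008); the aggregate score falls
monotonically with the injected burden, from 8.01 for the error-free
anchor (all five fractions at the 1/40 floor: 5·log₁₀40 ≈ 8.01) to 4.61
for the worst genome. `results/protein_flags.tsv` holds the per-protein
screen calls, e.g.

```
protein_id      tax_id  prefix  domain_z_outlier  extra_domain  missing_domain ...
XP_9005G0001T1  9005    XP      True              False         True
XP_9005G0003T1  9005    XP      True              True          False
```

The same pipeline is callable as a library (`orthoqa.pipeline.run`) on
any per-species bundles readable by `orthoqa.io.read_annotation_bundle`.

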