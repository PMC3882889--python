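# Methods

`orthoqa` implements a comparative protocol for assessing the quality of
protein-coding genome annotations across a clade. All evidence is drawn
from the annotations themselves — gene/mRNA/CDS features, protein
sequences, domain-hit tables, best-hit names — so the resulting quality
score is independent of assembly metrics (contig N50) and expression
evidence (EST counts), which serve only as external covariates for
validation.

## Ortholog sets

Each gene receives the name of its best database hit (highest bit score
with query coverage ≥ 50%; bit-score ties resolved to the
lexicographically smallest name so runs are reproducible). Genes sharing
a name across species are candidate orthologs, anchored on the designated
anchor species (one set per named anchor gene). A candidate is confirmed
by local synteny: at least two of the six flanking genes (three per side,
sides taken relative to transcription direction) match in side and
relative orientation, or both genes are the only carriers of their name
in their species ("single copy") and share at least one flanking gene. A
flanking match does not require the same rank within the three-gene
window; exact rank would be brittle to micro-rearrangements, and the
window is small enough that rank-free matching stays specific. When a
species has several same-named candidates, the one with the most flanking
matches joins the set (ties by gene identifier).

## Splice-variant clustering

Within a set, all proteins of reference-species genes are aligned to all
proteins in the set (exact affine-gap Smith–Waterman, BLOSUM62, gap open
12 / extend 1, no compositional adjustment or masking; a full DP aligner
is affordable at cluster scale and makes scores exactly reproducible).
Reciprocal best hits between each gene pair — score ties resolved to the
subject whose length is closest to the query, then accession — are merged
greedily in descending score order, refusing any merge that would place
two proteins of one gene in a cluster. Because a set holds at most one
gene per species, clusters also hold at most one protein per species.
The largest cluster is the "main" cluster (ties: contains the anchor
protein, then largest summed merge score).

## Splicing orthologs

Protein alignments transfer CDS coordinates between species: each aligned
residue pair contributes its three CDS nucleotides, attributed to exon
pairs through the two transcripts' exon maps (the annotated stop codon is
trimmed first so exon lengths describe the translated product). The
terminal aligned exons are extended gap-free to the beginning/end of the
respective exons, which keeps ragged local-alignment ends from erasing
terminal exons; CDS positions not covered by a defined exon inherit the
previous exon's label. Two proteins are **splicing orthologs** when their
coding exons pair one-to-one (mutual dominant partners — deterministic,
local, and directly diagnostic of splits and merges) and every pair
overlaps by at least 90% of both exon lengths (inclusive comparison).
Overlap is alignment-mediated rather than a bare length ratio: unrelated
exons of equal length should not count as conserved. Additional reported
criteria: all exons aligned, one-to-one mapping, exon lengths within ±15
codons (45 nt — the companion human–mouse literature uses codon
tolerance; configurable), and all splice junctions aligned at offset 0
(only defined when both proteins have ≥ 2 coding exons).

Non-conserved pairs are classified by precedence: **split/merge** (an
exon with two partners each covering ≥ 10% of it), **exon loss** (an exon
with < 10% of its length aligned while the remainder map one-to-one; the
10% tolerance absorbs a few nucleotides of DP gap-placement jitter at
exon boundaries), **not all exons aligned**, else **one-to-one with
length variation**. The 90% rule is deliberately non-transitive: lengths
in ratio 1 : 0.9 : 0.81 give a conserved chain A–B, B–C with A–C
unconserved.

Reference support for a protein is the number of reference species whose
clustered counterpart is a splicing ortholog (own species excluded, so a
reference protein can reach at most r−1 of r references). Core ortholog
sets are those where at least 17 organisms have support ≥ 3; a species'
core-protein count is the number of core sets in which its own protein
meets that bar.

## Protein-consistency screens

Screens run in clusters with at least five reference proteins (r ≥ 5) and
benchmark every member against the reference members. Z-scores always use
the reference members' own values of the statistic for mean and standard
deviation; a zero-spread reference distribution gives Z = 0 at the mean
and an infinite sentinel elsewhere. Thresholds are strict inequalities.

* **Domain content.** Domain composition is the *set* of superfamily
  identifiers (a signal-peptide call participates as one pseudo-term);
  repeat-count changes are the truncation test's business, not Jaccard's.
  The Jaccard score |P∩Q|/|P∪Q| is undefined when both sets are empty.
  Per gene, the isoform with maximal mean Jaccard versus its cluster's
  references represents the gene (ties: longest, then accession). A
  protein is a domain-score outlier when |Z| > 2 on its mean Jaccard.
  A superfamily present in ≥ r−1 references but not the query is
  **missing**; present in the query but absent from ≥ r−1 references,
  **extra**; and a shared superfamily whose maximum hit-length fraction
  in the query is < 0.6 and < 0.6 × the fraction in ≥ r−1 of the other
  references is **truncated**. All three anomaly tests compare against
  references with an r−1 requirement (this lets references be tested
  themselves, and keeps one aberrant protein elsewhere in the cluster
  from masking a real anomaly — under an all-members comparison a single
  independently damaged protein suppressed roughly a third of genuine
  truncations in simulation). The truncation threshold is applied to the
  hit-length *fraction*, the only dimensionally consistent reading.

* **Lengths.** Each cluster gets a center-star multiple alignment (center
  = member with maximal summed alignment score; every other member is
  aligned to the center globally and merged on center coordinates,
  "once a gap, always a gap" — deterministic, and downstream tests use
  only gap fractions and column identities, so a heavier progressive
  aligner would add fidelity the screens cannot see). Columns with
  reference gap content ≤ 20% form conserved blocks; runs before/after
  the first/last conserved block are N-/C-terminal, other non-conserved
  runs intermediate. The length statistic is the mean signed length
  difference versus references, per region, over the whole protein, and
  over fixed N-terminal windows of 30 and 100 residues (short regions and
  the upper bound of mitochondrial transit peptides). The window delta
  spans the columns holding either protein's first w residues, making it
  antisymmetric and sensitive to truncation and extension alike. Fixed
  windows flag conjunctively (|mean Δ| > 15 AND |Z| > 3); regions and
  whole protein disjunctively (either). The mean (the literal "average
  length difference") rather than a per-reference count keeps one
  similarly damaged reference from shielding a query.

* **N-terminal identity.** Mean ungapped identity versus references over
  the first 30/100 query residues must satisfy all of: identity < 50%,
  |Z(identity)| > 2, and |Z(log(N-terminal / whole-sequence identity))| >
  2 — the ratio term screens out globally divergent proteins whose
  N-terminus is no worse than the rest.

* **Start methionine.** A protein is flagged when its initial Met column
  aligns to a downstream (non-initial) Met of the counterpart, or vice
  versa, in more than (r−1)/2 reference comparisons.

## Organism scorecards

Per organism, over genes in analyzed sets (main cluster with r ≥ 5), five
flagged-gene fractions are computed: domain-score outliers; extra,
missing or truncated domains; length outliers; conserved downstream Met;
and genes with no protein in the main cluster. A gene is flagged when any
of its proteins is. The aggregate score is −Σ log₁₀(max(fᵢ, floor)) with
floor = 1/(analyzed genes): higher is better, and the floor keeps the
score finite when a fraction is zero (logs are base 10 — the published
score magnitudes are only consistent with base 10, e.g. fractions
0.002/0.033/0.036/0.051/0.049 aggregate to ≈ 8.23). The scorecard table
appends per-column means, standard deviations, and Pearson correlations
against contig N50 and EST count; subgroup correlations (e.g. excluding
designated outlier organisms) are available separately.

## Synthetic clades

The generator emulates the statistical structure the analysis assumes: a
single ancestral chromosome of multi-exon genes evolved down a balanced
binary tree by codon substitution (default 1% per codon per branch; start
codon, an internal in-frame ATG planted at codon 25, and the stop codon
are held invariant), defaults of 20 species with the first 12 as
references and 500 genes of 3–7 exons averaging 150 nt. Exon lengths are
multiples of three so exon-level edits never shift frame — codon-spanning
junctions are exercised by hand-built fixtures instead. About 30% of
genes carry one splice variant skipping a fixed internal exon, the same
exon in every species, so isoform clusters have unambiguous truth. Domains
are intervals tied to exon runs with hit fraction 1; best-hit names are
the ancestral gene names; a fraction of proteins carry signal peptides.
Protein FASTA is derived by extracting and translating exons from the
rendered genome, so sequence and structure cannot disagree.

Error injection mutates one species' copy of a gene in one of eight ways
(N-terminal truncation of 30 codons; start moved to the planted
downstream Met; loss, merge or split of an internal exon; domain deletion,
addition, or truncation to fraction 0.4), at most one class per gene per
species, each recorded in a truth table. Structural edits propagate to
domain tables by interval remapping (a domain wholly inside a lost span
disappears; partial overlaps shrink the interval and rescale the hit
fraction). Per-species rates may be uniform or graded linearly from 0 to
2× a base rate (mean = base), and species metadata (contig N50, EST
count) is re-derived from the mean rate so assembly quality covaries with
annotation quality as it does in real collections.

What the generator does **not** model: indel-rich divergence (indels are
available but default off, so that a clean clade is exactly conserved and
any flag is attributable to an injection), paralogous families and gene
duplications, UTR structure, alternative promoters, repeat or GC genome
structure, and realistic phylogenetic branch lengths. Passing recovery
tests therefore demonstrates the screens' mechanics and thresholds, not
their operating characteristics on real genomes, where reference spread
is wider and orthology itself is uncertain.

## Problem sizes and numerical choices

The full-scale evaluation (tests and examples) uses the default 20
species × 500 genes clade — about 13,000 proteins and ~170,000 cached
pairwise alignments — which completes in a few minutes on one CPU; unit
and property tests use clades of 3–10 species and tens of genes.
Alignment scores are integers under BLOSUM62, so score ties are real and
every tie-break (lexicographic names, length-closeness, accession order)
is specified; all randomized choices (identical-protein representative,
error placement) flow from explicit seeds, and reruns are byte-identical.
Degenerate inputs are defined rather than erroneous: empty alignments
give zero overlap matrices, single-exon pairs leave the junction
criterion undefined, clusters with r < 5 produce no screen flags, and
organisms with no analyzed genes are omitted from the scorecard with a
warning.
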