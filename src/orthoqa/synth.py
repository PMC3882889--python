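"""Seeded synthetic clades with known ortholog, isoform and exon structure.

The generator emulates the statistical structure the analysis assumes: a
clade of species sharing orthologous multi-exon genes (evolved along a
balanced binary tree by codon substitution), consistent splice variants
(the same exon-skip pattern in every species), domain annotations tied to
exon spans, best-hit names shared across true orthologs, and species
metadata.  Error injection then mutates individual species' annotations
in the eight ways the downstream screens target, recording a truth table
so every screen's sensitivity and false-flag rate can be measured.

Everything is deterministic under the config seed; mutated protein
sequences always re-derive exactly from the mutated gene structures and
the species' genome sequence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from . import io as oio
from .model import (
    AnnotationBundle,
    DomainHit,
    GeneRecord,
    ProteinRecord,
    SpeciesInfo,
    TranscriptRecord,
    ValidationError,
)

STOP_CODON = "TAA"
_BASES = "ACGT"
_NON_STOP = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]
MET_CODON_INDEX = 25  # an internal in-frame ATG planted in every gene
ERROR_CLASSES = (
    "nterm_truncation",
    "downstream_start",
    "exon_loss",
    "exon_merge",
    "exon_split",
    "domain_deletion",
    "domain_addition",
    "domain_truncation",
)
EXPECTED_FLAG = {
    "nterm_truncation": "length_or_nterm",
    "downstream_start": "downstream_met",
    "exon_loss": "exon_loss",
    "exon_merge": "split_merge",
    "exon_split": "split_merge",
    "domain_deletion": "missing_domain",
    "domain_addition": "extra_domain",
    "domain_truncation": "truncated_domain",
}


@dataclass
class CladeConfig:
    """Study conditions for a synthetic clade.

    Defaults model a mammal-scale evaluation: 20 organisms of which 12
    are higher-quality reference species, 500 shared genes with 3-7
    coding exons of ~150 nt, ~1% codon substitutions per tree branch, and
    isoforms (one skipped internal exon, consistent across species) for
    about 30% of genes.
    """

    n_species: int = 20
    n_reference: int = 12
    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_length_mean: int = 150
    exon_length_sd: int = 45
    min_exon_length: int = 30
    first_exon_min: int = 120
    intron_codons: int = 33
    substitution_rate: float = 0.01  # per codon per branch
    indel_rate: float = 0.0  # per gene per branch (one codon indel)
    isoform_prob: float = 0.3
    rearrangement_rate: float = 0.0
    name_noise: float = 0.0
    signal_peptide_prob: float = 0.2
    max_domains: int = 3
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, self.isoform_prob,
                     self.rearrangement_rate, self.name_noise, self.signal_peptide_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate {rate} outside [0, 1]")
        if self.min_exon_length < 3:
            raise ValidationError("exons must hold at least one codon")
        if self.n_reference > self.n_species:
            raise ValidationError("more reference species than species")


@dataclass
class ErrorSpec:
    """Per-species, per-class injection rates (fraction of genes)."""

    rates: dict[int, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def uniform(cls, taxa: list[int], rate: float, classes=ERROR_CLASSES) -> "ErrorSpec":
        return cls({t: {c: rate for c in classes} for t in taxa})

    @classmethod
    def graded(cls, taxa: list[int], base_rate: float = 0.02, classes=ERROR_CLASSES) -> "ErrorSpec":
        """Linear quality gradient: species i gets 2*i/(n-1) times the base
        rate, so rates span 0..2x base with mean equal to the base rate."""
        n = len(taxa)
        return cls(
            {
                t: {c: base_rate * (2 * i / (n - 1) if n > 1 else 1.0) for c in classes}
                for i, t in enumerate(taxa)
            }
        )

    def mean_rate(self, tax: int) -> float:
        r = self.rates.get(tax, {})
        return sum(r.values()) / len(r) if r else 0.0


# ---------------------------------------------------------------------------
# Internal simulation state
# ---------------------------------------------------------------------------

@dataclass
class SimGene:
    """One gene in one species: codon list (stop included), exon/intron
    layout (nt, multiples of 3), gene-level domains in full-length protein
    residue coordinates, and the consistent skip-exon isoform pattern."""

    name: str
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    intron_seqs: list[str]
    codons: list[str]
    skip_exon: int | None
    domains: list[list]  # [superfamily_id, start, end, pssm_length, fraction]
    has_signal: bool
    error: str | None = None

    def n_codons(self) -> int:
        return len(self.codons)

    def cds(self) -> str:
        return "".join(self.codons)


@dataclass
class SyntheticClade:
    config: CladeConfig
    species: list[SpeciesInfo]
    genes: dict[int, list[SimGene]]  # tax_id -> per-gene state (ancestral order)
    gene_order: dict[int, list[int]]  # tax_id -> gene indices in chromosome order
    truth_errors: pd.DataFrame | None = None

    @property
    def anchor_taxon(self) -> int:
        return self.species[0].tax_id

    @property
    def reference_taxa(self) -> set[int]:
        return {s.tax_id for s in self.species if s.is_reference}


def _random_gene(rng: random.Random, cfg: CladeConfig, idx: int) -> SimGene:
    n_exons = rng.randint(*cfg.exons_per_gene)
    lens = []
    for k in range(n_exons):
        ln = int(round(rng.gauss(cfg.exon_length_mean, cfg.exon_length_sd)))
        ln = max(cfg.min_exon_length, ln)
        ln -= ln % 3
        if k == 0:
            ln = max(ln, cfg.first_exon_min)
        lens.append(ln)
    total_codons = sum(lens) // 3
    codons = [rng.choice(_NON_STOP) for _ in range(total_codons)]
    codons[0] = "ATG"
    if total_codons > MET_CODON_INDEX + 5:
        codons[MET_CODON_INDEX] = "ATG"
    codons[-1] = STOP_CODON
    introns = [
        "".join(rng.choice(_NON_STOP) for _ in range(cfg.intron_codons))
        for _ in range(n_exons - 1)
    ]
    skip = None
    if n_exons >= 3 and rng.random() < cfg.isoform_prob:
        skip = rng.randrange(1, n_exons - 1)
    # domains: contiguous exon runs mapped to residue intervals
    n_dom = rng.randint(1, cfg.max_domains)
    bounds = [0]
    for ln in lens:
        bounds.append(bounds[-1] + ln)
    protein_len = total_codons - 1
    domains = []
    for d in range(n_dom):
        a = rng.randrange(0, n_exons)
        b = min(n_exons - 1, a + rng.randint(0, 1))
        s = bounds[a] // 3
        e = min(protein_len, (bounds[b + 1] + 2) // 3)
        if e - s < 10:
            continue
        domains.append([f"SF{idx:04d}_{d}", s, e, e - s, 1.0])
    if not domains:
        domains.append([f"SF{idx:04d}_0", 0, min(protein_len, lens[0] // 3), min(protein_len, lens[0] // 3), 1.0])
    return SimGene(
        name=f"GN{idx:04d}",
        strand=rng.choice("+-"),
        exon_lens=lens,
        intron_lens=[len(s) for s in introns],
        intron_seqs=introns,
        codons=codons,
        skip_exon=skip,
        domains=domains,
        has_signal=rng.random() < cfg.signal_peptide_prob,
    )


def _mutate_branch(genes: list[SimGene], cfg: CladeConfig, rng: random.Random) -> list[SimGene]:
    out = []
    for g in genes:
        codons = list(g.codons)
        protected = {0, len(codons) - 1}
        if len(codons) > MET_CODON_INDEX + 5:
            protected.add(MET_CODON_INDEX)
        for i in range(len(codons)):
            if i in protected:
                continue
            if rng.random() < cfg.substitution_rate:
                codons[i] = rng.choice(_NON_STOP)
        g2 = replace(
            g,
            codons=codons,
            exon_lens=list(g.exon_lens),
            intron_lens=list(g.intron_lens),
            intron_seqs=list(g.intron_seqs),
            domains=[list(d) for d in g.domains],
        )
        if cfg.indel_rate and rng.random() < cfg.indel_rate:
            _apply_codon_indel(g2, rng)
        out.append(g2)
    return out


def _apply_codon_indel(g: SimGene, rng: random.Random) -> None:
    """Insert or delete one codon inside a random exon (never the first or
    last codon, never the planted Met)."""
    bounds = [0]
    for ln in g.exon_lens:
        bounds.append(bounds[-1] + ln)
    k = rng.randrange(len(g.exon_lens))
    lo = bounds[k] // 3
    hi = bounds[k + 1] // 3
    candidates = [i for i in range(max(1, lo), hi) if i not in (MET_CODON_INDEX, len(g.codons) - 1)]
    if not candidates:
        return
    i = rng.choice(candidates)
    if rng.random() < 0.5 and g.exon_lens[k] > 3 * 2:
        del g.codons[i]
        g.exon_lens[k] -= 3
        _remap_domains_remove(g, i, 1)
    else:
        g.codons.insert(i, rng.choice(_NON_STOP))
        g.exon_lens[k] += 3
        _remap_domains_insert(g, i, 1)


def _remap_domains_remove(g: SimGene, start: int, length: int) -> None:
    """Remove a residue span; domains shrink or disappear, with the hit
    fraction rescaled to the surviving coverage of the original PSSM."""
    def f(x: int) -> int:
        return x - min(max(x - start, 0), length)

    kept = []
    for sf, s, e, plen, frac in g.domains:
        ns, ne = f(s), f(e)
        if ne - ns <= 0:
            continue
        new_frac = frac * (ne - ns) / (e - s)
        kept.append([sf, ns, ne, plen, new_frac])
    g.domains = kept


def _remap_domains_insert(g: SimGene, start: int, length: int) -> None:
    out = []
    for sf, s, e, plen, frac in g.domains:
        if start <= s:
            out.append([sf, s + length, e + length, plen, frac])
        elif start < e:
            out.append([sf, s, e + length, plen, frac])
        else:
            out.append([sf, s, e, plen, frac])
    g.domains = out


def generate_clade(config: CladeConfig) -> SyntheticClade:
    """Evolve the ancestral gene set down a balanced binary tree.

    Species i receives tax_id 9001+i; the first species is the anchor and
    the first ``n_reference`` are the reference set.
    """
    config.validate()
    rng = random.Random(config.seed)
    ancestor = [_random_gene(rng, config, i) for i in range(config.n_genes)]

    leaves: list[list[SimGene]] = [None] * config.n_species

    def evolve(node_genes: list[SimGene], lo: int, hi: int) -> None:
        if hi - lo == 1:
            leaves[lo] = node_genes
            return
        mid = (lo + hi + 1) // 2
        evolve(_mutate_branch(node_genes, config, rng), lo, mid)
        evolve(_mutate_branch(node_genes, config, rng), mid, hi)

    evolve(ancestor, 0, config.n_species)

    species = [
        SpeciesInfo(
            tax_id=9001 + i,
            name=f"species_{i:02d}",
            is_reference=i < config.n_reference,
            contig_n50=5_000_000,
            est_count=1_000_000,
        )
        for i in range(config.n_species)
    ]
    genes = {species[i].tax_id: leaves[i] for i in range(config.n_species)}
    gene_order = {}
    for i, sp in enumerate(species):
        order = list(range(config.n_genes))
        if config.rearrangement_rate:
            moved = [k for k in order if rng.random() < config.rearrangement_rate]
            targets = list(moved)
            rng.shuffle(targets)
            mapping = dict(zip(moved, targets))
            order = [mapping.get(k, k) for k in order]
        gene_order[sp.tax_id] = order
        if config.name_noise:
            for k, g in enumerate(genes[sp.tax_id]):
                if sp.tax_id != species[0].tax_id and rng.random() < config.name_noise:
                    g.name = f"NOISE_{sp.tax_id}_{k}"
    return SyntheticClade(config=config, species=species, genes=genes, gene_order=gene_order)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def inject_errors(clade: SyntheticClade, spec: ErrorSpec, seed: int | None = None) -> SyntheticClade:
    """Apply annotation errors in place and record a truth table.

    Classes are drawn independently per gene per species at the spec's
    rates; a gene receives at most one error per species.  Edits that do
    not fit a gene (too few exons, no domain to delete...) are skipped.
    Species metadata (contig N50, EST count) is re-derived from the mean
    injection rate so assembly quality covaries with annotation quality.
    """
    rng = random.Random(clade.config.seed + 7919 if seed is None else seed)
    rows = []
    for sp in clade.species:
        rates = spec.rates.get(sp.tax_id, {})
        sim_genes = clade.genes[sp.tax_id]
        for cls in ERROR_CLASSES:
            rate = rates.get(cls, 0.0)
            if rate <= 0:
                continue
            for gi, g in enumerate(sim_genes):
                if g.error is not None or rng.random() >= rate:
                    continue
                if _apply_error(g, cls, rng):
                    g.error = cls
                    rows.append(
                        {
                            "tax_id": sp.tax_id,
                            "gene_id": f"g{sp.tax_id}_{gi:04d}",
                            "gene_index": gi,
                            "error_class": cls,
                            "expected_flag": EXPECTED_FLAG[cls],
                        }
                    )
    clade.truth_errors = pd.DataFrame(
        rows, columns=["tax_id", "gene_id", "gene_index", "error_class", "expected_flag"]
    )
    new_species = []
    for sp in clade.species:
        mean = spec.mean_rate(sp.tax_id)
        new_species.append(
            replace(
                sp,
                contig_n50=int(5_000_000 / (1.0 + 400.0 * mean)),
                est_count=int(2_000_000 / (1.0 + 800.0 * mean)),
            )
        )
    clade.species = new_species
    return clade


def _apply_error(g: SimGene, cls: str, rng: random.Random) -> bool:
    n_exons = len(g.exon_lens)
    internal = [k for k in range(1, n_exons - 1) if k != g.skip_exon]
    if cls == "nterm_truncation":
        cut = 30
        if g.exon_lens[0] < 3 * cut + 30 or len(g.codons) <= cut + 20:
            return False
        del g.codons[:cut]
        g.exon_lens[0] -= 3 * cut
        _remap_domains_remove(g, 0, cut)
        return True
    if cls == "downstream_start":
        cut = MET_CODON_INDEX
        if (
            len(g.codons) <= MET_CODON_INDEX + 5
            or g.codons[MET_CODON_INDEX] != "ATG"
            or g.exon_lens[0] < 3 * cut + 30
        ):
            return False
        del g.codons[:cut]
        g.exon_lens[0] -= 3 * cut
        _remap_domains_remove(g, 0, cut)
        return True
    if cls == "exon_loss":
        if not internal:
            return False
        k = rng.choice(internal)
        bounds = _exon_bounds(g)
        s, e = bounds[k] // 3, bounds[k + 1] // 3
        del g.codons[s:e]
        del g.exon_lens[k]
        # the flanking introns collapse into one
        del g.intron_seqs[k - 1]
        del g.intron_lens[k - 1]
        if g.skip_exon is not None and g.skip_exon > k:
            g.skip_exon -= 1
        _remap_domains_remove(g, s, e - s)
        return True
    if cls == "exon_merge":
        pairs = [
            k
            for k in range(1, n_exons - 2)
            if g.skip_exon not in (k, k + 1)
        ]
        if not pairs:
            return False
        k = rng.choice(pairs)
        bounds = _exon_bounds(g)
        insert_at = bounds[k + 1] // 3
        intron = g.intron_seqs[k]
        added = [intron[i : i + 3] for i in range(0, len(intron), 3)]
        g.codons[insert_at:insert_at] = added
        g.exon_lens[k] = g.exon_lens[k] + len(intron) + g.exon_lens[k + 1]
        del g.exon_lens[k + 1]
        del g.intron_seqs[k]
        del g.intron_lens[k]
        if g.skip_exon is not None and g.skip_exon > k + 1:
            g.skip_exon -= 1
        _remap_domains_insert(g, insert_at, len(added))
        return True
    if cls == "exon_split":
        candidates = [k for k in internal if g.exon_lens[k] >= 60]
        if not candidates:
            return False
        k = rng.choice(candidates)
        half = (g.exon_lens[k] // 6) * 3
        rest = g.exon_lens[k] - half
        g.exon_lens[k : k + 1] = [half, rest]
        new_intron = "".join(rng.choice(_NON_STOP) for _ in range(33))
        g.intron_seqs.insert(k, new_intron)
        g.intron_lens.insert(k, len(new_intron))
        if g.skip_exon is not None and g.skip_exon > k:
            g.skip_exon += 1
        return True
    if cls == "domain_deletion":
        if not g.domains:
            return False
        del g.domains[rng.randrange(len(g.domains))]
        return True
    if cls == "domain_addition":
        plen = 50
        start = rng.randrange(0, max(1, len(g.codons) - 1 - plen))
        g.domains.append(
            [f"SFX_{rng.randrange(10**6):06d}", start, start + plen, plen, 1.0]
        )
        return True
    if cls == "domain_truncation":
        big = [d for d in g.domains if d[4] >= 0.9]
        if not big:
            return False
        d = big[rng.randrange(len(big))]
        d[4] = 0.4
        d[2] = d[1] + max(5, int(0.4 * d[3]))
        return True
    raise ValueError(f"unknown error class {cls!r}")


def _exon_bounds(g: SimGene) -> list[int]:
    bounds = [0]
    for ln in g.exon_lens:
        bounds.append(bounds[-1] + ln)
    return bounds


# ---------------------------------------------------------------------------
# Rendering to annotation bundles
# ---------------------------------------------------------------------------

SPACER = 120


def _render_species(clade: SyntheticClade, sp: SpeciesInfo):
    """Build the species' chromosome and cross-linked records; protein
    sequences are derived by extracting and translating exons from the
    rendered genome so FASTA and GFF3 can never disagree."""
    sim_genes = clade.genes[sp.tax_id]
    order = clade.gene_order[sp.tax_id]
    chrom_parts: list[str] = []
    pos = 0
    genes: list[GeneRecord] = []
    rng = random.Random(clade.config.seed * 1000003 + sp.tax_id)
    slots = sorted(range(len(order)), key=lambda gi: order[gi])
    for gi in slots:
        g = sim_genes[gi]
        spacer = "".join(rng.choice(_BASES) for _ in range(SPACER))
        chrom_parts.append(spacer)
        pos += SPACER
        cds = g.cds()
        bounds = _exon_bounds(g)
        tx_parts = []
        exon_tx: list[tuple[int, int]] = []  # in transcription-direction segment coords
        seg_pos = 0
        for k, ln in enumerate(g.exon_lens):
            tx_parts.append(cds[bounds[k] : bounds[k + 1]])
            exon_tx.append((seg_pos, seg_pos + ln))
            seg_pos += ln
            if k < len(g.intron_seqs):
                tx_parts.append(g.intron_seqs[k])
                seg_pos += g.intron_lens[k]
        segment = "".join(tx_parts)
        if g.strand == "-":
            genomic_segment = str(Seq(segment).reverse_complement())
            exons = [
                (pos + len(segment) - e, pos + len(segment) - s) for s, e in exon_tx
            ]
        else:
            genomic_segment = segment
            exons = [(pos + s, pos + e) for s, e in exon_tx]
        chrom_parts.append(genomic_segment)
        gene_id = f"g{sp.tax_id}_{gi:04d}"
        gene = GeneRecord(
            gene_id=gene_id,
            species=sp.tax_id,
            chrom="chr1",
            span=(pos, pos + len(segment)),
            strand=g.strand,
            swissprot_name=g.name,
        )
        prefix = "NP" if sp.tax_id == clade.anchor_taxon else "XP"
        isoforms: list[tuple[str, list[tuple[int, int]]]] = [("t1", exons)]
        if g.skip_exon is not None:
            kept = [e for k, e in enumerate(exons) if k != g.skip_exon]
            isoforms.append(("t2", kept))
        for t_name, t_exons in isoforms:
            pid = f"{prefix}_{sp.tax_id}G{gi:04d}{t_name.upper()}"
            gene.transcripts.append(
                TranscriptRecord(f"{gene_id}_{t_name}", t_exons, pid)
            )
        pos += len(segment)
        genes.append(gene)
    chrom = "".join(chrom_parts)
    # derive proteins from the genome
    for gene in genes:
        gi = int(gene.gene_id.rsplit("_", 1)[1])
        g = sim_genes[gi]
        for t in gene.transcripts:
            spliced = []
            for s, e in t.coding_exons:
                part = chrom[s:e]
                if gene.strand == "-":
                    part = str(Seq(part).reverse_complement())
                spliced.append(part)
            cds = "".join(spliced)
            protein = str(Seq(cds).translate())
            if not protein.endswith("*") or "*" in protein[:-1]:
                raise ValidationError(
                    f"internal stop or missing stop in synthetic CDS {t.protein_id}"
                )
            protein = protein[:-1]
            emap = oio.build_exon_residue_map(t)
            is_skip = t.transcript_id.endswith("t2")
            domains = _isoform_domains(g, is_skip)
            gene.proteins.append(
                ProteinRecord(
                    protein_id=t.protein_id,
                    gene_id=gene.gene_id,
                    sequence=protein,
                    curation_status="NP" if t.protein_id.startswith("NP") else "XP",
                    exon_residue_map=emap,
                    domains=domains,
                    has_signal_peptide=g.has_signal,
                    cds_includes_stop=True,
                    species=sp.tax_id,
                )
            )
    return genes, chrom


def _isoform_domains(g: SimGene, skip: bool) -> list[DomainHit]:
    doms = [list(d) for d in g.domains]
    if skip and g.skip_exon is not None:
        bounds = _exon_bounds(g)
        s = bounds[g.skip_exon] // 3
        e = bounds[g.skip_exon + 1] // 3
        tmp = SimGene(
            name=g.name, strand=g.strand, exon_lens=[], intron_lens=[], intron_seqs=[],
            codons=[], skip_exon=None, domains=doms, has_signal=g.has_signal,
        )
        _remap_domains_remove(tmp, s, e - s)
        doms = tmp.domains
    out = []
    for sf, s, e, plen, frac in doms:
        if frac <= 0 or e <= s:
            continue
        out.append(DomainHit(sf, (s, e), plen, round(min(1.0, frac), 6)))
    return sorted(out, key=lambda d: (d.protein_interval, d.superfamily_id))


def to_bundles(clade: SyntheticClade) -> dict[int, AnnotationBundle]:
    out = {}
    for sp in clade.species:
        genes, _chrom = _render_species(clade, sp)
        out[sp.tax_id] = AnnotationBundle(species=sp, genes=genes)
    return out


def best_hit_table(clade: SyntheticClade, tax_id: int) -> pd.DataFrame:
    rows = []
    sim_genes = clade.genes[tax_id]
    for gi, g in enumerate(sim_genes):
        for t in range(2 if g.skip_exon is not None else 1):
            prefix = "NP" if tax_id == clade.anchor_taxon else "XP"
            pid = f"{prefix}_{tax_id}G{gi:04d}T{t + 1}"
            n_codons = len(g.codons) - 1
            if t == 1:
                bounds = _exon_bounds(g)
                n_codons -= (bounds[g.skip_exon + 1] - bounds[g.skip_exon]) // 3
            rows.append(
                {
                    "query_id": pid,
                    "subject_name": g.name,
                    "bit_score": 2.0 * n_codons,
                    "query_coverage": 1.0,
                }
            )
    return pd.DataFrame(rows, columns=["query_id", "subject_name", "bit_score", "query_coverage"])


def write_clade(clade: SyntheticClade, out_dir: str | Path) -> dict[int, dict[str, Path]]:
    """Write per-species GFF3/FASTA/tables plus species and truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = to_bundles(clade)
    paths: dict[int, dict[str, Path]] = {}
    for tax, bundle in bundles.items():
        p = {
            "gff3": out_dir / f"sp{tax}.gff3",
            "fasta": out_dir / f"sp{tax}.faa",
            "domains": out_dir / f"sp{tax}.domains.tsv",
            "signal": out_dir / f"sp{tax}.signal.tsv",
            "best_hits": out_dir / f"sp{tax}.besthits.tsv",
        }
        oio.write_gff3(bundle, p["gff3"])
        oio.write_protein_fasta(bundle, p["fasta"])
        oio.write_domain_table(bundle, p["domains"])
        oio.write_signal_table(bundle, p["signal"])
        best_hit_table(clade, tax).to_csv(p["best_hits"], sep="\t", index=False)
        paths[tax] = p
    oio.write_species_table(clade.species, out_dir / "species.tsv")
    truth = clade.truth_errors if clade.truth_errors is not None else pd.DataFrame(
        columns=["tax_id", "gene_id", "gene_index", "error_class", "expected_flag"]
    )
    truth.to_csv(out_dir / "truth_errors.tsv", sep="\t", index=False)
    return paths
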