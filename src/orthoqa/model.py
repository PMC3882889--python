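"""Domain types for comparative annotation assessment.

Coordinate conventions
----------------------
All genomic intervals are stored 0-based half-open.  GFF3 input/output
converts to/from 1-based inclusive at the file boundary only.  CDS-level
("transcript") coordinates are nucleotide offsets into the spliced coding
sequence, again 0-based half-open.  Coding exons are ordered 5'->3' in
transcription direction, so on the minus strand the first exon has the
largest genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


class ValidationError(ValueError):
    """A record violates a structural invariant (bad CDS length, empty exon...)."""


@dataclass(frozen=True)
class SpeciesInfo:
    """One organism in the analysis, with the assembly/evidence covariates
    used when correlating quality scores (contig N50, EST count)."""

    tax_id: int
    name: str
    is_reference: bool = False
    contig_n50: int = 0
    est_count: int = 0

    def __post_init__(self) -> None:
        if self.contig_n50 < 0 or self.est_count < 0:
            raise ValidationError(f"negative N50/EST count for tax {self.tax_id}")


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain superfamily hit on a protein.

    ``hit_length_fraction`` is the aligned PSSM span divided by the full
    PSSM length; values near 1 mean the domain model is covered end to end.
    """

    superfamily_id: str
    protein_interval: Interval
    pssm_length: int
    hit_length_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_length_fraction <= 1.0):
            raise ValidationError(
                f"hit_length_fraction {self.hit_length_fraction} outside (0, 1]"
            )
        if self.protein_interval[0] < 0 or self.protein_interval[1] <= self.protein_interval[0]:
            raise ValidationError(f"bad domain interval {self.protein_interval}")


@dataclass
class TranscriptRecord:
    transcript_id: str
    coding_exons: list[Interval]  # genomic, ordered 5'->3' in transcription direction
    protein_id: str

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding_exons)


@dataclass
class ProteinRecord:
    """A translated protein tied back to its gene's exon structure.

    ``exon_residue_map`` gives, per coding exon, the half-open interval of
    CDS nucleotides it contributes; the intervals tile ``[0, cds_length)``.
    ``cds_includes_stop`` records whether the final 3 nt of the annotated
    CDS encode the stop codon (they are trimmed before any exon-structure
    comparison so exon lengths reflect the translated product).
    """

    protein_id: str
    gene_id: str
    sequence: str
    curation_status: str = "XP"  # "NP" curated-like, "XP" predicted-like
    exon_residue_map: list[Interval] = field(default_factory=list)
    domains: list[DomainHit] = field(default_factory=list)
    has_signal_peptide: bool = False
    cds_includes_stop: bool = True
    species: int = 0

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.exon_residue_map)
        if self.exon_residue_map:
            expected = 3 * len(self.sequence) + (3 if self.cds_includes_stop else 0)
            if total != expected:
                raise ValidationError(
                    f"{self.protein_id}: exon map covers {total} nt, "
                    f"expected {expected} for {len(self.sequence)} aa"
                )
            pos = 0
            for s, e in self.exon_residue_map:
                if s != pos or e <= s:
                    raise ValidationError(
                        f"{self.protein_id}: exon map does not tile CDS coordinates"
                    )
                pos = e

    def coding_exon_lengths(self) -> list[int]:
        """CDS-nucleotide length of each coding exon, stop codon excluded."""
        return [e - s for s, e in self.comparison_exon_map()]

    def comparison_exon_map(self) -> list[Interval]:
        """Exon map trimmed of the stop codon, used for structure comparison.

        If the stop codon is annotated as part of the CDS, the trailing 3 nt
        are removed; an exon left empty by the trim (a stop codon in its own
        terminal exon) is dropped.
        """
        if not self.cds_includes_stop:
            return list(self.exon_residue_map)
        limit = sum(e - s for s, e in self.exon_residue_map) - 3
        out: list[Interval] = []
        for s, e in self.exon_residue_map:
            if s >= limit:
                break
            out.append((s, min(e, limit)))
        return out


@dataclass
class GeneRecord:
    gene_id: str
    species: int
    chrom: str
    span: Interval
    strand: str
    transcripts: list[TranscriptRecord] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)
    swissprot_name: str | None = None
    is_single_copy: bool = False

    def protein(self, protein_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)


@dataclass
class AnnotationBundle:
    """Everything loaded for one species."""

    species: SpeciesInfo
    genes: list[GeneRecord]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for g in self.genes for p in g.proteins]
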