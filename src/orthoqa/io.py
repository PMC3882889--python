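"""Readers and writers for annotation bundles and report tables.

Input formats per species: gene/mRNA/CDS features in GFF3 (1-based
inclusive, converted to internal 0-based half-open at this boundary),
protein sequences in FASTA keyed by protein_id, and plain TSV tables for
best hits, domain hits, signal peptides and species metadata.
"""

from __future__ import annotations

import logging
import random
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import (
    AnnotationBundle,
    DomainHit,
    GeneRecord,
    Interval,
    ProteinRecord,
    SpeciesInfo,
    TranscriptRecord,
    ValidationError,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _read_gff3(path: str | Path):
    """Yield (line_no, fields dict) for each feature line of a GFF3 file."""
    path = Path(path)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{i}: expected 9 columns, got {len(cols)}")
            try:
                start = int(cols[3])
                end = int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{i}: bad interval {start}..{end}")
            yield {
                "chrom": cols[0],
                "type": cols[2],
                "start": start - 1,  # to 0-based half-open
                "end": end,
                "strand": cols[6],
                "phase": cols[7],
                "attrs": _parse_attributes(cols[8]),
                "line": i,
            }


def build_exon_residue_map(transcript: TranscriptRecord) -> list[Interval]:
    """CDS-nucleotide interval contributed by each coding exon.

    Cumulative sums of exon lengths in transcription order; a codon split
    by a junction simply has its nucleotides on both sides of the boundary
    (all downstream overlap arithmetic is done in nucleotide space).
    """
    out: list[Interval] = []
    pos = 0
    for s, e in transcript.coding_exons:
        if e <= s:
            raise ValidationError(
                f"{transcript.transcript_id}: zero-length coding exon {s}..{e}"
            )
        out.append((pos, pos + (e - s)))
        pos += e - s
    return out


def read_annotation_bundle(
    gff3_path: str | Path,
    fasta_path: str | Path,
    species_info: SpeciesInfo,
    domains_path: str | Path | None = None,
    signal_path: str | Path | None = None,
    seed: int = 0,
) -> AnnotationBundle:
    """Load one species' annotation into cross-linked records.

    Proteins lacking a gene and genes lacking CDS are dropped with a
    warning; a CDS whose length (after phase trimming) is not a multiple
    of 3, or whose protein length disagrees with it, excludes the gene.
    Identical proteins from UTR-only transcript variants are deduplicated,
    the representative chosen by a seeded RNG.
    """
    genes_raw: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    for f in _read_gff3(gff3_path):
        attrs = f["attrs"]
        if f["type"] == "gene":
            genes_raw[attrs["ID"]] = {"feat": f, "mrnas": []}
        elif f["type"] == "mRNA":
            rec = {"feat": f, "cds": [], "protein_id": attrs.get("protein_id", attrs["ID"])}
            mrnas[attrs["ID"]] = rec
            parent = attrs.get("Parent")
            if parent in genes_raw:
                genes_raw[parent]["mrnas"].append(attrs["ID"])
        elif f["type"] == "CDS":
            parent = f["attrs"].get("Parent")
            if parent in mrnas:
                mrnas[parent]["cds"].append(f)

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    domain_rows: dict[str, list[DomainHit]] = {}
    if domains_path is not None:
        dom = pd.read_csv(domains_path, sep="\t", comment="#")
        for r in dom.itertuples(index=False):
            domain_rows.setdefault(r.protein_id, []).append(
                DomainHit(
                    superfamily_id=str(r.superfamily_id),
                    protein_interval=(int(r.start), int(r.end)),
                    pssm_length=int(r.pssm_length),
                    hit_length_fraction=float(r.hit_length_fraction),
                )
            )
    signal_ids: set[str] = set()
    if signal_path is not None:
        sig = pd.read_csv(signal_path, sep="\t", comment="#")
        signal_ids = {
            str(r.protein_id) for r in sig.itertuples(index=False) if bool(r.has_signal_peptide)
        }

    rng = random.Random(seed)
    genes: list[GeneRecord] = []
    for gene_id, graw in sorted(genes_raw.items()):
        f = graw["feat"]
        gene = GeneRecord(
            gene_id=gene_id,
            species=species_info.tax_id,
            chrom=f["chrom"],
            span=(f["start"], f["end"]),
            strand=f["strand"],
        )
        for mrna_id in graw["mrnas"]:
            rec = mrnas[mrna_id]
            if not rec["cds"]:
                log.warning("%s: mRNA %s has no CDS features, skipped", gff3_path, mrna_id)
                continue
            cds = sorted(rec["cds"], key=lambda c: c["start"])
            strand = gene.strand
            exons = [(c["start"], c["end"]) for c in cds]
            phases = [c["phase"] for c in cds]
            if strand == "-":
                exons = exons[::-1]
                phases = phases[::-1]
            # trim leading partial codon indicated by the first exon's phase
            first_phase = int(phases[0]) if phases[0] not in (".", "") else 0
            if first_phase:
                s, e = exons[0]
                exons[0] = (s + first_phase, e) if strand == "+" else (s, e - first_phase)
            try:
                tr = TranscriptRecord(mrna_id, exons, rec["protein_id"])
                emap = build_exon_residue_map(tr)
            except ValidationError as exc:
                log.warning("gene %s excluded: %s", gene_id, exc)
                gene.transcripts = []
                break
            total = emap[-1][1]
            if total % 3:
                log.warning(
                    "gene %s excluded: CDS length %d not a multiple of 3", gene_id, total
                )
                gene.transcripts = []
                break
            seq = seqs.get(rec["protein_id"])
            if seq is None:
                log.warning("protein %s missing from FASTA, transcript dropped", rec["protein_id"])
                continue
            if total == 3 * (len(seq) + 1):
                stop = True
            elif total == 3 * len(seq):
                stop = False
            else:
                log.warning(
                    "gene %s excluded: protein %s length %d inconsistent with CDS %d nt",
                    gene_id, rec["protein_id"], len(seq), total,
                )
                gene.transcripts = []
                break
            gene.transcripts.append(tr)
            gene.proteins.append(
                ProteinRecord(
                    protein_id=rec["protein_id"],
                    gene_id=gene_id,
                    sequence=seq,
                    curation_status="NP" if rec["protein_id"].startswith("NP") else "XP",
                    exon_residue_map=emap,
                    domains=sorted(
                        domain_rows.get(rec["protein_id"], []),
                        key=lambda d: (d.protein_interval, d.superfamily_id),
                    ),
                    has_signal_peptide=rec["protein_id"] in signal_ids,
                    cds_includes_stop=stop,
                    species=species_info.tax_id,
                )
            )
        if not gene.proteins:
            log.warning("gene %s has no usable coding transcript, dropped", gene_id)
            continue
        _deduplicate_identical(gene, rng)
        genes.append(gene)
    return AnnotationBundle(species=species_info, genes=genes)


def _deduplicate_identical(gene: GeneRecord, rng: random.Random) -> None:
    """Collapse identical proteins (UTR-only transcript variants share a CDS);
    the representative is picked at random from each identity group."""
    groups: dict[tuple, list[int]] = {}
    for i, p in enumerate(gene.proteins):
        key = (p.sequence, tuple(p.exon_residue_map))
        groups.setdefault(key, []).append(i)
    keep = sorted(rng.choice(idxs) for idxs in groups.values())
    if len(keep) < len(gene.proteins):
        gene.proteins = [gene.proteins[i] for i in keep]
        kept_pids = {p.protein_id for p in gene.proteins}
        gene.transcripts = [t for t in gene.transcripts if t.protein_id in kept_pids]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path) -> list[SpeciesInfo]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SpeciesInfo(
            tax_id=int(r.tax_id),
            name=str(r.name),
            is_reference=bool(r.is_reference),
            contig_n50=int(r.contig_n50),
            est_count=int(r.est_count),
        )
        for r in df.itertuples(index=False)
    ]


def read_best_hits(path: str | Path) -> pd.DataFrame:
    """Best-hit table with columns query_id, subject_name, bit_score, query_coverage."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"query_id", "subject_name", "bit_score", "query_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: best-hit table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gff3(bundle: AnnotationBundle, path: str | Path) -> None:
    """Write gene/mRNA/CDS features, converting back to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in sorted(bundle.genes, key=lambda g: (g.chrom, g.span)):
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, "orthoqa", "gene", str(g.span[0] + 1), str(g.span[1]), ".",
                 g.strand, ".", attrs]
            )
        )
        for t in g.transcripts:
            lines.append(
                "\t".join(
                    [g.chrom, "orthoqa", "mRNA", str(min(s for s, _ in t.coding_exons) + 1),
                     str(max(e for _, e in t.coding_exons)), ".", g.strand, ".",
                     f"ID={t.transcript_id};Parent={g.gene_id};protein_id={t.protein_id}"]
                )
            )
            phase = 0
            cum = 0
            rows = []
            for s, e in t.coding_exons:
                rows.append((s, e, phase))
                cum += e - s
                phase = (3 - cum % 3) % 3
            for s, e, ph in sorted(rows):
                lines.append(
                    "\t".join(
                        [g.chrom, "orthoqa", "CDS", str(s + 1), str(e), ".", g.strand,
                         str(ph), f"ID=cds-{t.transcript_id};Parent={t.transcript_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_protein_fasta(bundle: AnnotationBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in bundle.genes:
            for p in g.proteins:
                fh.write(f">{p.protein_id}\n{p.sequence}\n")


def write_domain_table(bundle: AnnotationBundle, path: str | Path) -> None:
    rows = []
    for p in bundle.all_proteins():
        for d in p.domains:
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "superfamily_id": d.superfamily_id,
                    "start": d.protein_interval[0],
                    "end": d.protein_interval[1],
                    "pssm_length": d.pssm_length,
                    "hit_length_fraction": round(d.hit_length_fraction, 6),
                }
            )
    cols = ["protein_id", "superfamily_id", "start", "end", "pssm_length", "hit_length_fraction"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_signal_table(bundle: AnnotationBundle, path: str | Path) -> None:
    rows = [
        {"protein_id": p.protein_id, "has_signal_peptide": p.has_signal_peptide}
        for p in bundle.all_proteins()
    ]
    pd.DataFrame(rows, columns=["protein_id", "has_signal_peptide"]).to_csv(
        path, sep="\t", index=False
    )


def write_species_table(species: list[SpeciesInfo], path: str | Path) -> None:
    rows = [
        {
            "tax_id": s.tax_id,
            "name": s.name,
            "is_reference": s.is_reference,
            "contig_n50": s.contig_n50,
            "est_count": s.est_count,
        }
        for s in species
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(results: dict[str, pd.DataFrame], out_dir: str | Path, seed: int | None = None) -> None:
    """Write each result table as a TSV with a deterministic column order.

    ``results`` maps a base name (e.g. ``protein_flags``) to a DataFrame.
    The seed used for any randomized choice during the run is recorded as a
    comment header so reruns are traceable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            df.to_csv(fh, sep="\t", index=False)


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
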