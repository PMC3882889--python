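"""Human-anchored ortholog sets from best-hit names plus local synteny.

A gene's candidate orthologs in other species are the genes whose best
database hit carries the same protein name; candidates are confirmed by
local synteny: at least two of the six flanking genes (three per side)
match in expected order and orientation, or both genes are single copy in
their species and share at least one flanking gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import AnnotationBundle, GeneRecord

log = logging.getLogger(__name__)


@dataclass
class FlankContext:
    """Up to k flanking gene names per side of a focal gene.

    Sides are relative to the focal gene's transcription direction
    (upstream = 5' of the gene), neighbors ordered by genomic proximity,
    and each neighbor carries its orientation relative to the focal gene
    (True = same strand).  Unnamed neighbors are kept as ``None``
    placeholders that can never match.
    """

    gene_id: str
    upstream: list[tuple[str | None, bool]] = field(default_factory=list)
    downstream: list[tuple[str | None, bool]] = field(default_factory=list)


def assign_swissprot_name(
    best_hits: pd.DataFrame,
    protein_to_gene: dict[str, str],
    min_coverage: float = 0.5,
) -> dict[str, str]:
    """Per gene, the name of the highest-bit-score hit with sufficient
    query coverage; bit-score ties go to the lexicographically smallest
    name.  Genes with no qualifying hit are absent from the result."""
    best: dict[str, tuple[float, str]] = {}
    for row in best_hits.itertuples(index=False):
        if float(row.query_coverage) < min_coverage:
            continue
        gene = protein_to_gene.get(str(row.query_id))
        if gene is None:
            continue
        key = (-float(row.bit_score), str(row.subject_name))
        if gene not in best or key < best[gene]:
            best[gene] = key
    return {g: name for g, (_, name) in best.items()}


def flank_context(
    gene: GeneRecord,
    chromosome_order: list[GeneRecord],
    names: dict[tuple[int, str], str | None],
    k: int = 3,
) -> FlankContext:
    """Neighbors of a gene in its per-chromosome order (by start coordinate).

    A gene near a contig edge simply has fewer neighbors.
    """
    idx = next(i for i, g in enumerate(chromosome_order) if g.gene_id == gene.gene_id)
    left = chromosome_order[max(0, idx - k): idx][::-1]  # nearest first
    right = chromosome_order[idx + 1: idx + 1 + k]
    if gene.strand == "-":
        left, right = right, left

    def annotate(neighbors):
        return [
            (names.get((g.species, g.gene_id)), g.strand == gene.strand) for g in neighbors
        ]

    return FlankContext(gene.gene_id, upstream=annotate(left), downstream=annotate(right))


def _side_matches(side_a, side_b) -> set[str]:
    """Names appearing on the same side of both genes with consistent
    relative orientation (position within the window is not required)."""
    a = {name: orient for name, orient in side_a if name is not None}
    return {
        name
        for name, orient in side_b
        if name is not None and name in a and a[name] == orient
    }


def count_synteny_matches(anchor_ctx: FlankContext, target_ctx: FlankContext) -> int:
    return len(_side_matches(anchor_ctx.upstream, target_ctx.upstream)) + len(
        _side_matches(anchor_ctx.downstream, target_ctx.downstream)
    )


def shared_flanking_names(anchor_ctx: FlankContext, target_ctx: FlankContext) -> set[str]:
    a = {n for n, _ in anchor_ctx.upstream + anchor_ctx.downstream if n is not None}
    b = {n for n, _ in target_ctx.upstream + target_ctx.downstream if n is not None}
    return a & b


def confirm_synteny(
    anchor_ctx: FlankContext,
    target_ctx: FlankContext,
    anchor_single_copy: bool,
    target_single_copy: bool,
) -> bool:
    """True iff >=2 flanking names match in expected order and orientation,
    or both genes are single copy and share >=1 flanking gene (order and
    orientation then not required)."""
    if count_synteny_matches(anchor_ctx, target_ctx) >= 2:
        return True
    if anchor_single_copy and target_single_copy:
        return len(shared_flanking_names(anchor_ctx, target_ctx)) >= 1
    return False


@dataclass
class OrthologSet:
    set_id: str
    swissprot_name: str
    anchor_gene: GeneRecord
    members: dict[int, GeneRecord] = field(default_factory=dict)  # tax_id -> gene
    synteny_support: dict[int, int] = field(default_factory=dict)
    unanalyzable: bool = False

    def all_genes(self) -> list[GeneRecord]:
        return [self.anchor_gene] + [
            g for t, g in sorted(self.members.items()) if t != self.anchor_gene.species
        ]


def build_ortholog_sets(
    bundles: dict[int, AnnotationBundle],
    best_hits: dict[int, pd.DataFrame],
    anchor_taxon: int,
    min_coverage: float = 0.5,
    k: int = 3,
) -> list[OrthologSet]:
    """Assemble one ortholog set per named anchor-species gene.

    Each candidate member (same name, other species) must pass synteny
    confirmation against the anchor gene; at most one gene per species
    joins (the one with the most flanking matches, ties by gene_id).
    Anchor genes with no confirmed member become singleton sets flagged
    unanalyzable.  Duplicate anchor names produce multiple sets
    disambiguated by gene_id; a target gene joins only its best anchor.
    """
    names: dict[tuple[int, str], str | None] = {}
    single_copy: dict[tuple[int, str], bool] = {}
    for tax, bundle in bundles.items():
        p2g = {p.protein_id: g.gene_id for g in bundle.genes for p in g.proteins}
        gene_names = assign_swissprot_name(best_hits[tax], p2g, min_coverage)
        counts: dict[str, int] = {}
        for g in bundle.genes:
            nm = gene_names.get(g.gene_id)
            names[(tax, g.gene_id)] = nm
            if nm is not None:
                counts[nm] = counts.get(nm, 0) + 1
        for g in bundle.genes:
            nm = gene_names.get(g.gene_id)
            g.swissprot_name = nm
            g.is_single_copy = nm is not None and counts[nm] == 1
            single_copy[(tax, g.gene_id)] = g.is_single_copy

    contexts: dict[tuple[int, str], FlankContext] = {}
    for tax, bundle in bundles.items():
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in bundle.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: g.span)
            for g in chrom_genes:
                contexts[(tax, g.gene_id)] = flank_context(g, chrom_genes, names, k)

    by_name: dict[str, list[tuple[int, GeneRecord]]] = {}
    for tax, bundle in bundles.items():
        for g in bundle.genes:
            if g.swissprot_name is not None:
                by_name.setdefault(g.swissprot_name, []).append((tax, g))

    sets: list[OrthologSet] = []
    for name in sorted(by_name):
        entries = by_name[name]
        anchors = [g for tax, g in entries if tax == anchor_taxon]
        if not anchors:
            continue
        anchors.sort(key=lambda g: g.gene_id)
        if len(anchors) > 1:
            log.warning("anchor species has %d genes named %r; keeping all", len(anchors), name)
        name_sets = []
        for a in anchors:
            sid = name if len(anchors) == 1 else f"{name}|{a.gene_id}"
            name_sets.append(OrthologSet(set_id=sid, swissprot_name=name, anchor_gene=a))
        targets = [(tax, g) for tax, g in entries if tax != anchor_taxon]
        # each target joins the anchor it supports best (ties: anchor gene_id)
        assignments: dict[str, list[tuple[int, GeneRecord, int]]] = {s.set_id: [] for s in name_sets}
        for tax, g in targets:
            best = None
            for s in name_sets:
                a = s.anchor_gene
                actx = contexts[(anchor_taxon, a.gene_id)]
                tctx = contexts[(tax, g.gene_id)]
                if not confirm_synteny(
                    actx, tctx, single_copy[(anchor_taxon, a.gene_id)], single_copy[(tax, g.gene_id)]
                ):
                    continue
                support = count_synteny_matches(actx, tctx)
                key = (-support, s.anchor_gene.gene_id)
                if best is None or key < best[0]:
                    best = (key, s.set_id, support)
            if best is not None:
                assignments[best[1]].append((tax, g, best[2]))
        for s in name_sets:
            per_species: dict[int, tuple[GeneRecord, int]] = {}
            for tax, g, support in assignments[s.set_id]:
                cur = per_species.get(tax)
                if cur is None or (-support, g.gene_id) < (-cur[1], cur[0].gene_id):
                    per_species[tax] = (g, support)
            s.members = {tax: g for tax, (g, _) in per_species.items()}
            s.members[anchor_taxon] = s.anchor_gene
            s.synteny_support = {tax: sup for tax, (g, sup) in per_species.items()}
            s.unanalyzable = len(s.members) <= 1
            sets.append(s)
    return sets


def ortholog_sets_table(sets: list[OrthologSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for tax in sorted(s.members):
            rows.append(
                {
                    "set_id": s.set_id,
                    "name": s.swissprot_name,
                    "tax_id": tax,
                    "gene_id": s.members[tax].gene_id,
                    "synteny_support_count": s.synteny_support.get(tax, -1),
                }
            )
    cols = ["set_id", "name", "tax_id", "gene_id", "synteny_support_count"]
    return pd.DataFrame(rows, columns=cols)
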