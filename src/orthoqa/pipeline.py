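"""End-to-end orchestration: load -> orthology -> clustering -> splice
conservation -> QA screens -> scorecards.

Per-ortholog-set computations are independent of one another and of
execution order; all randomized choices (representative selection) use
the run seed, so a rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as oio
from .align import (
    ProteinCluster,
    alignment_score,
    pairwise_align,
    progressive_msa,
    reciprocal_best_hits,
)
from .model import AnnotationBundle, ProteinRecord
from .orthology import OrthologSet, build_ortholog_sets, ortholog_sets_table
from .qa import MIN_REFERENCE_PROTEINS, QAFlags, screen_cluster
from .quality import build_scorecards, organism_fractions, scorecard_table
from .splice import (
    classify_nonconservation,
    core_protein_sets,
    count_reference_support,
    splice_profile_pair,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the protocol, with their published defaults."""

    anchor_taxon: int = 0
    reference_taxa: set[int] = field(default_factory=set)
    overlap_threshold: float = 0.9
    len_tolerance_nt: int = 45
    junction_tolerance_nt: int = 0
    min_cluster_r: int = MIN_REFERENCE_PROTEINS
    domain_z_cutoff: float = 2.0
    length_z_cutoff: float = 3.0
    length_delta_cutoff: int = 15
    min_coverage: float = 0.5
    flank_k: int = 3
    core_min_organisms: int = 17
    core_min_ref_support: int = 3
    support_levels: tuple[int, ...] = (3, 6, 9)
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold outside (0, 1]")
        if self.anchor_taxon and self.reference_taxa and self.anchor_taxon not in self.reference_taxa:
            log.info("anchor taxon %s is not a reference species", self.anchor_taxon)


class AlignmentCache:
    """Memoized local scores and pairwise alignments, keyed on unordered
    protein pairs (scores and exon correspondences are symmetric)."""

    def __init__(self) -> None:
        self._scores: dict[frozenset, float] = {}
        self._alns: dict[tuple[str, str, str], object] = {}

    def score(self, p: ProteinRecord, q: ProteinRecord) -> float:
        key = frozenset((p.protein_id, q.protein_id))
        if key not in self._scores:
            self._scores[key] = alignment_score(p, q, mode="local")
        return self._scores[key]

    def align(self, p: ProteinRecord, q: ProteinRecord, mode: str = "local"):
        key = (p.protein_id, q.protein_id, mode)
        if key not in self._alns:
            self._alns[key] = pairwise_align(p, q, mode=mode)
        return self._alns[key]


@dataclass
class SetResult:
    oset: OrthologSet
    clusters: list[ProteinCluster]
    profiles: list[dict]  # rows for splice_profiles.tsv
    support: dict[int, int]  # tax -> best reference support in this set
    flags: dict[str, QAFlags]
    per_protein_support: dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: RunConfig
    sets: list[SetResult]
    core_set_ids: list[str]
    core_counts: dict[int, int]
    tables: dict[str, pd.DataFrame]


def cluster_ortholog_set(
    oset: OrthologSet,
    config: RunConfig,
    cache: AlignmentCache,
) -> list[ProteinCluster]:
    """Reciprocal best hits between gene pairs (reference side required,
    matching the protocol's reference-vs-all alignment scope), then greedy
    merging in descending score order."""
    genes = oset.all_genes()
    proteins = [p for g in genes for p in g.proteins]
    rbh = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            if (
                ga.species not in config.reference_taxa
                and gb.species not in config.reference_taxa
            ):
                continue
            rbh.extend(reciprocal_best_hits(ga.proteins, gb.proteins, cache.score))
    return greedy_cluster_wrapper(oset, proteins, rbh, config)


def greedy_cluster_wrapper(oset, proteins, rbh, config):
    from .align import greedy_cluster

    return greedy_cluster(
        oset.set_id, proteins, rbh, config.reference_taxa, config.anchor_taxon
    )


def evaluate_set(
    oset: OrthologSet,
    config: RunConfig,
    cache: AlignmentCache,
) -> SetResult:
    clusters = cluster_ortholog_set(oset, config, cache)
    profile_rows = []
    conserved: dict[frozenset, bool] = {}
    kwargs = dict(
        overlap_threshold=config.overlap_threshold,
        len_tolerance_nt=config.len_tolerance_nt,
        junction_tolerance_nt=config.junction_tolerance_nt,
    )
    for cl in clusters:
        refs = [p for p in cl.members if p.species in config.reference_taxa]
        done = set()
        for p in cl.members:
            for q in refs:
                key = frozenset((p.protein_id, q.protein_id))
                if p.protein_id == q.protein_id or key in done:
                    continue
                done.add(key)
                corr, prof = splice_profile_pair(
                    p, q, lambda a, b: cache.align(a, b, "local"), **kwargs
                )
                conserved[key] = prof.all_90pct_overlap
                cause = (
                    None
                    if prof.all_90pct_overlap
                    else classify_nonconservation(corr, prof).category
                )
                profile_rows.append(
                    {
                        "set_id": oset.set_id,
                        "protein_id": p.protein_id,
                        "ref_protein_id": q.protein_id,
                        "all_exons_aligned": prof.all_exons_aligned,
                        "one_to_one": prof.one_to_one,
                        "all_90pct_overlap": prof.all_90pct_overlap,
                        "all_len_within_15": prof.all_len_within_15,
                        "junctions_aligned": prof.junctions_aligned,
                        "cause": cause if cause is not None else "",
                    }
                )
    support: dict[int, int] = {}
    per_protein_support: dict[str, int] = {}
    for cl in clusters:
        for p in cl.members:
            s, _levels = count_reference_support(
                p, cl, conserved, config.reference_taxa, config.support_levels
            )
            per_protein_support[p.protein_id] = s
            support[p.species] = max(support.get(p.species, 0), s)

    flags: dict[str, QAFlags] = {}
    for cl in clusters:
        msa = None
        if cl.r >= config.min_cluster_r and len(cl.members) > 1:
            msa = progressive_msa(cl.members, aligner=cache.score)
        cl_flags = screen_cluster(cl, config.reference_taxa, msa=msa)
        for pid, f in cl_flags.items():
            f.not_in_largest_cluster = not cl.is_largest
            flags[pid] = f
    return SetResult(oset, clusters, profile_rows, support, flags, per_protein_support)


def run(
    bundles: dict[int, AnnotationBundle],
    best_hits: dict[int, pd.DataFrame],
    config: RunConfig,
) -> PipelineResult:
    """Run the full protocol over loaded per-species bundles."""
    config.validate()
    sets = build_ortholog_sets(
        bundles, best_hits, config.anchor_taxon, config.min_coverage, config.flank_k
    )
    analyzed = [s for s in sets if not s.unanalyzable]
    log.info("built %d ortholog sets (%d analyzable)", len(sets), len(analyzed))
    cache = AlignmentCache()
    results = [evaluate_set(s, config, cache) for s in analyzed]

    set_support = {r.oset.set_id: r.support for r in results}
    core_ids, core_counts = core_protein_sets(
        set_support, config.core_min_organisms, config.core_min_ref_support
    )

    # per-gene flag collection over analyzed genes
    gene_flags: dict[tuple[int, str], list[QAFlags]] = {}
    for r in results:
        main = next((c for c in r.clusters if c.is_largest), None)
        if main is None or main.r < config.min_cluster_r:
            continue  # organism fractions are over genes in analyzed sets
        for g in r.oset.all_genes():
            gene_flags[(g.species, g.gene_id)] = [
                r.flags[p.protein_id] for p in g.proteins if p.protein_id in r.flags
            ]
    fractions = organism_fractions(gene_flags)
    species = {tax: b.species for tax, b in bundles.items()}
    cards = build_scorecards(fractions, core_counts, species)

    tables = {
        "ortholog_sets": ortholog_sets_table([r.oset for r in results]),
        "splice_profiles": pd.DataFrame(
            [row for r in results for row in r.profiles],
            columns=[
                "set_id", "protein_id", "ref_protein_id", "all_exons_aligned",
                "one_to_one", "all_90pct_overlap", "all_len_within_15",
                "junctions_aligned", "cause",
            ],
        ),
        "reference_support": pd.DataFrame(
            [
                {
                    "set_id": r.oset.set_id,
                    "protein_id": pid,
                    "support": sup,
                    **{
                        f"level_{t}": sup >= t for t in config.support_levels
                    },
                }
                for r in results
                for pid, sup in sorted(r.per_protein_support.items())
            ],
            columns=["set_id", "protein_id", "support"]
            + [f"level_{t}" for t in config.support_levels],
        ),
        "protein_flags": protein_flags_table(results, bundles),
        "scorecard": scorecard_table(cards) if cards else pd.DataFrame(),
        "core_sets": pd.DataFrame({"set_id": core_ids}),
    }
    result = PipelineResult(config, results, core_ids, core_counts, tables)
    if config.out_dir:
        oio.write_report(tables, config.out_dir, seed=config.seed)
    return result


def protein_flags_table(results: list[SetResult], bundles) -> pd.DataFrame:
    by_pid = {
        p.protein_id: p for b in bundles.values() for p in b.all_proteins()
    }
    rows = []
    for r in results:
        for pid in sorted(r.flags):
            f = r.flags[pid]
            p = by_pid[pid]
            rows.append(
                {
                    "set_id": r.oset.set_id,
                    "protein_id": pid,
                    "gene_id": p.gene_id,
                    "tax_id": p.species,
                    "prefix": p.curation_status,
                    "domain_z_outlier": f.domain_z_outlier,
                    "extra_domain": f.extra_domain,
                    "missing_domain": f.missing_domain,
                    "truncated_domain": f.truncated_domain,
                    "downstream_met": f.downstream_met,
                    "length_outlier": f.length_outlier,
                    "nterm_identity_outlier": f.nterm_identity_outlier,
                    "not_in_largest_cluster": f.not_in_largest_cluster,
                    "length_regions": ";".join(f.length_outlier_regions),
                }
            )
    cols = [
        "set_id", "protein_id", "gene_id", "tax_id", "prefix", "domain_z_outlier",
        "extra_domain", "missing_domain", "truncated_domain", "downstream_met",
        "length_outlier", "nterm_identity_outlier", "not_in_largest_cluster",
        "length_regions",
    ]
    return pd.DataFrame(rows, columns=cols)


def load_bundles(
    species_table: str | Path,
    paths: dict[int, dict[str, str | Path]],
    seed: int = 0,
) -> tuple[dict[int, AnnotationBundle], dict[int, pd.DataFrame]]:
    """Load all species' bundles and best-hit tables from files.

    ``paths`` maps tax_id to a dict with keys gff3, fasta, domains,
    signal, best_hits (as written by the synthetic generator).
    """
    species = {s.tax_id: s for s in oio.read_species_table(species_table)}
    bundles = {}
    hits = {}
    for tax, p in paths.items():
        bundles[tax] = oio.read_annotation_bundle(
            p["gff3"], p["fasta"], species[tax],
            domains_path=p.get("domains"), signal_path=p.get("signal"), seed=seed,
        )
        hits[tax] = oio.read_best_hits(p["best_hits"])
    return bundles, hits
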