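"""Splicing-ortholog detection: CDS exon structures mapped through protein
alignments.

Each aligned residue pair contributes three aligned CDS-nucleotide pairs,
attributed to exon pairs through the two proteins' exon maps (stop codon
excluded).  The terminal aligned exons are extended gap-free to the
beginning and end of the respective exons before attribution, so ragged
local-alignment ends do not spuriously strip terminal exons.  Two
proteins are splicing orthologs when all protein-coding exons pair
one-to-one with at least 90% overlap in the lengths of both exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Interval, ProteinRecord
from .align import PairwiseAlignment, ProteinCluster


@dataclass
class ExonCorrespondence:
    """Aligned-nucleotide overlap structure for one protein pair.

    ``overlap`` is an (exons of p) x (exons of q) matrix of aligned CDS
    nucleotide counts.  ``junction_offsets_p[j]`` is the signed nucleotide
    distance from the image of p's j-th internal junction to the nearest
    junction of q (None when the junction lies outside the alignment);
    likewise for q.
    """

    p_id: str
    q_id: str
    p_exon_lengths: list[int]
    q_exon_lengths: list[int]
    overlap: np.ndarray
    junction_offsets_p: list[int | None] = field(default_factory=list)
    junction_offsets_q: list[int | None] = field(default_factory=list)

    def transposed(self) -> "ExonCorrespondence":
        return ExonCorrespondence(
            p_id=self.q_id,
            q_id=self.p_id,
            p_exon_lengths=self.q_exon_lengths,
            q_exon_lengths=self.p_exon_lengths,
            overlap=self.overlap.T.copy(),
            junction_offsets_p=[None if o is None else -o for o in self.junction_offsets_q],
            junction_offsets_q=[None if o is None else -o for o in self.junction_offsets_p],
        )


def _junctions(exon_map: list[Interval]) -> list[int]:
    """Internal junction positions in CDS-nucleotide coordinates."""
    return [e for _, e in exon_map[:-1]]


def _exon_index_of(pos: int, exon_map: list[Interval]) -> int | None:
    """Exon label of a CDS nucleotide position.

    Positions past an exon's end but before the next exon's start inherit
    the previous exon's label; positions preceding the first exon have no
    label.  (With a gap-free exon map this reduces to a plain lookup plus
    the trailing-position rule.)
    """
    if not exon_map or pos < exon_map[0][0]:
        return None
    for i, (s, e) in enumerate(exon_map):
        if pos < s:
            return i - 1
        if pos < e:
            return i
    return len(exon_map) - 1


def _nt_blocks(aln: PairwiseAlignment, p_map, q_map) -> list[tuple[int, int, int]]:
    """Aligned CDS-nucleotide runs as (p_start, q_start, length), with the
    gap-free terminal extension into the first/last aligned exons."""
    blocks = [
        (3 * qs, 3 * ss, 3 * (qe - qs)) for (qs, qe), (ss, se) in aln.blocks
    ]
    if not blocks:
        return blocks
    a0, b0, _ = blocks[0]
    ip = _exon_index_of(a0, p_map)
    iq = _exon_index_of(b0, q_map)
    if ip is not None and iq is not None:
        ext = min(a0 - p_map[ip][0], b0 - q_map[iq][0])
        if ext > 0:
            blocks.insert(0, (a0 - ext, b0 - ext, ext))
    pa, qa, ln = blocks[-1]
    a1, b1 = pa + ln, qa + ln
    ip = _exon_index_of(a1 - 1, p_map)
    iq = _exon_index_of(b1 - 1, q_map)
    if ip is not None and iq is not None:
        ext = min(p_map[ip][1] - a1, q_map[iq][1] - b1)
        if ext > 0:
            blocks.append((a1, b1, ext))
    return blocks


def build_exon_correspondence(
    aln: PairwiseAlignment, p: ProteinRecord, q: ProteinRecord
) -> ExonCorrespondence:
    """Attribute aligned nucleotide pairs to exon pairs by interval math.

    An empty alignment yields an all-zero overlap matrix.
    """
    p_map = p.comparison_exon_map()
    q_map = q.comparison_exon_map()
    overlap = np.zeros((len(p_map), len(q_map)), dtype=np.int64)
    blocks = _nt_blocks(aln, p_map, q_map)
    for pa, qa, ln in blocks:
        delta = qa - pa
        pe = pa + ln
        for i, (ps, pend) in enumerate(p_map):
            s = max(pa, ps)
            e = min(pe, pend)
            if e <= s:
                continue
            # map this run into q space and split over q exons
            for j, (qs, qend) in enumerate(q_map):
                s2 = max(s + delta, qs)
                e2 = min(e + delta, qend)
                if e2 > s2:
                    overlap[i, j] += e2 - s2
        # nucleotides past the last defined exon inherit its label, so any
        # run beyond the maps (possible only with truncated maps) is folded
        # into the terminal exons via _exon_index_of; with tiling maps the
        # interval intersection above already covers every position.

    def offsets(junctions_self, junctions_other, forward: bool):
        out: list[int | None] = []
        for x in junctions_self:
            mapped = None
            for pa, qa, ln in blocks:
                a, b = (pa, qa) if forward else (qa, pa)
                if a <= x <= a + ln:
                    mapped = b + (x - a)
                    break
            if mapped is None or not junctions_other:
                out.append(None)
                continue
            off = min((j - mapped for j in junctions_other), key=lambda d: (abs(d), d))
            out.append(off)
        return out

    jp = _junctions(p_map)
    jq = _junctions(q_map)
    return ExonCorrespondence(
        p_id=p.protein_id,
        q_id=q.protein_id,
        p_exon_lengths=[e - s for s, e in p_map],
        q_exon_lengths=[e - s for s, e in q_map],
        overlap=overlap,
        junction_offsets_p=offsets(jp, jq, forward=True),
        junction_offsets_q=offsets(jq, jp, forward=False),
    )


@dataclass(frozen=True)
class ConservationProfile:
    """The five splicing-conservation criteria for a protein pair.

    ``junctions_aligned`` is None (undefined) unless both proteins have at
    least two coding exons.  By construction ``all_90pct_overlap`` implies
    ``one_to_one`` implies ``all_exons_aligned``.
    """

    all_exons_aligned: bool
    one_to_one: bool
    all_90pct_overlap: bool
    all_len_within_15: bool
    junctions_aligned: bool | None


def _mutual_matching(overlap: np.ndarray) -> list[tuple[int, int]] | None:
    """Perfect matching by mutual dominant partners, or None.

    Exon i's dominant partner is the exon with the largest overlap (ties:
    smallest index); the matching must be a bijection covering all exons
    of both proteins with nonzero overlap everywhere.
    """
    n, m = overlap.shape
    if n != m or n == 0:
        return None
    pairs = []
    for i in range(n):
        j = int(np.argmax(overlap[i]))
        if overlap[i, j] == 0:
            return None
        if int(np.argmax(overlap[:, j])) != i:
            return None
        pairs.append((i, j))
    if len({j for _, j in pairs}) != n:
        return None
    return pairs


def conservation_profile(
    corr: ExonCorrespondence,
    overlap_threshold: float = 0.9,
    len_tolerance_nt: int = 45,
    junction_tolerance_nt: int = 0,
) -> ConservationProfile:
    """Evaluate the five conservation criteria on an exon correspondence.

    Length tolerance defaults to 15 codons (45 nt); threshold comparisons
    are inclusive (>= for overlap, <= for length and junction tolerance).
    """
    ov = corr.overlap
    lp = np.asarray(corr.p_exon_lengths)
    lq = np.asarray(corr.q_exon_lengths)
    all_aligned = (
        ov.size > 0 and bool((ov.sum(axis=1) > 0).all() and (ov.sum(axis=0) > 0).all())
    )
    pairs = _mutual_matching(ov) if all_aligned else None
    one_to_one = pairs is not None
    all_90 = one_to_one and all(
        ov[i, j] >= overlap_threshold * lp[i] and ov[i, j] >= overlap_threshold * lq[j]
        for i, j in pairs
    )
    within_15 = one_to_one and all(
        abs(int(lp[i]) - int(lq[j])) <= len_tolerance_nt for i, j in pairs
    )
    if len(lp) >= 2 and len(lq) >= 2:
        offs = corr.junction_offsets_p + corr.junction_offsets_q
        junctions = all(o is not None and abs(o) <= junction_tolerance_nt for o in offs)
    else:
        junctions = None
    return ConservationProfile(all_aligned, one_to_one, all_90, within_15, junctions)


@dataclass(frozen=True)
class NonConservationCause:
    category: str  # split_merge | exon_loss | not_all_aligned | one_to_one_length_vary


def classify_nonconservation(
    corr: ExonCorrespondence, profile: ConservationProfile, split_fraction: float = 0.1
) -> NonConservationCause:
    """Assign the cause of a failed 90%-overlap test, by precedence:
    exon split/merge, then exon loss, then incomplete alignment coverage,
    then pure length variation under a one-to-one mapping."""
    if profile.all_90pct_overlap:
        raise ValueError("classify_nonconservation called on a conserved pair")
    ov = corr.overlap
    lp = corr.p_exon_lengths
    lq = corr.q_exon_lengths
    for i in range(ov.shape[0]):
        if (ov[i] >= split_fraction * lp[i]).sum() >= 2 and lp[i] > 0:
            return NonConservationCause("split_merge")
    for j in range(ov.shape[1]):
        if (ov[:, j] >= split_fraction * lq[j]).sum() >= 2 and lq[j] > 0:
            return NonConservationCause("split_merge")
    # an exon is "lost" when essentially nothing of it participates in the
    # alignment; the same 10% fraction used for split/merge tolerates a few
    # nucleotides of gap-placement jitter at the exon boundary
    p_lost = [i for i in range(ov.shape[0]) if ov[i].sum() < split_fraction * lp[i]]
    q_lost = [j for j in range(ov.shape[1]) if ov[:, j].sum() < split_fraction * lq[j]]
    if p_lost or q_lost:
        rest = np.delete(np.delete(ov, p_lost, axis=0), q_lost, axis=1)
        if rest.size and _mutual_matching(rest) is not None:
            return NonConservationCause("exon_loss")
        return NonConservationCause("not_all_aligned")
    if not profile.one_to_one:
        return NonConservationCause("not_all_aligned")
    return NonConservationCause("one_to_one_length_vary")


# ---------------------------------------------------------------------------
# Symmetric pair evaluation and reference support
# ---------------------------------------------------------------------------

def splice_profile_pair(
    p: ProteinRecord,
    q: ProteinRecord,
    align_fn,
    **profile_kwargs,
):
    """Correspondence + profile for a pair, symmetric by construction.

    The alignment is computed once with the pair in canonical accession
    order, so profile(p, q) and profile(q, p) agree on every criterion.
    """
    flip = p.protein_id > q.protein_id
    a, b = (q, p) if flip else (p, q)
    corr = build_exon_correspondence(align_fn(a, b), a, b)
    if flip:
        corr = corr.transposed()
    return corr, conservation_profile(corr, **profile_kwargs)


def count_reference_support(
    protein: ProteinRecord,
    cluster: ProteinCluster,
    conserved: dict[frozenset, bool],
    reference_taxa: set[int],
    thresholds: tuple[int, ...] = (3, 6, 9),
) -> tuple[int, dict[int, bool]]:
    """Number of reference species whose clustered counterpart is a
    splicing ortholog of this protein (self-species excluded, so a
    reference protein can reach at most r-1)."""
    support = 0
    for other in cluster.members:
        if other.species == protein.species or other.species not in reference_taxa:
            continue
        if conserved.get(frozenset((protein.protein_id, other.protein_id)), False):
            support += 1
    return support, {t: support >= t for t in thresholds}


def core_protein_sets(
    set_support: dict[str, dict[int, int]],
    min_organisms: int = 17,
    min_ref_support: int = 3,
) -> tuple[list[str], dict[int, int]]:
    """Core ortholog sets and per-species core-protein counts.

    ``set_support`` maps set_id -> {tax_id: reference support of that
    species' protein}.  A set qualifies when at least ``min_organisms`` of
    its members meet ``min_ref_support``; a species' core count is the
    number of qualifying sets in which its own protein meets the bar.
    """
    core_ids = []
    counts: dict[int, int] = {}
    for sid in sorted(set_support):
        sup = set_support[sid]
        qualifying = [tax for tax, s in sup.items() if s >= min_ref_support]
        if len(qualifying) >= min_organisms:
            core_ids.append(sid)
            for tax in qualifying:
                counts[tax] = counts.get(tax, 0) + 1
    return core_ids, counts
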