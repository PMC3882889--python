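"""Pairwise protein alignment, reciprocal best hits, greedy splice-variant
clustering, and a deterministic progressive multiple alignment.

Alignment is exact affine-gap dynamic programming (BLOSUM62, gap open 12
for the first gap position and 1 per extension, the usual "11/1" BLAST
parameterisation) rather than a heuristic word-seeded search: ortholog
sets contain at most a few dozen proteins, so exact DP is affordable and
the scores serve only to order merges.  No compositional adjustment and
no masking are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .model import ProteinRecord, ValidationError

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = mode
    return aligner


_ALIGNERS = {"local": _make_aligner("local"), "global": _make_aligner("global")}


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal pairwise alignment as ungapped blocks.

    ``blocks`` is a list of ``((q_start, q_end), (s_start, s_end))`` residue
    intervals, strictly increasing in both sequences.  ``identity`` is the
    number of identical residues divided by the alignment length (columns,
    gaps included).
    """

    query_id: str
    subject_id: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    score: float
    identity: float

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for (qs, qe), (ss, se) in self.blocks
            for i, j in zip(range(qs, qe), range(ss, se))
        ]

    def is_empty(self) -> bool:
        return not self.blocks


def _validate(p: ProteinRecord) -> None:
    bad = set(p.sequence) - _ALPHABET
    if bad or not p.sequence:
        raise ValidationError(
            f"{p.protein_id}: sequence empty or contains non-amino-acid characters {sorted(bad)}"
        )


def pairwise_align(p: ProteinRecord, q: ProteinRecord, mode: str = "local") -> PairwiseAlignment:
    """Optimal affine-gap alignment of two proteins.

    Ties between co-optimal alignments are broken deterministically by the
    DP traceback order (the "high road": matches preferred, then gaps in
    the subject).  In local mode a pair with no positive-scoring segment
    yields an empty alignment with score 0.
    """
    _validate(p)
    _validate(q)
    aligner = _ALIGNERS[mode]
    score = aligner.score(p.sequence, q.sequence)
    if mode == "local" and score <= 0:
        return PairwiseAlignment(p.protein_id, q.protein_id, (), 0.0, 0.0)
    aln = aligner.align(p.sequence, q.sequence)[0]
    qb, sb = aln.aligned
    blocks = tuple((tuple(a), tuple(b)) for a, b in zip(qb.tolist(), sb.tolist()))
    ident = 0
    ncols = 0
    prev_q = blocks[0][0][0] if blocks else 0
    prev_s = blocks[0][1][0] if blocks else 0
    for (qs, qe), (ss, se) in blocks:
        ncols += (qs - prev_q) + (ss - prev_s)  # gap columns between blocks
        for i, j in zip(range(qs, qe), range(ss, se)):
            ncols += 1
            if p.sequence[i] == q.sequence[j]:
                ident += 1
        prev_q, prev_s = qe, se
    identity = ident / ncols if ncols else 0.0
    return PairwiseAlignment(p.protein_id, q.protein_id, blocks, float(score), identity)


def alignment_score(p: ProteinRecord, q: ProteinRecord, mode: str = "local") -> float:
    """Score-only fast path (no traceback)."""
    _validate(p)
    _validate(q)
    score = float(_ALIGNERS[mode].score(p.sequence, q.sequence))
    if mode == "local" and score < 0:
        return 0.0
    return score


def read_score_table(path) -> "callable":
    """Load precomputed pairwise scores (TSV: query, subject, score) as a
    symmetric score function, bypassing internal alignment."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    table = {
        frozenset((str(r.query), str(r.subject))): float(r.score)
        for r in df.itertuples(index=False)
    }

    def scores(p: ProteinRecord, q: ProteinRecord) -> float:
        return table.get(frozenset((p.protein_id, q.protein_id)), 0.0)

    return scores


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hit(query: ProteinRecord, candidates: list[ProteinRecord], scores) -> ProteinRecord | None:
    """Highest-scoring candidate; ties go to the protein whose length is
    closest to the query's, then to accession order."""
    best = None
    best_key = None
    for c in candidates:
        s = scores(query, c)
        if s <= 0:
            continue
        key = (-s, abs(len(c.sequence) - len(query.sequence)), c.protein_id)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def reciprocal_best_hits(
    gene_a: list[ProteinRecord],
    gene_b: list[ProteinRecord],
    scores,
) -> list[tuple[ProteinRecord, ProteinRecord, float]]:
    """Mutual-best protein pairs between the isoforms of two genes.

    ``scores`` is a callable ``(p, q) -> float`` (symmetric); pairs with
    non-positive score are never hits.
    """
    out = []
    for a in gene_a:
        b = _best_hit(a, gene_b, scores)
        if b is None:
            continue
        if _best_hit(b, gene_a, scores) is a:
            out.append((a, b, scores(a, b)))
    return out


# ---------------------------------------------------------------------------
# Greedy clustering of splice variants
# ---------------------------------------------------------------------------

@dataclass
class ProteinCluster:
    set_id: str
    members: list[ProteinRecord] = field(default_factory=list)
    r: int = 0
    is_largest: bool = False

    def member_by_species(self) -> dict[int, ProteinRecord]:
        return {p.species: p for p in self.members}

    def protein_ids(self) -> set[str]:
        return {p.protein_id for p in self.members}


def greedy_cluster(
    set_id: str,
    proteins: list[ProteinRecord],
    rbh_pairs: list[tuple[ProteinRecord, ProteinRecord, float]],
    reference_taxa: set[int],
    anchor_taxon: int | None = None,
) -> list[ProteinCluster]:
    """Partition an ortholog set's proteins into closest-isoform clusters.

    Reciprocal best hits are processed in order of descending score (ties:
    smaller length difference, then accession pair) and two clusters are
    merged unless the merge would put two proteins of one gene in the same
    cluster.  Since an ortholog set holds at most one gene per species this
    also keeps clusters to one protein per species.  The largest cluster is
    flagged; size ties go to the cluster containing the anchor species'
    protein, then to the one with the greatest summed merge score.
    """
    parent: dict[str, str] = {p.protein_id: p.protein_id for p in proteins}
    genes: dict[str, set[str]] = {p.protein_id: {p.gene_id} for p in proteins}
    by_id = {p.protein_id: p for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged_score: dict[str, float] = {p.protein_id: 0.0 for p in proteins}
    ordered = sorted(
        rbh_pairs,
        key=lambda t: (
            -t[2],
            abs(len(t[0].sequence) - len(t[1].sequence)),
            min(t[0].protein_id, t[1].protein_id),
            max(t[0].protein_id, t[1].protein_id),
        ),
    )
    for a, b, score in ordered:
        ra, rb = find(a.protein_id), find(b.protein_id)
        if ra == rb:
            continue
        if genes[ra] & genes[rb]:
            continue  # would place two proteins of one gene together
        parent[rb] = ra
        genes[ra] |= genes.pop(rb)
        merged_score[ra] = merged_score[ra] + merged_score.pop(rb) + score

    groups: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        groups.setdefault(find(p.protein_id), []).append(p)
    clusters = []
    for root, members in sorted(groups.items()):
        members.sort(key=lambda p: p.protein_id)
        clusters.append(
            ProteinCluster(
                set_id=set_id,
                members=members,
                r=len({p.species for p in members if p.species in reference_taxa}),
            )
        )
    if clusters:
        def largest_key(c: ProteinCluster):
            root = find(c.members[0].protein_id)
            has_anchor = any(p.species == anchor_taxon for p in c.members)
            return (-len(c.members), 0 if has_anchor else 1, -merged_score.get(root, 0.0),
                    c.members[0].protein_id)

        min(clusters, key=largest_key).is_largest = True
    return clusters


# ---------------------------------------------------------------------------
# Progressive multiple alignment (center-star)
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """Rows of equal length over residues and ``-`` gap symbols."""

    ids: list[str]
    rows: list[str]

    def row(self, protein_id: str) -> str:
        return self.rows[self.ids.index(protein_id)]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_index(self, protein_id: str, residue: int) -> int:
        """MSA column holding a given 0-based residue of one row."""
        row = self.row(protein_id)
        seen = -1
        for col, ch in enumerate(row):
            if ch != "-":
                seen += 1
                if seen == residue:
                    return col
        raise IndexError(residue)

    def to_fasta(self, path) -> None:
        """Write the alignment as aligned (gapped) FASTA."""
        with open(path, "w") as fh:
            for pid, row in zip(self.ids, self.rows):
                fh.write(f">{pid}\n{row}\n")


def progressive_msa(members: list[ProteinRecord], aligner=None) -> MSA:
    """Center-star multiple alignment of a cluster.

    The center sequence maximises the summed global alignment score to all
    other members (ties: accession order); every other sequence is aligned
    to the center globally and the pairwise alignments are merged on center
    coordinates ("once a gap, always a gap").  Deterministic, and each row
    reproduces its input sequence after gap removal.
    """
    if not members:
        raise ValidationError("empty cluster has no alignment")
    if len(members) == 1:
        return MSA([members[0].protein_id], [members[0].sequence])
    score = aligner or (lambda p, q: alignment_score(p, q, mode="global"))
    sums = []
    for p in members:
        s = sum(score(p, q) for q in members if q is not p)
        sums.append((-s, p.protein_id))
    center = members[min(range(len(members)), key=lambda i: sums[i])]
    others = [p for p in members if p is not center]
    alns = {p.protein_id: pairwise_align(center, p, mode="global") for p in others}

    n = len(center.sequence)

    def insert_runs(p: ProteinRecord) -> dict[int, tuple[int, int]]:
        """Slot -> subject residue run inserted before that center position.

        Subject residues not aligned to any center residue are attached to
        the slot of the next aligned center position (slot ``n`` for
        trailing overhang), so "once a gap, always a gap" holds when runs
        from different subjects share a slot.
        """
        runs: dict[int, tuple[int, int]] = {}
        blocks = alns[p.protein_id].blocks
        prev_s = 0
        for (cs, _ce), (ss, se) in blocks:
            if ss > prev_s:
                runs[cs] = (prev_s, ss)
            prev_s = se
        if prev_s < len(p.sequence):
            runs[n] = (prev_s, len(p.sequence))
        return runs

    all_runs = {p.protein_id: insert_runs(p) for p in others}
    ins = [0] * (n + 1)
    for runs in all_runs.values():
        for k, (a, b) in runs.items():
            ins[k] = max(ins[k], b - a)

    def build_row(p: ProteinRecord | None) -> str:
        if p is None:  # center row
            out = []
            for k in range(n + 1):
                out.append("-" * ins[k])
                if k < n:
                    out.append(center.sequence[k])
            return "".join(out)
        seq = p.sequence
        runs = all_runs[p.protein_id]
        aligned_to = {}
        for (cs, ce), (ss, _se) in alns[p.protein_id].blocks:
            for off in range(ce - cs):
                aligned_to[cs + off] = ss + off
        out = []
        for k in range(n + 1):
            if ins[k]:
                a, b = runs.get(k, (0, 0))
                chunk = seq[a:b]
                out.append(chunk + "-" * (ins[k] - len(chunk)))
            if k < n:
                out.append(seq[aligned_to[k]] if k in aligned_to else "-")
        return "".join(out)

    rows = {center.protein_id: build_row(None)}
    for p in others:
        rows[p.protein_id] = build_row(p)
    ids = [p.protein_id for p in members]
    return MSA(ids, [rows[i] for i in ids])
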