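"""Cross-species protein-consistency screens.

All screens operate within a protein cluster containing at least five
reference-species proteins (r >= 5) and benchmark every member against
the reference members.  Z-scores use the reference proteins' own values
of each statistic to estimate mean and standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .align import MSA, ProteinCluster, progressive_msa
from .model import ProteinRecord

log = logging.getLogger(__name__)

MIN_REFERENCE_PROTEINS = 5


@dataclass
class ReferenceDistribution:
    """Mean/sd of a statistic over reference proteins, for Z-scoring.

    With zero spread the Z-score is 0 at the mean and an infinite sentinel
    elsewhere (so any deviation from a perfectly uniform reference is an
    outlier).
    """

    statistic: str
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, statistic: str, values: list[float]) -> "ReferenceDistribution":
        arr = np.asarray(values, dtype=float)
        return cls(statistic, float(arr.mean()), float(arr.std(ddof=0)), len(values))

    def z(self, value: float) -> float:
        if self.sd == 0.0:
            return 0.0 if value == self.mean else math.inf
        return (value - self.mean) / self.sd


@dataclass
class QAFlags:
    protein_id: str
    domain_z_outlier: bool = False
    extra_domain: bool = False
    missing_domain: bool = False
    truncated_domain: bool = False
    length_outlier: bool = False
    length_outlier_regions: list[str] = field(default_factory=list)
    nterm_identity_outlier: bool = False
    downstream_met: bool = False
    not_in_largest_cluster: bool = False

    def any_flag(self) -> bool:
        return any(
            (
                self.domain_z_outlier,
                self.extra_domain,
                self.missing_domain,
                self.truncated_domain,
                self.length_outlier,
                self.nterm_identity_outlier,
                self.downstream_met,
            )
        )


# ---------------------------------------------------------------------------
# Domain content
# ---------------------------------------------------------------------------

SIGNAL_PEPTIDE_TERM = "__signal_peptide__"


def domain_content(p: ProteinRecord, include_signal: bool = True) -> frozenset[str]:
    """The set of domain superfamily IDs, plus a signal-peptide pseudo-term."""
    terms = {d.superfamily_id for d in p.domains}
    if include_signal and p.has_signal_peptide:
        terms.add(SIGNAL_PEPTIDE_TERM)
    return frozenset(terms)


def jaccard_domain_score(p: ProteinRecord, q: ProteinRecord, include_signal: bool = True) -> float | None:
    """|P ∩ Q| / |P ∪ Q| over domain superfamily sets; None (undefined)
    when both proteins are annotation-free."""
    a = domain_content(p, include_signal)
    b = domain_content(q, include_signal)
    if not a and not b:
        return None
    return len(a & b) / len(a | b)


def mean_jaccard_vs_references(
    p: ProteinRecord, cluster: ProteinCluster, reference_taxa: set[int]
) -> float | None:
    scores = [
        s
        for q in cluster.members
        if q.species in reference_taxa and q.protein_id != p.protein_id
        and (s := jaccard_domain_score(p, q)) is not None
    ]
    return float(np.mean(scores)) if scores else None


def select_domain_representative(
    gene_proteins: list[ProteinRecord],
    clusters: list[ProteinCluster],
    reference_taxa: set[int],
) -> ProteinRecord:
    """The gene's protein with maximum average Jaccard score against its
    cluster's reference counterparts; ties go to the longest protein, then
    accession.  If no protein has a defined score the longest is returned
    (unscored)."""
    cluster_of = {
        p_id: c for c in clusters for p_id in c.protein_ids()
    }
    best = None
    best_key = None
    for p in gene_proteins:
        c = cluster_of.get(p.protein_id)
        score = mean_jaccard_vs_references(p, c, reference_taxa) if c else None
        key = (
            0 if score is not None else 1,
            -(score if score is not None else 0.0),
            -len(p.sequence),
            p.protein_id,
        )
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


def domain_z_outliers(
    cluster: ProteinCluster, reference_taxa: set[int], z_cutoff: float = 2.0
) -> dict[str, bool]:
    """|Z| > cutoff (strict) on each member's mean Jaccard score vs the
    reference members, Z-scored against the reference members' own values."""
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return {}
    stats = {
        p.protein_id: mean_jaccard_vs_references(p, cluster, reference_taxa)
        for p in cluster.members
    }
    ref_vals = [
        v for p in cluster.members
        if p.species in reference_taxa and (v := stats[p.protein_id]) is not None
    ]
    if len(ref_vals) < 2:
        return {p.protein_id: False for p in cluster.members}
    dist = ReferenceDistribution.from_values("mean_jaccard", ref_vals)
    return {
        pid: (v is not None and abs(dist.z(v)) > z_cutoff) for pid, v in stats.items()
    }


def domain_anomalies(
    cluster: ProteinCluster,
    reference_taxa: set[int],
    truncation_fraction: float = 0.6,
) -> dict[str, dict[str, bool]]:
    """Extra / missing / truncated domain flags per cluster member.

    missing: a superfamily present in at least r-1 reference proteins but
    absent from the query (r-1 rather than r so reference proteins can be
    tested themselves); extra: present in the query but absent from at
    least r-1 reference proteins; truncated: the query's maximum hit
    length fraction for a shared superfamily is below 60% and below 60% of
    that superfamily's fraction in the reference proteins.  All three
    comparisons are against the reference members so one aberrant protein
    elsewhere in the cluster cannot mask an anomaly, and each requires
    agreement from all but one of the available reference comparators: a
    non-reference protein is compared to all r references (tolerance 1),
    a reference protein to the other r-1 (the same one-comparator
    tolerance, keeping reference proteins as testable as the rest).
    """
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return {}
    refs = [p for p in cluster.members if p.species in reference_taxa]
    out: dict[str, dict[str, bool]] = {}
    max_hlf = {
        p.protein_id: _max_hit_fractions(p) for p in cluster.members
    }
    for p in cluster.members:
        other_refs = [q for q in refs if q.protein_id != p.protein_id]
        need = len(other_refs) - 1
        content = domain_content(p)
        counts: dict[str, int] = {}
        for q in other_refs:
            for sf in domain_content(q):
                counts[sf] = counts.get(sf, 0) + 1
        missing = any(sf not in content and c >= need for sf, c in counts.items())
        extra = any(
            sum(1 for q in other_refs if sf not in domain_content(q)) >= need
            for sf in content
        )
        truncated = False
        for sf, frac in max_hlf[p.protein_id].items():
            if frac >= truncation_fraction:
                continue
            vouching = sum(
                1
                for q in other_refs
                if sf in max_hlf[q.protein_id]
                and frac < truncation_fraction * max_hlf[q.protein_id][sf]
            )
            if vouching >= need:
                truncated = True
                break
        out[p.protein_id] = {"missing": missing, "extra": extra, "truncated": truncated}
    return out


def _max_hit_fractions(p: ProteinRecord) -> dict[str, float]:
    out: dict[str, float] = {}
    for d in p.domains:
        out[d.superfamily_id] = max(out.get(d.superfamily_id, 0.0), d.hit_length_fraction)
    return out


# ---------------------------------------------------------------------------
# MSA regions
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Contiguous MSA column blocks labeled N-terminal / conserved /
    intermediate / C-terminal."""

    blocks: list[tuple[str, int, int]]  # (label, start_col, end_col)

    def columns(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for lab, s, e in self.blocks if lab == label]


def label_regions(msa: MSA, reference_ids: list[str]) -> RegionPartition:
    """Label columns by reference gap content.

    Maximal runs of columns whose gap fraction across reference rows is at
    most 20% are conserved; runs before the first / after the last
    conserved block are N-/C-terminal, remaining gaps are intermediate.
    With no conserved column the whole alignment is one N-terminal region.
    """
    ref_rows = [msa.row(i) for i in reference_ids]
    width = msa.width
    nref = len(ref_rows)
    conserved_cols = [
        sum(1 for r in ref_rows if r[c] == "-") / nref <= 0.2 for c in range(width)
    ]
    if not any(conserved_cols):
        log.warning("no conserved column in MSA; whole alignment labeled N-terminal")
        return RegionPartition([("N-terminal", 0, width)])
    blocks: list[tuple[str, int, int]] = []
    first = conserved_cols.index(True)
    last = width - 1 - conserved_cols[::-1].index(True)
    if first > 0:
        blocks.append(("N-terminal", 0, first))
    c = first
    while c <= last:
        start = c
        state = conserved_cols[c]
        while c <= last and conserved_cols[c] == state:
            c += 1
        blocks.append(("conserved" if state else "intermediate", start, c))
    if last + 1 < width:
        blocks.append(("C-terminal", last + 1, width))
    return RegionPartition(blocks)


# ---------------------------------------------------------------------------
# Length outliers
# ---------------------------------------------------------------------------

def _residues_in_cols(row: str, start: int, end: int) -> int:
    return sum(1 for ch in row[start:end] if ch != "-")


def _window_delta(msa: MSA, pid: str, qid: str, window: int) -> int:
    """Signed N-terminal length difference over a fixed residue window.

    The window spans the MSA columns holding the first ``window`` residues
    of either protein; the delta is (p residues) - (q residues) in that
    span, an antisymmetric measure of N-terminal truncation/extension.
    """
    def end_col(protein_id: str) -> int:
        row = msa.row(protein_id)
        n = sum(1 for ch in row if ch != "-")
        w = min(window, n)
        return msa.column_index(protein_id, w - 1) + 1 if w else 0

    limit = max(end_col(pid), end_col(qid))
    return _residues_in_cols(msa.row(pid), 0, limit) - _residues_in_cols(
        msa.row(qid), 0, limit
    )


def length_outliers(
    cluster: ProteinCluster,
    msa: MSA,
    partition: RegionPartition,
    reference_taxa: set[int],
    delta_cutoff: int = 15,
    z_cutoff: float = 3.0,
    nterm_windows: tuple[int, ...] = (30, 100),
) -> dict[str, tuple[bool, list[str]]]:
    """Flag unusual lengths per region and over the whole protein.

    The length statistic is the average signed length difference against
    the reference members (self excluded).  Fixed N-terminal windows
    (30/100 aa) use the conjunctive rule: |mean delta| > 15 AND |Z| > 3;
    MSA-derived regions and the whole protein use the disjunctive rule
    (either condition).  Returns per-protein (flagged, list of offending
    region names).
    """
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return {}
    refs = [p for p in cluster.members if p.species in reference_taxa]

    regions: list[tuple[str, callable, bool]] = []  # (name, delta_fn(p,q), conjunctive)
    for w in nterm_windows:
        regions.append(
            (f"nterm{w}", lambda p, q, w=w: _window_delta(msa, p.protein_id, q.protein_id, w), True)
        )
    regions.append(("whole", lambda p, q: len(p.sequence) - len(q.sequence), False))
    for label in ("N-terminal", "conserved", "intermediate", "C-terminal"):
        for s, e in partition.columns(label):
            regions.append(
                (
                    f"{label}[{s}:{e}]",
                    lambda p, q, s=s, e=e: _residues_in_cols(msa.row(p.protein_id), s, e)
                    - _residues_in_cols(msa.row(q.protein_id), s, e),
                    False,
                )
            )

    out: dict[str, tuple[bool, list[str]]] = {p.protein_id: (False, []) for p in cluster.members}
    for name, delta_fn, conjunctive in regions:
        stats: dict[str, float] = {}
        for p in cluster.members:
            deltas = [delta_fn(p, q) for q in refs if q.protein_id != p.protein_id]
            if deltas:
                stats[p.protein_id] = float(np.mean(deltas))
        ref_means = [stats[p.protein_id] for p in refs if p.protein_id in stats]
        if len(ref_means) < 2:
            continue
        dist = ReferenceDistribution.from_values(f"len_delta:{name}", ref_means)
        for p in cluster.members:
            if p.protein_id not in stats:
                continue
            mean_d = stats[p.protein_id]
            big = abs(mean_d) > delta_cutoff
            z_out = abs(dist.z(mean_d)) > z_cutoff
            hit = (big and z_out) if conjunctive else (big or z_out)
            if hit:
                flagged, names = out[p.protein_id]
                names.append(name)
                out[p.protein_id] = (True, names)
    return out


# ---------------------------------------------------------------------------
# N-terminal identity
# ---------------------------------------------------------------------------

def _pair_identity(row_p: str, row_q: str, cols: slice) -> float | None:
    """Ungapped identity over a column span (positions where both rows
    have residues); None when nothing is comparable."""
    matches = 0
    compared = 0
    for a, b in zip(row_p[cols], row_q[cols]):
        if a != "-" and b != "-":
            compared += 1
            if a == b:
                matches += 1
    return matches / compared if compared else None


def nterm_identity_outliers(
    cluster: ProteinCluster,
    msa: MSA,
    reference_taxa: set[int],
    identity_cutoff: float = 0.5,
    z_cutoff: float = 2.0,
    windows: tuple[int, ...] = (30, 100),
) -> dict[str, bool]:
    """Flag poor N-terminal identity relative to both the references and
    the protein's own whole-sequence identity.

    All three conditions are required: mean N-terminal identity < 50%,
    |Z(identity)| > 2, and |Z(log(N-terminal / whole identity))| > 2 — the
    ratio term screens out globally divergent proteins.
    """
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return {}
    refs = [p for p in cluster.members if p.species in reference_taxa]
    out = {p.protein_id: False for p in cluster.members}
    for window in windows:
        ident: dict[str, float] = {}
        ratio: dict[str, float] = {}
        for p in cluster.members:
            row_p = msa.row(p.protein_id)
            n = min(window, len(p.sequence))
            end = msa.column_index(p.protein_id, n - 1) + 1
            nvals, wvals = [], []
            for q in refs:
                if q.protein_id == p.protein_id:
                    continue
                row_q = msa.row(q.protein_id)
                ni = _pair_identity(row_p, row_q, slice(0, end))
                wi = _pair_identity(row_p, row_q, slice(0, msa.width))
                if ni is not None:
                    nvals.append(ni)
                if wi is not None:
                    wvals.append(wi)
            if not nvals or not wvals:
                continue
            ident[p.protein_id] = float(np.mean(nvals))
            whole = float(np.mean(wvals))
            if whole == 0.0 or ident[p.protein_id] == 0.0:
                log.info("protein %s excluded from N-terminal identity test (zero identity)", p.protein_id)
                ident.pop(p.protein_id, None)
                continue
            ratio[p.protein_id] = math.log(ident[p.protein_id] / whole)
        ref_ids = {p.protein_id for p in refs}
        ri = [v for pid, v in ident.items() if pid in ref_ids]
        rr = [v for pid, v in ratio.items() if pid in ref_ids]
        if len(ri) < 2 or len(rr) < 2:
            continue
        d_ident = ReferenceDistribution.from_values(f"nterm{window}_identity", ri)
        d_ratio = ReferenceDistribution.from_values(f"nterm{window}_logratio", rr)
        for pid in ident:
            if pid not in ratio:
                continue
            if (
                ident[pid] < identity_cutoff
                and abs(d_ident.z(ident[pid])) > z_cutoff
                and abs(d_ratio.z(ratio[pid])) > z_cutoff
            ):
                out[pid] = True
    return out


# ---------------------------------------------------------------------------
# Downstream methionine
# ---------------------------------------------------------------------------

def downstream_met_flags(
    cluster: ProteinCluster, msa: MSA, reference_taxa: set[int]
) -> dict[str, bool]:
    """Flag proteins whose initial Met aligns to a downstream (non-initial)
    Met of a reference counterpart, or vice versa, in more than (r-1)/2 of
    the reference comparisons."""
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return {}
    refs = [p for p in cluster.members if p.species in reference_taxa]
    r = cluster.r

    start_col: dict[str, int] = {}
    residue_at: dict[str, dict[int, tuple[str, int]]] = {}
    for p in cluster.members:
        row = msa.row(p.protein_id)
        res = {}
        k = 0
        for col, ch in enumerate(row):
            if ch != "-":
                res[col] = (ch, k)
                k += 1
        residue_at[p.protein_id] = res
        if p.sequence.startswith("M"):
            start_col[p.protein_id] = msa.column_index(p.protein_id, 0)

    def pair_shifted(a: str, b: str) -> bool:
        # a's initial Met aligned to a downstream Met of b, or vice versa
        for x, y in ((a, b), (b, a)):
            col = start_col.get(x)
            if col is None:
                continue
            hit = residue_at[y].get(col)
            if hit is not None and hit[0] == "M" and hit[1] > 0:
                return True
        return False

    out = {}
    for p in cluster.members:
        count = sum(
            1
            for q in refs
            if q.protein_id != p.protein_id and pair_shifted(p.protein_id, q.protein_id)
        )
        out[p.protein_id] = count > (r - 1) / 2
    return out


# ---------------------------------------------------------------------------
# Cluster-level driver
# ---------------------------------------------------------------------------

def screen_cluster(
    cluster: ProteinCluster,
    reference_taxa: set[int],
    msa: MSA | None = None,
) -> dict[str, QAFlags]:
    """Run all per-cluster screens; clusters with r < 5 yield no flags
    (the not-in-largest-cluster property is handled by the caller)."""
    flags = {p.protein_id: QAFlags(p.protein_id) for p in cluster.members}
    if cluster.r < MIN_REFERENCE_PROTEINS:
        return flags
    if msa is None:
        msa = progressive_msa(cluster.members)
    zout = domain_z_outliers(cluster, reference_taxa)
    anomalies = domain_anomalies(cluster, reference_taxa)
    partition = label_regions(
        msa, [p.protein_id for p in cluster.members if p.species in reference_taxa]
    )
    lengths = length_outliers(cluster, msa, partition, reference_taxa)
    nterm = nterm_identity_outliers(cluster, msa, reference_taxa)
    met = downstream_met_flags(cluster, msa, reference_taxa)
    for pid, f in flags.items():
        f.domain_z_outlier = zout.get(pid, False)
        a = anomalies.get(pid, {})
        f.missing_domain = a.get("missing", False)
        f.extra_domain = a.get("extra", False)
        f.truncated_domain = a.get("truncated", False)
        flagged, names = lengths.get(pid, (False, []))
        f.length_outlier = flagged
        f.length_outlier_regions = names
        f.nterm_identity_outlier = nterm.get(pid, False)
        f.downstream_met = met.get(pid, False)
    return flags
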