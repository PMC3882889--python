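"""Scoring pipeline output against a synthetic clade's truth labels.

For each injected error class the recovery rate is the fraction of
injections whose expected signal fired:

* domain classes and the downstream-start class: the expected per-protein
  flag is set on at least one of the gene's proteins;
* N-terminal truncation: a length or N-terminus identity flag;
* exon-level classes: the expected cause is the majority classification
  among the protein's non-conserved reference comparisons.

False-flag rates are measured per screen on clean proteins (genes of the
same species with no injected error).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FLAG_SCREENS = (
    "missing_domain",
    "extra_domain",
    "truncated_domain",
    "downstream_met",
    "length_outlier",
    "nterm_identity_outlier",
)
SPLICE_CAUSES = ("split_merge", "exon_loss", "not_all_aligned", "one_to_one_length_vary")


@dataclass
class RecoveryReport:
    recovery: dict[str, float]  # error class -> fraction recovered
    n_injected: dict[str, int]
    false_flag_rate: dict[str, float]  # screen -> rate on clean proteins
    overall_false_rate: float


def _majority_cause(rows: pd.DataFrame) -> str | None:
    """Dominant outcome over a protein's reference comparisons; conserved
    comparisons count toward a 'conserved' majority."""
    if rows.empty:
        return None
    counts = rows["cause"].fillna("").replace("", "conserved").value_counts()
    top = counts.idxmax()
    if counts[top] * 2 <= len(rows):
        return None
    return top


def evaluate_recovery(
    truth: pd.DataFrame,
    protein_flags: pd.DataFrame,
    splice_profiles: pd.DataFrame,
) -> RecoveryReport:
    pf = protein_flags
    sp = splice_profiles
    rec: dict[str, int] = {}
    tot: dict[str, int] = {}
    for row in truth.itertuples(index=False):
        cls = row.error_class
        tot[cls] = tot.get(cls, 0) + 1
        mine = pf[(pf.tax_id == row.tax_id) & (pf.gene_id == row.gene_id)]
        if mine.empty:
            continue
        expected = row.expected_flag
        if expected == "length_or_nterm":
            hit = bool(mine.length_outlier.any() or mine.nterm_identity_outlier.any())
        elif expected in FLAG_SCREENS:
            hit = bool(mine[expected].any())
        else:  # splice cause
            hit = False
            for pid in mine.protein_id:
                rows = sp[sp.protein_id == pid]
                rows2 = sp[sp.ref_protein_id == pid]
                rows2 = rows2.rename(
                    columns={"protein_id": "ref_protein_id", "ref_protein_id": "protein_id"}
                )
                if _majority_cause(pd.concat([rows, rows2])) == expected:
                    hit = True
                    break
        if hit:
            rec[cls] = rec.get(cls, 0) + 1

    err_genes = set(zip(truth.tax_id, truth.gene_id))
    clean = pf[[(t, g) not in err_genes for t, g in zip(pf.tax_id, pf.gene_id)]]
    false_rates = {}
    for screen in FLAG_SCREENS + ("domain_z_outlier",):
        false_rates[screen] = float(clean[screen].mean()) if len(clean) else 0.0
    cause_by_pid = {}
    for pid, grp in sp.groupby("protein_id"):
        cause_by_pid[pid] = _majority_cause(grp)
    clean_causes = [
        cause_by_pid.get(pid) for pid in clean.protein_id if pid in cause_by_pid
    ]
    for cause in SPLICE_CAUSES:
        false_rates[cause] = (
            sum(1 for c in clean_causes if c == cause) / len(clean_causes)
            if clean_causes
            else 0.0
        )
    any_flag = clean[list(FLAG_SCREENS)].any(axis=1) if len(clean) else pd.Series(dtype=bool)
    overall = float(any_flag.mean()) if len(clean) else 0.0
    return RecoveryReport(
        recovery={c: rec.get(c, 0) / tot[c] for c in tot},
        n_injected=tot,
        false_flag_rate=false_rates,
        overall_false_rate=overall,
    )
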