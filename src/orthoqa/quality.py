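"""Per-organism annotation-quality scorecards.

Five flagged-gene fractions per organism (domain-score outlier; extra,
missing or truncated domain; length outlier; conserved downstream
methionine; no protein in the main cluster) are combined into a negative
sum-of-logs score, -sum_i log10(max(f_i, floor)): higher means fewer
anomalies, hence better annotation quality.  The floor (one over the
number of analyzed genes) keeps the score finite when a fraction is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import SpeciesInfo
from .qa import QAFlags

log = logging.getLogger(__name__)

FRACTION_NAMES = ("f_domain_z", "f_domain_anom", "f_length", "f_met", "f_not_main_cluster")


@dataclass
class OrganismScorecard:
    tax_id: int
    n_genes: int
    fractions: dict[str, float] = field(default_factory=dict)
    aggregate_score: float = 0.0
    core_protein_count: int = 0
    contig_n50: int = 0
    est_count: int = 0


def organism_fractions(
    gene_flags: dict[tuple[int, str], list[QAFlags]],
) -> dict[int, dict[str, float]]:
    """Flagged-gene fractions per organism.

    ``gene_flags`` maps (tax_id, gene_id) -> the QA flags of each of the
    gene's proteins, for every analyzed gene (those in ortholog sets whose
    main cluster has enough reference proteins).  A gene counts toward a
    category when any of its proteins is flagged; for the main-cluster
    category, when none of its proteins is in the largest cluster.
    """
    counters: dict[int, dict[str, int]] = {}
    totals: dict[int, int] = {}
    for (tax, _gene), flags in gene_flags.items():
        c = counters.setdefault(tax, {name: 0 for name in FRACTION_NAMES})
        totals[tax] = totals.get(tax, 0) + 1
        if any(f.domain_z_outlier for f in flags):
            c["f_domain_z"] += 1
        if any(f.extra_domain or f.missing_domain or f.truncated_domain for f in flags):
            c["f_domain_anom"] += 1
        if any(f.length_outlier for f in flags):
            c["f_length"] += 1
        if any(f.downstream_met for f in flags):
            c["f_met"] += 1
        if flags and all(f.not_in_largest_cluster for f in flags):
            c["f_not_main_cluster"] += 1
    out = {}
    for tax, c in counters.items():
        n = totals[tax]
        if n == 0:
            log.warning("organism %s has no analyzed genes; scorecard omitted", tax)
            continue
        out[tax] = {name: c[name] / n for name in FRACTION_NAMES}
        out[tax]["n_genes"] = n
    return out


def aggregate_score(fractions: dict[str, float], floor: float) -> float:
    """Negative sum of log10 fractions, floored to stay finite."""
    return -sum(
        math.log10(max(fractions[name], floor)) for name in FRACTION_NAMES
    )


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient with two-sided p-value; (nan, nan) when a
    vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (math.nan, math.nan)
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def build_scorecards(
    fractions: dict[int, dict[str, float]],
    core_counts: dict[int, int],
    species: dict[int, SpeciesInfo],
) -> list[OrganismScorecard]:
    cards = []
    for tax in sorted(fractions):
        f = fractions[tax]
        n = int(f["n_genes"])
        card = OrganismScorecard(
            tax_id=tax,
            n_genes=n,
            fractions={k: f[k] for k in FRACTION_NAMES},
            aggregate_score=aggregate_score(f, floor=1.0 / n),
            core_protein_count=core_counts.get(tax, 0),
            contig_n50=species[tax].contig_n50,
            est_count=species[tax].est_count,
        )
        cards.append(card)
    return cards


def scorecard_table(cards: list[OrganismScorecard]) -> pd.DataFrame:
    """Per-organism report with summary rows: per-column averages and
    standard deviations plus Pearson correlations against contig N50 and
    EST count."""
    rows = []
    for c in sorted(cards, key=lambda c: -c.aggregate_score):
        row = {"tax_id": str(c.tax_id), "n_genes": c.n_genes}
        row.update({k: round(v, 6) for k, v in c.fractions.items()})
        row["aggregate_score"] = round(c.aggregate_score, 3)
        row["core_proteins"] = c.core_protein_count
        row["contig_n50"] = c.contig_n50
        row["est_count"] = c.est_count
        rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = list(FRACTION_NAMES) + ["aggregate_score", "core_proteins"]
    summary = []
    vals = {col: df[col].astype(float).to_numpy() for col in value_cols}
    summary.append(
        {"tax_id": "average", **{c: round(float(np.mean(v)), 6) for c, v in vals.items()}}
    )
    summary.append(
        {"tax_id": "sd", **{c: round(float(np.std(v, ddof=0)), 6) for c, v in vals.items()}}
    )
    for covariate in ("contig_n50", "est_count"):
        cov = df[covariate].astype(float).to_numpy()
        corr_row = {"tax_id": f"corr_{covariate}"}
        for c, v in vals.items():
            r, _ = correlate(v, cov) if np.std(v) > 0 and np.std(cov) > 0 else (math.nan, math.nan)
            corr_row[c] = round(r, 3) if not math.isnan(r) else math.nan
        summary.append(corr_row)
    return pd.concat([df, pd.DataFrame(summary)], ignore_index=True)


def subgroup_correlations(
    cards: list[OrganismScorecard],
    groups: dict[str, list[int]],
    covariate: str = "contig_n50",
) -> dict[str, float]:
    """Pearson correlation of the aggregate score vs a covariate within
    each taxonomic subgroup (e.g. after excluding designated outliers)."""
    out = {}
    by_tax = {c.tax_id: c for c in cards}
    for name, taxa in groups.items():
        sub = [by_tax[t] for t in taxa if t in by_tax]
        if len(sub) < 3:
            out[name] = math.nan
            continue
        r, _ = correlate(
            [c.aggregate_score for c in sub], [getattr(c, covariate) for c in sub]
        )
        out[name] = r
    return out
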