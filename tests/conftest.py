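"""Shared fixtures and fixture builders."""

from __future__ import annotations

import random

import pytest

from orthoqa.model import DomainHit, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_protein(
    seq: str,
    exon_lens_nt: list[int] | None = None,
    pid: str = "P1",
    gene: str = "g1",
    species: int = 9001,
    stop: bool = False,
    domains: list[DomainHit] | None = None,
    signal: bool = False,
) -> ProteinRecord:
    """Build a protein with an exon map given as per-exon nt lengths.

    With ``stop=False`` the lengths must sum to 3*len(seq); with
    ``stop=True`` to 3*(len(seq)+1).
    """
    emap = []
    pos = 0
    for ln in exon_lens_nt or [3 * len(seq) + (3 if stop else 0)]:
        emap.append((pos, pos + ln))
        pos += ln
    return ProteinRecord(
        protein_id=pid,
        gene_id=gene,
        species=species,
        sequence=seq,
        exon_residue_map=emap,
        cds_includes_stop=stop,
        domains=domains or [],
        has_signal_peptide=signal,
    )


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA) for _ in range(n))


@pytest.fixture(scope="session")
def small_clean_clade():
    """A small error-free clade shared by integration tests."""
    from orthoqa.synth import CladeConfig, generate_clade

    return generate_clade(CladeConfig(n_species=6, n_reference=5, n_genes=10, seed=42))


@pytest.fixture(scope="session")
def small_clean_run(small_clean_clade):
    from orthoqa.pipeline import RunConfig, run
    from orthoqa.synth import best_hit_table, to_bundles

    clade = small_clean_clade
    bundles = to_bundles(clade)
    hits = {t: best_hit_table(clade, t) for t in bundles}
    config = RunConfig(
        anchor_taxon=clade.anchor_taxon,
        reference_taxa=clade.reference_taxa,
        core_min_organisms=4,
        seed=7,
    )
    return run(bundles, hits, config), clade, config
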