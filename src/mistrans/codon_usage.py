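"""Codon-usage accounting and gene ranking by mistranslatable-codon content.

Which genes are most exposed to a given mistranslating tRNA is, to first
order, a question of how many codons readable by that tRNA each gene
carries.  This module tabulates codon usage across a CDS database (stop
codons excluded) and ranks genes by their content of a target codon set,
either as a raw count or normalized per codon (density).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import pandas as pd

from .sequence_db import SequenceDatabase, translate_codon

__all__ = ["codon_usage_table", "rank_genes_by_target_codons"]


def _validate_codons(codon_set: Iterable[str]) -> list[str]:
    codons = [c.upper().replace("U", "T") for c in codon_set]
    if not codons:
        raise ValueError("codon set must be nonempty")
    for c in codons:
        if translate_codon(c) == "*":
            raise ValueError(f"stop codon {c!r} in target set")
    return codons


def _gene_codons(gene) -> Iterable[str]:
    cds = gene.cds
    # stop codon, when present, lies beyond 3 * protein length
    for i in range(len(gene.protein)):
        yield cds[3 * i : 3 * i + 3]


def codon_usage_table(db: SequenceDatabase) -> pd.DataFrame:
    """Per-codon counts and fractions over all coding positions of a database.

    Returns a DataFrame indexed by codon with columns ``count`` and
    ``fraction`` (fractions sum to 1); stop codons are excluded.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    counts: Counter[str] = Counter()
    for gene in db:
        counts.update(_gene_codons(gene))
    total = sum(counts.values())
    table = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype="int64").sort_index(),
        }
    )
    table.index.name = "codon"
    table["fraction"] = table["count"] / total
    return table


def rank_genes_by_target_codons(
    db: SequenceDatabase, codon_set: Iterable[str], normalize: bool = False
) -> pd.DataFrame:
    """Rank genes by their content of the target codons.

    With ``normalize=False`` genes are sorted by descending raw count of
    target codons; with ``normalize=True`` by count per coding codon
    (density), which favors short, codon-dense genes.  Ties break
    lexicographically by gene ID.
    """
    codons = set(_validate_codons(codon_set))
    rows = []
    for gene in db:
        count = sum(1 for c in _gene_codons(gene) if c in codons)
        length = len(gene.protein)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "target_codon_count": count,
                "n_codons": length,
                "density": count / length,
            }
        )
    table = pd.DataFrame(rows)
    key = "density" if normalize else "target_codon_count"
    table = table.sort_values(
        [key, "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    return table
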