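"""Residue- and codon-level mistranslation frequencies and decoding classes.

The central statistic: the fraction of unique peptides in which serine was
observed in place of the genomically encoded valine or threonine.  Two
evidence rules guard it:

* **sibling rule** - a substituted peptide counts only if its wild-type
  (non-substituted) form was also observed in the same replicate;
* **unique localization** - for codon-level analysis a substituted peptide
  must carry exactly one substituted site and its wild-type sequence must
  occur exactly once in the protein database, so the event maps to a single
  codon.

The codon-level view is what separates decoding routes: a tRNA with
anticodon 34-36 reads its fully Watson-Crick codon directly, can read two
further codons by inosine-34 wobble when A34 is deaminated, and should not
read the codon mismatched at the third position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .masses import SubstitutionSpec, substitution
from .phenotype_stats import holm_bonferroni, welch_t_test
from .psm_pipeline import UniquePeptide
from .sequence_db import SequenceDatabase, codons_for_residue, translate_codon

__all__ = [
    "DECODING_CLASSES",
    "VARIANT_ANTICODONS",
    "UndefinedFrequencyError",
    "FrequencyResult",
    "CodonFrequency",
    "MistranslationReport",
    "sibling_filter",
    "mistranslation_frequency",
    "unique_localization_filter",
    "per_codon_frequency",
    "classify_decoding",
    "compare_replicate_frequencies",
    "TestSummary",
    "write_report",
]

DECODING_CLASSES = (
    "watson_crick",
    "wobble_I34",
    "wobble_GU",
    "mismatch_3prime",
    "other",
)

#: Anticodons (5'->3', RNA) of the serine tRNA variants that misread
#: valine and threonine codons in the fly lines this pipeline analyses.
VARIANT_ANTICODONS = {"V": "AAC", "T": "AGU"}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class UndefinedFrequencyError(ValueError):
    """Raised when a frequency has an empty denominator (not reported as 0)."""


@dataclass(frozen=True)
class FrequencyResult:
    """Residue-level mistranslation frequency for one replicate."""

    substitution: SubstitutionSpec
    n_mistranslated: int
    n_total: int
    frequency_pct: float
    replicate_id: str = ""


@dataclass(frozen=True)
class CodonFrequency:
    """Mistranslation frequency at one codon, with its decoding class."""

    codon: str  # DNA alphabet, e.g. "ACT"
    n_sub_events: int
    n_wt_events: int
    frequency_pct: float
    decoding_class: str

    @property
    def rna(self) -> str:
        return self.codon.replace("T", "U")


@dataclass(frozen=True)
class MistranslationReport:
    """Per-replicate bundle: residue-level frequency plus per-codon detail."""

    replicate_id: str
    frequency: FrequencyResult
    codon_frequencies: tuple[CodonFrequency, ...]
    n_psms_input: int
    n_psms_passing: int
    n_unique_peptides: int


class TestSummary(NamedTuple):
    statistic: float
    pvalue: float
    adjusted_pvalue: float


def _is_sub_of(u: UniquePeptide, sub: SubstitutionSpec) -> bool:
    return u.is_substituted and u.sub_from == sub.from_aa and u.sub_to == sub.to_aa


def sibling_filter(unique_peptides: Sequence[UniquePeptide]) -> list[UniquePeptide]:
    """Substituted peptides whose wild-type sibling was also observed.

    The sibling is a wild-type :class:`UniquePeptide` with an identical
    ``base_sequence`` in the same (replicate's) collection.  Requiring the
    sibling anchors every counted mistranslation event to a peptide whose
    unmodified form is demonstrably detectable.
    """
    wild_type_seqs = {
        u.base_sequence for u in unique_peptides if not u.is_substituted
    }
    return [
        u
        for u in unique_peptides
        if u.is_substituted and u.base_sequence in wild_type_seqs
    ]


def mistranslation_frequency(
    unique_peptides: Sequence[UniquePeptide],
    sub: SubstitutionSpec,
    replicate_id: str = "",
    apply_sibling: bool = True,
    count_mode: str = "unique",
    substituted_in_denominator: bool = True,
) -> FrequencyResult:
    """Residue-level mistranslation frequency, as a percentage.

    Numerator: unique substituted peptides for ``sub`` (after the sibling
    rule unless ``apply_sibling=False``).  Denominator: unique peptides
    whose wild-type sequence contains at least one origin residue --
    wild-type forms plus, by default, the substituted forms themselves
    (each identity tuple counted once).  ``count_mode="psm"`` weights each
    unique peptide by its PSM multiplicity instead.

    Raises :class:`UndefinedFrequencyError` when the denominator is empty:
    an absent denominator is not a 0% frequency.
    """
    if count_mode not in ("unique", "psm"):
        raise ValueError("count_mode must be 'unique' or 'psm'")
    weight = (lambda u: u.psm_count) if count_mode == "psm" else (lambda u: 1)

    numerator_set = [u for u in unique_peptides if _is_sub_of(u, sub)]
    if apply_sibling:
        numerator_set = sibling_filter(
            [u for u in unique_peptides if not u.is_substituted] + numerator_set
        )

    def in_denominator(u: UniquePeptide) -> bool:
        if sub.from_aa not in u.base_sequence:
            return False
        if u.is_substituted and not substituted_in_denominator:
            return False
        return True

    n_mis = sum(weight(u) for u in numerator_set)
    n_total = sum(weight(u) for u in unique_peptides if in_denominator(u))
    if n_total == 0:
        raise UndefinedFrequencyError(
            f"no peptides containing {sub.from_aa} observed; frequency undefined"
        )
    return FrequencyResult(
        substitution=sub,
        n_mistranslated=n_mis,
        n_total=n_total,
        frequency_pct=100.0 * n_mis / n_total,
        replicate_id=replicate_id,
    )


def unique_localization_filter(
    substituted_peptides: Sequence[UniquePeptide], db: SequenceDatabase
) -> list[UniquePeptide]:
    """Keep substituted peptides with exactly one attributable event.

    A peptide survives iff it carries exactly one substituted site and its
    wild-type sequence occurs at exactly one position across the protein
    database, so the substituted residue maps to a single codon.
    """
    kept = []
    for u in substituted_peptides:
        if len(u.sub_positions) != 1:
            continue
        if len(db.locate(u.base_sequence)) == 1:
            kept.append(u)
    return kept


def classify_decoding(anticodon: str, codon: str) -> str:
    """Classify how a tRNA anticodon could decode a codon.

    Both arguments are 5'->3' triplets (RNA or DNA alphabet).  The
    anticodon's positions 35 and 36 must Watson-Crick pair codon positions
    2 and 1; position 34 then meets the codon's third (wobble) position:

    * Watson-Crick pair -> ``watson_crick`` (A34:U3 included: such codons
      are read as fully complementary);
    * A34 against C3 or A3 -> ``wobble_I34`` (decoding expected only if
      A34 is deaminated to inosine, which pairs U, C, and A);
    * G34:U3 or U34:G3 -> ``wobble_GU``;
    * anything else at position 3 -> ``mismatch_3prime``;
    * any position-35/36 mispair -> ``other``.
    """
    ac = anticodon.upper().replace("T", "U")
    cd = codon.upper().replace("T", "U")
    for trip, name in ((ac, "anticodon"), (cd, "codon")):
        if len(trip) != 3 or set(trip) - set("ACGU"):
            raise ValueError(f"invalid {name} {trip!r}")
    # codon 1 pairs anticodon 36, codon 2 pairs anticodon 35 (antiparallel)
    if (ac[2], cd[0]) not in _WC_PAIRS or (ac[1], cd[1]) not in _WC_PAIRS:
        return "other"
    a34, c3 = ac[0], cd[2]
    if (a34, c3) in _WC_PAIRS:
        return "watson_crick"
    if a34 == "A" and c3 in ("C", "A"):
        return "wobble_I34"
    if (a34, c3) in (("G", "U"), ("U", "G")):
        return "wobble_GU"
    return "mismatch_3prime"


def per_codon_frequency(
    unique_peptides: Sequence[UniquePeptide],
    db: SequenceDatabase,
    sub: SubstitutionSpec,
    anticodon: str | None = None,
) -> list[CodonFrequency]:
    """Mistranslation frequency at every codon encoding the origin residue.

    Substituted peptides are restricted by :func:`unique_localization_filter`;
    wild-type peptides are restricted to uniquely locating sequences.
    Counting is occurrence-level: every origin-residue site of a retained
    wild-type peptide contributes one wild-type event at its codon, and
    every retained substituted peptide contributes one substitution event
    at the codon of its (single) substituted site.
    """
    codons = codons_for_residue(sub.from_aa)  # raises for invalid residue
    if anticodon is None:
        anticodon = VARIANT_ANTICODONS.get(sub.from_aa)
        if anticodon is None:
            raise ValueError(
                f"no default anticodon for origin residue {sub.from_aa!r}; "
                "pass anticodon= explicitly"
            )
    n_sub: dict[str, int] = {c: 0 for c in codons}
    n_wt: dict[str, int] = {c: 0 for c in codons}

    substituted = [u for u in unique_peptides if _is_sub_of(u, sub)]
    for u in unique_localization_filter(substituted, db):
        loc = db.locate(u.base_sequence)[0]
        gene = db[loc.gene_id]
        codon = gene.codon(loc.start + u.sub_positions[0])
        if translate_codon(codon) != sub.from_aa:  # pragma: no cover - db invariant
            raise ValueError(
                f"codon {codon} at {loc.gene_id}:{loc.start + u.sub_positions[0]} "
                f"does not encode {sub.from_aa}"
            )
        n_sub[codon] += 1

    for u in unique_peptides:
        if u.is_substituted:
            continue
        locs = db.locate(u.base_sequence)
        if len(locs) != 1:
            continue
        gene = db[locs[0].gene_id]
        for i, aa in enumerate(u.base_sequence):
            if aa == sub.from_aa:
                n_wt[gene.codon(locs[0].start + i)] += 1

    out = []
    for codon in codons:
        total = n_sub[codon] + n_wt[codon]
        freq = 100.0 * n_sub[codon] / total if total else 0.0
        out.append(
            CodonFrequency(
                codon=codon,
                n_sub_events=n_sub[codon],
                n_wt_events=n_wt[codon],
                frequency_pct=freq,
                decoding_class=classify_decoding(anticodon, codon),
            )
        )
    return out


def compare_replicate_frequencies(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestSummary:
    """Welch t-test between per-replicate frequency vectors of two genotypes.

    Returns the statistic, the raw two-sided p-value, and the
    Holm-adjusted p-value (equal to the raw p for a single comparison; for
    codon-wise families collect raw p-values and apply
    :func:`mistrans.phenotype_stats.holm_bonferroni` across them).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    stat, p = welch_t_test(group_a, group_b)
    return TestSummary(stat, p, float(holm_bonferroni([p])[0]))


def quantify_replicate(
    psms,
    db: SequenceDatabase | None,
    sub: SubstitutionSpec | tuple[str, str],
    fdr: float = 0.01,
    tol_ppm: float | None = 20.0,
    replicate_id: str = "",
    count_mode: str = "unique",
) -> MistranslationReport:
    """Run the full per-replicate pipeline on PSM records.

    ``psms`` may be a path to a PSM table or a sequence of
    :class:`~mistrans.psm_pipeline.PSMRecord`.  Steps: parse (with ppm
    gate), target-decoy q-values, FDR filter, collapse to unique peptides,
    residue-level frequency, and -- when ``db`` is given -- per-codon
    frequencies with decoding classes.
    """
    from .psm_pipeline import (
        collapse_to_unique,
        compute_qvalues,
        filter_fdr,
        read_psm_table,
    )

    if isinstance(sub, tuple):
        sub = substitution(*sub)
    if isinstance(psms, str):
        psms = read_psm_table(psms, tol_ppm=tol_ppm).records
    else:
        psms = list(psms)
    n_in = len(psms)
    passing = filter_fdr(compute_qvalues(psms), threshold=fdr)
    uniques = collapse_to_unique(passing)
    freq = mistranslation_frequency(
        uniques, sub, replicate_id=replicate_id, count_mode=count_mode
    )
    codon_freqs: tuple[CodonFrequency, ...] = ()
    if db is not None:
        codon_freqs = tuple(per_codon_frequency(uniques, db, sub))
    return MistranslationReport(
        replicate_id=replicate_id,
        frequency=freq,
        codon_frequencies=codon_freqs,
        n_psms_input=n_in,
        n_psms_passing=len(passing),
        n_unique_peptides=len(uniques),
    )


def write_report(reports: Iterable[MistranslationReport], path: str) -> None:
    """Write replicate reports as TSV: one summary row, then codon rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "replicate_id\trow_type\tsubstitution\tcodon\tdecoding_class\t"
            "n_mistranslated\tn_total\tfrequency_pct\n"
        )
        for rep in reports:
            f = rep.frequency
            label = f"{f.substitution.from_aa}->{f.substitution.to_aa}"
            fh.write(
                f"{rep.replicate_id}\tresidue\t{label}\t.\t.\t"
                f"{f.n_mistranslated}\t{f.n_total}\t{f.frequency_pct:.6f}\n"
            )
            for c in rep.codon_frequencies:
                fh.write(
                    f"{rep.replicate_id}\tcodon\t{label}\t{c.rna}\t{c.decoding_class}\t"
                    f"{c.n_sub_events}\t{c.n_sub_events + c.n_wt_events}\t"
                    f"{c.frequency_pct:.6f}\n"
                )
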