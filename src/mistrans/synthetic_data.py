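"""Synthetic data generators with ground-truth ledgers.

Every pipeline stage is testable without external downloads: a random
coding-gene database stands in for the organism's proteome, a simulated
Lys-C shotgun experiment produces PSM tables with known per-codon
substitution rates (plus score-matched decoys), and simple parametric
models produce survival and count phenotype tables.

Each generator is a pure function of its seed: rerunning with the same
parameters yields byte-identical files.  The PSM generator also returns a
:class:`GroundTruthLedger` recording exactly which substitution events
were emitted, so estimator recovery can be checked against realized (not
merely nominal) truth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .masses import peptide_mass, substitution_delta
from .phenotype_stats import CountTable2x2
from .psm_pipeline import PSMRecord
from .sequence_db import (
    CodingGene,
    SequenceDatabase,
    codons_for_residue,
    digest_lysC,
)

__all__ = [
    "AA_FREQUENCIES",
    "SimulationSpec",
    "GroundTruthLedger",
    "generate_proteome",
    "write_paired_fasta",
    "generate_psms",
    "generate_survival",
    "generate_counts",
]

# Average amino-acid frequencies of well-annotated proteomes (UniProtKB
# averages, percent); used as sampling weights for synthetic proteins.
AA_FREQUENCIES: Mapping[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.09, "Y": 2.92, "V": 6.87,
}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with defaults set to its design.

    The default substitution model is serine misincorporation at
    threonine codons with per-codon rates of 1% at ACT, 0.5% at ACC, and
    0 at ACA/ACG -- strong wobble-ordered rates on the order observed for
    mistranslating tRNA variants -- over a proteome large enough that each
    threonine codon is covered by >= 5,000 wild-type occurrences.
    Detection of the wild-type sibling defaults to certain (1.0); target
    and decoy scores are unit-variance Gaussians separated by 4 SD, which
    yields a sharp 1% FDR gate retaining most targets.
    """

    seed: int = 0
    n_genes: int = 1600
    length_log_mean: float = math.log(350.0)
    length_log_sigma: float = 0.35
    min_length: int = 60
    max_length: int = 2000
    aa_weights: Mapping[str, float] = field(default_factory=lambda: dict(AA_FREQUENCIES))
    codon_weights: Mapping[str, float] | None = None  # None = uniform per family
    substitution: tuple[str, str] = ("T", "S")
    per_codon_rates: Mapping[str, float] = field(
        default_factory=lambda: {"ACT": 0.01, "ACC": 0.005, "ACA": 0.0, "ACG": 0.0}
    )
    detection_prob: float = 1.0
    decoy_fraction: float = 0.5  # decoys emitted per target peptide sequence
    target_score_mean: float = 4.0
    decoy_score_mean: float = 0.0
    score_sd: float = 1.0
    mass_error_ppm_sd: float = 3.0
    max_mass_error_ppm: float = 15.0
    min_peptide_length: int = 7
    max_peptide_length: int = 45
    n_spectra: int | None = None  # optional cap on emitted target rows

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")
        if not 0 <= self.decoy_fraction:
            raise ValueError("decoy_fraction must be >= 0")
        for codon, rate in self.per_codon_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for {codon} outside [0, 1]")
        if any(w < 0 for w in self.aa_weights.values()) or not any(
            self.aa_weights.values()
        ):
            raise ValueError("invalid amino-acid weights")


@dataclass
class GroundTruthLedger:
    """Realized truth of one simulated PSM table.

    Per-codon counts cover only uniquely-locating peptides (the only ones
    the codon-level estimator can use); substituted rows whose sequence
    occurs at multiple database positions are tallied separately as
    ambiguous.  Conservation: ``sum(per_codon_sub) + n_ambiguous_sub``
    equals the number of substituted target rows emitted.
    """

    substitution: tuple[str, str]
    per_codon_sub: dict[str, int] = field(default_factory=dict)
    per_codon_wt: dict[str, int] = field(default_factory=dict)
    n_ambiguous_sub: int = 0
    n_target_rows: int = 0
    n_decoy_rows: int = 0
    n_wt_peptides: int = 0
    n_origin_wt_peptides: int = 0
    n_sub_peptides: int = 0

    def codon_truth_pct(self, codon: str) -> float:
        """Realized per-codon substitution frequency, in percent."""
        s = self.per_codon_sub.get(codon, 0)
        w = self.per_codon_wt.get(codon, 0)
        return 100.0 * s / (s + w) if s + w else 0.0

    def peptide_frequency_pct(self) -> float:
        """Realized peptide-level frequency (substituted forms in denominator)."""
        denom = self.n_origin_wt_peptides + self.n_sub_peptides
        return 100.0 * self.n_sub_peptides / denom if denom else 0.0


def _codon_choices(codon_weights: Mapping[str, float] | None) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-residue synonymous codon lists with normalized sampling weights."""
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in AA_FREQUENCIES:
        codons = codons_for_residue(aa)
        if codon_weights:
            w = np.array(
                [float(codon_weights.get(c, 0.0)) for c in codons], dtype=float
            )
            if w.sum() <= 0:
                w = np.ones(len(codons))
        else:
            w = np.ones(len(codons))
        table[aa] = (codons, w / w.sum())
    return table


def generate_proteome(spec: SimulationSpec) -> SequenceDatabase:
    """Sample a random coding-gene database under the simulation spec.

    Protein lengths are lognormal (clipped); residues are drawn i.i.d.
    from ``aa_weights``; each residue's codon is drawn from the synonymous
    family under ``codon_weights`` (uniform by default).  Every CDS ends
    with a TAA stop codon.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    aas = sorted(spec.aa_weights)
    aa_p = np.array([spec.aa_weights[a] for a in aas], dtype=float)
    aa_p = aa_p / aa_p.sum()
    lengths = np.clip(
        np.round(
            rng.lognormal(spec.length_log_mean, spec.length_log_sigma, spec.n_genes)
        ).astype(int),
        spec.min_length,
        spec.max_length,
    )
    choices = _codon_choices(spec.codon_weights)
    total = int(lengths.sum())
    residues = rng.choice(np.array(aas), size=total, p=aa_p)
    # choose codons per residue, vectorized within each amino-acid family
    codon_arr = np.empty(total, dtype="<U3")
    for aa in aas:
        mask = residues == aa
        k = int(mask.sum())
        if k:
            codons, w = choices[aa]
            codon_arr[mask] = rng.choice(np.array(codons), size=k, p=w)
    genes = []
    pos = 0
    width = len(str(spec.n_genes))
    for g, length in enumerate(lengths, start=1):
        protein = "".join(residues[pos : pos + length])
        cds = "".join(codon_arr[pos : pos + length]) + "TAA"
        pos += length
        genes.append(CodingGene(f"gene_{g:0{width}d}", protein, cds, has_stop=True))
    return SequenceDatabase.from_genes(genes)


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_paired_fasta(
    db: SequenceDatabase, protein_path: str, cds_path: str
) -> None:
    """Write the database as deterministic protein and CDS FASTA files."""
    with open(protein_path, "w", encoding="utf-8") as fh:
        for gene in db:
            fh.write(f">{gene.gene_id}\n{_wrap(gene.protein)}\n")
    with open(cds_path, "w", encoding="utf-8") as fh:
        for gene in db:
            fh.write(f">{gene.gene_id}\n{_wrap(gene.cds)}\n")


def generate_psms(
    spec: SimulationSpec, db: SequenceDatabase
) -> tuple[list[PSMRecord], GroundTruthLedger]:
    """Simulate a searched shotgun run over ``db`` under the spec's model.

    Proteins are digested with Lys-C (no missed cleavages); peptides in
    the configured length window are considered once each.  For every
    distinct peptide sequence the wild-type form is observed with
    ``detection_prob``; independently, every origin-residue site (at each
    database occurrence) is substituted with its codon's rate, emitting a
    single-site substituted PSM.  Decoys are reversed peptide sequences
    with null-distribution scores.  All masses are consistent with the
    emitted sequences, with a small clipped ppm error.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    origin, dest = spec.substitution
    delta = substitution_delta(origin, dest)
    rates = {k.upper().replace("U", "T"): v for k, v in spec.per_codon_rates.items()}

    # distinct peptide sequences -> occurrences, deterministic order
    occurrences: dict[str, list[tuple[str, int]]] = {}
    for gene in db:
        for pep, start in digest_lysC(gene.protein, max_missed=0):
            if spec.min_peptide_length <= len(pep) <= spec.max_peptide_length:
                occurrences.setdefault(pep, []).append((gene.gene_id, start))
    seqs = sorted(occurrences)
    if not seqs:
        raise ValueError("digest produced no peptides in the length window")
    if spec.n_spectra is not None and len(seqs) > spec.n_spectra:
        keep = rng.choice(len(seqs), size=spec.n_spectra, replace=False)
        seqs = [seqs[i] for i in sorted(keep)]

    ledger = GroundTruthLedger(substitution=(origin, dest))
    for codon in codons_for_residue(origin):
        ledger.per_codon_sub[codon] = 0
        ledger.per_codon_wt[codon] = 0

    records: list[PSMRecord] = []
    scan = 0

    def emit(seq: str, positions: tuple[int, ...], is_decoy: bool, score: float) -> None:
        nonlocal scan
        scan += 1
        mods = [(p, delta) for p in positions]
        calc = peptide_mass(seq, mods)
        err = float(
            np.clip(
                rng.normal(0.0, spec.mass_error_ppm_sd),
                -spec.max_mass_error_ppm,
                spec.max_mass_error_ppm,
            )
        )
        records.append(
            PSMRecord(
                spectrum_id=f"scan_{scan:07d}",
                base_sequence=seq,
                sub_positions=positions,
                sub_from=origin if positions else "",
                sub_to=dest if positions else "",
                charge=int(rng.integers(2, 4)),
                calc_mass=calc,
                obs_mass=calc * (1 + err * 1e-6),
                score=score,
                is_decoy=is_decoy,
            )
        )

    target_seq_set = set(seqs)
    for seq in seqs:
        locs = occurrences[seq]
        unique_loc = len(locs) == 1
        wt_observed = rng.random() < spec.detection_prob
        if wt_observed:
            emit(seq, (), False, float(rng.normal(spec.target_score_mean, spec.score_sd)))
            ledger.n_target_rows += 1
            ledger.n_wt_peptides += 1
            if origin in seq:
                ledger.n_origin_wt_peptides += 1
        site_positions = [i for i, aa in enumerate(seq) if aa == origin]
        emitted_positions: set[int] = set()
        for gene_id, start in locs:
            gene = db[gene_id]
            for i in site_positions:
                codon = gene.codon(start + i)
                rate = rates.get(codon, 0.0)
                if rate > 0 and rng.random() < rate and i not in emitted_positions:
                    emitted_positions.add(i)
                    emit(
                        seq,
                        (i,),
                        False,
                        float(rng.normal(spec.target_score_mean, spec.score_sd)),
                    )
                    ledger.n_target_rows += 1
                    ledger.n_sub_peptides += 1
                    if unique_loc:
                        ledger.per_codon_sub[codon] += 1
                    else:
                        ledger.n_ambiguous_sub += 1
        if wt_observed and unique_loc:
            gene = db[locs[0][0]]
            for i in site_positions:
                ledger.per_codon_wt[gene.codon(locs[0][1] + i)] += 1
        # decoy: reversed sequence, skipping collisions with real peptides
        if rng.random() < spec.decoy_fraction:
            decoy_seq = seq[::-1]
            if decoy_seq not in target_seq_set:
                emit(
                    decoy_seq,
                    (),
                    True,
                    float(rng.normal(spec.decoy_score_mean, spec.score_sd)),
                )
                ledger.n_decoy_rows += 1
    return records, ledger


def generate_survival(
    n_per_group: Sequence[int],
    hazards: Sequence[float],
    censor_rate: float = 0.0,
    seed: int = 0,
    interval_days: int = 3,
    group_labels: Sequence[str] | None = None,
) -> "pd.DataFrame":
    """Two-group (or k-group) survival table under exponential hazards.

    Death times are exponential with the given per-day hazards and are
    discretized upward to the inspection grid (every ``interval_days``
    days, mirroring transfer-to-fresh-food scoring).  Censoring is an
    independent exponential with hazard chosen so the pre-discretization
    censoring probability equals ``censor_rate``; ``censor_rate=1``
    censors every subject at its drawn time.
    """
    import pandas as pd

    if len(n_per_group) != len(hazards):
        raise ValueError("n_per_group and hazards must have equal length")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    if any(h <= 0 for h in hazards):
        raise ValueError("hazards must be positive")
    if group_labels is None:
        group_labels = [chr(ord("A") + i) for i in range(len(hazards))]
    rng = np.random.default_rng([seed, 2])
    rows = []
    sid = 0
    for label, n, h in zip(group_labels, n_per_group, hazards):
        death = rng.exponential(1.0 / h, size=n)
        if censor_rate >= 1.0:
            censored = np.ones(n, dtype=bool)
            observed_time = death
        elif censor_rate <= 0.0:
            censored = np.zeros(n, dtype=bool)
            observed_time = death
        else:
            c_hazard = h * censor_rate / (1.0 - censor_rate)
            censor = rng.exponential(1.0 / c_hazard, size=n)
            censored = censor < death
            observed_time = np.minimum(death, censor)
        day = np.ceil(observed_time / interval_days) * interval_days
        day = np.maximum(day, interval_days)
        for i in range(n):
            sid += 1
            rows.append(
                {
                    "subject_id": f"s{sid:05d}",
                    "group": label,
                    "sex": "F",
                    "day": float(day[i]),
                    "status": "censored" if censored[i] else "dead",
                }
            )
    return pd.DataFrame(rows)


def generate_counts(
    p_per_group: Sequence[float],
    n_per_group: Sequence[int],
    seed: int = 0,
) -> CountTable2x2:
    """Binomial success/failure counts for two groups as a 2x2 table."""
    if len(p_per_group) != 2 or len(n_per_group) != 2:
        raise ValueError("exactly two groups are required")
    for p in p_per_group:
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    k = [int(rng.binomial(n, p)) for p, n in zip(p_per_group, n_per_group)]
    return CountTable2x2(
        a=k[0], b=int(n_per_group[0]) - k[0], c=k[1], d=int(n_per_group[1]) - k[1]
    )
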