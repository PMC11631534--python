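"""PSM table I/O, target-decoy q-values, FDR filtering, and unique-peptide collapse.

This is the stand-in for the search-engine/post-processor stage of the
pipeline: peptide-spectrum matches (PSMs) arrive in a tab-separated table,
are validated against structural invariants (substitution annotation must
match the wild-type sequence, at most two substituted sites per peptide,
precursor mass within tolerance), scored against the decoy population to
obtain q-values, gated at a PSM-level FDR (1% by default), and collapsed to
unique peptides.

The q-value estimator is a transparent target-decoy competition: no
semi-supervised rescoring is attempted, because downstream analysis only
needs a calibrated FDR gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .masses import within_ppm

__all__ = [
    "PSM_COLUMNS",
    "PSMRecord",
    "UniquePeptide",
    "RowRejection",
    "ParsedPSMs",
    "read_psm_table",
    "write_psm_table",
    "records_to_frame",
    "compute_qvalues",
    "filter_fdr",
    "collapse_to_unique",
    "MAX_SUB_SITES",
]

#: Exact column order of the tab-separated PSM dialect.
PSM_COLUMNS = [
    "spectrum_id",
    "base_sequence",
    "sub_positions",
    "sub_from",
    "sub_to",
    "charge",
    "calc_mass",
    "obs_mass",
    "score",
    "is_decoy",
]

#: Search design allows at most this many substituted sites per peptide.
MAX_SUB_SITES = 2


@dataclass
class PSMRecord:
    """One peptide-spectrum match.

    ``base_sequence`` is always the wild-type (pre-substitution) peptide;
    ``sub_positions`` are 0-based in-peptide indices carrying the
    substitution (empty tuple for a wild-type identification).
    """

    spectrum_id: str
    base_sequence: str
    sub_positions: tuple[int, ...]
    sub_from: str
    sub_to: str
    charge: int
    calc_mass: float
    obs_mass: float
    score: float
    is_decoy: bool
    q_value: float | None = None

    @property
    def is_substituted(self) -> bool:
        return bool(self.sub_positions)

    @property
    def identity(self) -> tuple:
        return (self.base_sequence, self.sub_positions, self.sub_from, self.sub_to)


@dataclass(frozen=True)
class UniquePeptide:
    """A unique peptide identity with its PSM multiplicity and best q-value."""

    base_sequence: str
    sub_positions: tuple[int, ...]
    sub_from: str
    sub_to: str
    psm_count: int
    best_q: float

    @property
    def is_substituted(self) -> bool:
        return bool(self.sub_positions)

    @property
    def identity(self) -> tuple:
        return (self.base_sequence, self.sub_positions, self.sub_from, self.sub_to)


class RowRejection(NamedTuple):
    """A rejected input row: 0-based data-row index plus the reason."""

    row: int
    reason: str


class ParsedPSMs(NamedTuple):
    records: list[PSMRecord]
    rejected: list[RowRejection]


def _parse_row(row: pd.Series, tol_ppm: float | None) -> PSMRecord:
    seq = str(row["base_sequence"]).strip().upper()
    if not seq:
        raise ValueError("empty base_sequence")
    raw_pos = str(row["sub_positions"]).strip()
    if raw_pos:
        # positions are 1-based in file, 0-based in memory
        positions = tuple(sorted(int(p) - 1 for p in raw_pos.split(";")))
    else:
        positions = ()
    sub_from = str(row["sub_from"]).strip().upper()
    sub_to = str(row["sub_to"]).strip().upper()
    if positions:
        if not sub_from or not sub_to:
            raise ValueError("substituted row lacks sub_from/sub_to")
        if len(positions) > MAX_SUB_SITES:
            raise ValueError(
                f"{len(positions)} substitution sites exceed the maximum of {MAX_SUB_SITES}"
            )
        for p in positions:
            if not 0 <= p < len(seq):
                raise ValueError(f"substitution position {p + 1} outside peptide")
            if seq[p] != sub_from:
                raise ValueError(
                    f"base_sequence[{p + 1}] = {seq[p]!r} does not match sub_from {sub_from!r}"
                )
    record = PSMRecord(
        spectrum_id=str(row["spectrum_id"]),
        base_sequence=seq,
        sub_positions=positions,
        sub_from=sub_from,
        sub_to=sub_to,
        charge=int(row["charge"]),
        calc_mass=float(row["calc_mass"]),
        obs_mass=float(row["obs_mass"]),
        score=float(row["score"]),
        is_decoy=bool(int(row["is_decoy"])),
    )
    if not math.isfinite(record.score):
        raise ValueError("non-finite score")
    if tol_ppm is not None and not within_ppm(
        record.obs_mass, record.calc_mass, tol_ppm
    ):
        ppm = abs(record.obs_mass - record.calc_mass) / record.calc_mass * 1e6
        raise ValueError(f"precursor mass error {ppm:.1f} ppm exceeds {tol_ppm} ppm")
    return record


def read_psm_table(path: str, tol_ppm: float | None = 20.0) -> ParsedPSMs:
    """Parse the tab-separated PSM dialect, collecting per-row violations.

    Structurally invalid rows (annotation/sequence mismatch, more than
    :data:`MAX_SUB_SITES` substituted sites, precursor mass outside
    ``tol_ppm``) are rejected individually and reported; valid rows are
    returned as :class:`PSMRecord` objects.  Set ``tol_ppm=None`` to skip
    the mass gate at parse time.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing required columns {missing}")
    records: list[PSMRecord] = []
    rejected: list[RowRejection] = []
    for i, row in table.iterrows():
        try:
            records.append(_parse_row(row, tol_ppm))
        except (ValueError, TypeError) as exc:
            rejected.append(RowRejection(int(i), str(exc)))
    return ParsedPSMs(records, rejected)


def records_to_frame(psms: Iterable[PSMRecord]) -> pd.DataFrame:
    """Render records back into the tab-separated dialect (1-based positions)."""
    rows = []
    for r in psms:
        rows.append(
            {
                "spectrum_id": r.spectrum_id,
                "base_sequence": r.base_sequence,
                "sub_positions": ";".join(str(p + 1) for p in r.sub_positions),
                "sub_from": r.sub_from,
                "sub_to": r.sub_to,
                "charge": r.charge,
                "calc_mass": f"{r.calc_mass:.6f}",
                "obs_mass": f"{r.obs_mass:.6f}",
                "score": f"{r.score:.6f}",
                "is_decoy": int(r.is_decoy),
            }
        )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_table(psms: Iterable[PSMRecord], path: str) -> None:
    records_to_frame(psms).to_csv(path, sep="\t", index=False)


def compute_qvalues(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Assign target-decoy q-values; returns new records in the input order.

    At every score threshold s, FDR(s) = #{decoys >= s} / max(1,
    #{targets >= s}), with decoys counted before targets at tied scores
    (conservative).  A target's q-value is the minimum FDR over all
    thresholds that admit it; q is therefore nonincreasing in score.
    Decoys inherit the q-value of the nearest lower-or-equal-scoring
    target (1.0 if none).
    """
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs")
    order = sorted(
        range(len(psms)), key=lambda i: (-psms[i].score, not psms[i].is_decoy)
    )
    n = len(order)
    fdr = [0.0] * n
    d = t = 0
    for rank, idx in enumerate(order):
        if psms[idx].is_decoy:
            d += 1
        else:
            t += 1
        fdr[rank] = min(1.0, d / max(1, t))
    # running minimum from the permissive end gives the q-value
    q = [0.0] * n
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, fdr[rank])
        q[rank] = running
    out = [replace(p) for p in psms]
    # decoys take the q of the next target at equal-or-lower score
    next_target_q = [1.0] * n
    pending = 1.0
    for rank in range(n - 1, -1, -1):
        if not psms[order[rank]].is_decoy:
            pending = q[rank]
        next_target_q[rank] = pending
    for rank, idx in enumerate(order):
        out[idx].q_value = q[rank] if not psms[idx].is_decoy else next_target_q[rank]
    return out


def filter_fdr(psms: Sequence[PSMRecord], threshold: float = 0.01) -> list[PSMRecord]:
    """Keep target PSMs with q-value <= threshold; decoys are removed."""
    if not 0 < threshold <= 1:
        raise ValueError("FDR threshold must be in (0, 1]")
    for p in psms:
        if not p.is_decoy and p.q_value is None:
            raise ValueError("q-values must be computed before FDR filtering")
    return [p for p in psms if not p.is_decoy and p.q_value <= threshold]


def collapse_to_unique(psms: Sequence[PSMRecord]) -> list[UniquePeptide]:
    """Collapse filtered PSMs to unique peptide identity tuples.

    Identity is (base_sequence, sub_positions, sub_from, sub_to): the
    wild-type and substituted forms of the same sequence, or two different
    substituted positions, are distinct unique peptides.
    """
    groups: dict[tuple, list[PSMRecord]] = {}
    for p in psms:
        groups.setdefault(p.identity, []).append(p)
    uniques = [
        UniquePeptide(
            base_sequence=key[0],
            sub_positions=key[1],
            sub_from=key[2],
            sub_to=key[3],
            psm_count=len(members),
            best_q=min(m.q_value if m.q_value is not None else 1.0 for m in members),
        )
        for key, members in groups.items()
    ]
    uniques.sort(key=lambda u: u.identity)
    return uniques
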