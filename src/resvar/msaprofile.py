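"""Alignment profiles: mapping mutations onto homologue columns.

The central question for each clinical mutation token (say T790M) is whether
the mutant residue is already realised somewhere in evolution — i.e. whether
methionine appears, in any homologous sequence, at the alignment column that
corresponds to reference position 790.  This module ingests an aligned
protein family with one designated reference row, builds the position→column
map and per-column residue counts, and answers that question per mutation
("occurred" vs "novel"), per domain (possible vs observed SNV spectra), and
per labelled mutation set (occurred/novel contingency tables).

Conventions, fixed package-wide:

* coordinates are 1-based and inclusive, in full-protein numbering, with
  ``reference_offset`` bridging to the domain-local alignment;
* frequencies use **all** alignment rows (reference included) as the
  denominator; rows showing a gap or an ambiguity code at a column stay in
  the denominator but can never match a mutant residue;
* printed percentages are truncated toward zero (87/276 → "31%"), with one
  decimal place below 1%.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codonspace import AMINO_ACIDS, CodingDomain, missense_neighbors, translate_codon
from .errors import CoordinateError, InputError, ReferenceMismatchError

GAP = "-"
#: one-letter codes that denote an unknown or non-standard residue; they are
#: counted in denominators but never match a mutant residue
AMBIGUITY_CODES = frozenset("XBZJUO")


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single missense mutation in full-protein 1-based coordinates."""

    wt: str
    position: int
    mut: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", self.wt.upper())
        object.__setattr__(self, "mut", self.mut.upper())
        if self.wt == self.mut:
            raise InputError(f"{self.wt}{self.position}{self.mut}: wild type equals mutant")
        if self.position < 1:
            raise InputError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt, self.mut):
            if aa not in AMINO_ACIDS:
                raise InputError(f"invalid amino-acid letter {aa!r} in mutation token")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass(frozen=True)
class OccurrenceRecord:
    """Whether (and how often) a mutant residue is seen among homologues."""

    mutation: PointMutation
    observed: bool
    count: int
    n_rows: int
    frequency: float
    reported_percent: str


@dataclass(frozen=True)
class SNVSpectrum:
    """Possible vs observed missense-SNV counts for a coding domain.

    ``detail`` maps each protein position to its reachable amino-acid set
    and the subset of it seen in at least one alignment row.
    """

    domain_id: str
    possible: int
    observed: int
    detail: Mapping[int, tuple[frozenset[str], frozenset[str]]]


@dataclass
class MutationClassTable:
    """Occurred/novel counts per (gene, mutation class)."""

    counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def add(self, gene: str, mutation_class: str, observed: bool) -> None:
        row = self.counts.setdefault(
            (gene, mutation_class), {"occurred": 0, "novel": 0, "total": 0}
        )
        row["occurred" if observed else "novel"] += 1
        row["total"] += 1

    def occurred_and_total(self, mutation_class: str | None = None) -> tuple[int, int]:
        """Pooled (occurred, total) over rows, optionally one class only."""
        occurred = total = 0
        for (_, cls), row in self.counts.items():
            if mutation_class is None or cls == mutation_class:
                occurred += row["occurred"]
                total += row["total"]
        return occurred, total

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"gene": g, "class": c, **row} for (g, c), row in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            records, columns=["gene", "class", "occurred", "novel", "total"]
        )


@dataclass(frozen=True)
class AlignmentProfile:
    """An MSA indexed by reference-protein coordinates.

    ``column_map`` sends each reference protein position to the 1-based
    alignment column holding that residue; reference gap columns are not
    mapped.  ``column_counts`` holds, per column, the residue→count table
    over all rows (gaps and ambiguity codes included).
    """

    rows: tuple[tuple[str, str], ...]
    reference_id: str
    reference_offset: int
    column_map: Mapping[int, int]
    column_counts: tuple[Mapping[str, int], ...]
    n_rows: int
    column_confidence: Mapping[int, float] | None = None

    @property
    def reference_row(self) -> str:
        for rid, seq in self.rows:
            if rid == self.reference_id:
                return seq
        raise InputError(f"reference id {self.reference_id!r} missing")  # pragma: no cover

    def column_for(self, position: int) -> int:
        try:
            return self.column_map[position]
        except KeyError:
            mapped = sorted(self.column_map)
            span = f"{mapped[0]}-{mapped[-1]}" if mapped else "(empty)"
            raise CoordinateError(
                f"position {position} is not mapped to any alignment column "
                f"(mapped reference range: {span})"
            ) from None

    def reference_residue(self, position: int) -> str:
        return self.reference_row[self.column_for(position) - 1].upper()

    def residue_count(self, position: int, residue: str) -> int:
        """Rows carrying *residue* at the column mapped to *position*."""
        counts = self.column_counts[self.column_for(position) - 1]
        return counts.get(residue.upper(), 0)


def build_profile(
    rows: Sequence[tuple[str, str]],
    reference_id: str,
    reference_offset: int = 1,
    column_confidence: Mapping[int, float] | None = None,
) -> AlignmentProfile:
    """Index an aligned family by its reference row.

    *rows* are (id, aligned sequence) pairs; all sequences must share one
    length.  *reference_offset* is the full-protein position of the first
    (non-gap) reference residue, so that a domain alignment can be addressed
    in full-protein coordinates.
    """
    if not rows:
        raise InputError("alignment has no rows")
    width = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != width:
            raise InputError(
                f"ragged alignment: row {rid!r} has length {len(seq)}, expected {width}"
            )
    by_id = {rid: seq for rid, seq in rows}
    if reference_id not in by_id:
        raise InputError(f"reference id {reference_id!r} not found among alignment rows")
    reference = by_id[reference_id]
    if not reference.strip(GAP):
        raise InputError(f"reference row {reference_id!r} is empty")

    column_map: dict[int, int] = {}
    position = reference_offset
    for col, residue in enumerate(reference, start=1):
        if residue != GAP:
            column_map[position] = col
            position += 1

    column_counts = tuple(
        Counter(seq[col].upper() for _, seq in rows) for col in range(width)
    )
    return AlignmentProfile(
        rows=tuple((rid, seq) for rid, seq in rows),
        reference_id=reference_id,
        reference_offset=reference_offset,
        column_map=column_map,
        column_counts=column_counts,
        n_rows=len(rows),
        column_confidence=dict(column_confidence) if column_confidence else None,
    )


def report_percent(count: int, total: int) -> str:
    """Format a count/total as the truncated percentage string convention.

    Whole percents (truncated toward zero) at or above 1%; one truncated
    decimal place below 1%.
    """
    if total < 1:
        raise InputError("report_percent: total must be >= 1")
    if not 0 <= count <= total:
        raise InputError(f"report_percent: count {count} outside [0, {total}]")
    pct = 100.0 * count / total
    if pct >= 1.0:
        return f"{math.floor(pct)}%"
    return f"{math.floor(pct * 10) / 10:.1f}%"


def mutation_occurrence(
    profile: AlignmentProfile, mutation: PointMutation
) -> OccurrenceRecord:
    """Count alignment rows realising *mutation*'s mutant residue.

    The reference residue at the mapped column must equal the mutation's
    stated wild type.  The denominator is all rows, reference included.
    """
    found = profile.reference_residue(mutation.position)
    if found != mutation.wt:
        raise ReferenceMismatchError(
            f"{mutation}: reference carries {found!r} at position "
            f"{mutation.position}, expected {mutation.wt!r}"
        )
    count = profile.residue_count(mutation.position, mutation.mut)
    return OccurrenceRecord(
        mutation=mutation,
        observed=count >= 1,
        count=count,
        n_rows=profile.n_rows,
        frequency=count / profile.n_rows,
        reported_percent=report_percent(count, profile.n_rows),
    )


def observed_spectrum(
    profile: AlignmentProfile,
    domain: CodingDomain,
    min_confidence: float | None = None,
) -> SNVSpectrum:
    """Compare the possible missense-SNV space of *domain* with the MSA.

    Per position, the reachable set comes from the codon's missense
    neighbourhood and the observed subset is every reachable residue present
    in at least one alignment row at the mapped column.  With
    *min_confidence* set and a confidence track available, columns scoring
    below the threshold are dropped from both totals.
    """
    unmapped = [p for p in domain.positions if p not in profile.column_map]
    if unmapped:
        raise CoordinateError(
            f"{domain.gene_id}: {len(unmapped)} domain positions not mapped "
            f"to alignment columns: {unmapped}"
        )
    mismatches = []
    for position in domain.positions:
        wt = translate_codon(domain.codon_at(position))
        if profile.reference_residue(position) != wt:
            mismatches.append(
                f"{position} (CDS {wt}, alignment {profile.reference_residue(position)})"
            )
    if mismatches:
        raise ReferenceMismatchError(
            f"{domain.gene_id}: CDS translation disagrees with the reference "
            f"row at: {', '.join(mismatches)}"
        )

    detail: dict[int, tuple[frozenset[str], frozenset[str]]] = {}
    possible = observed = 0
    for position in domain.positions:
        column = profile.column_for(position)
        if (
            min_confidence is not None
            and profile.column_confidence is not None
            and profile.column_confidence.get(column, 1.0) < min_confidence
        ):
            continue
        reachable = missense_neighbors(domain.codon_at(position)).reachable
        counts = profile.column_counts[column - 1]
        seen = frozenset(aa for aa in reachable if counts.get(aa, 0) >= 1)
        detail[position] = (reachable, seen)
        possible += len(reachable)
        observed += len(seen)
    return SNVSpectrum(
        domain_id=domain.gene_id, possible=possible, observed=observed, detail=detail
    )


def classify_mutations(
    profile: AlignmentProfile,
    mutations: Iterable[PointMutation],
    labels: Mapping[PointMutation, tuple[str, str]],
) -> MutationClassTable:
    """Tabulate occurred/novel counts per (gene, mutation class)."""
    table = MutationClassTable()
    errors = []
    for mutation in mutations:
        try:
            gene, cls = labels[mutation]
        except KeyError:
            errors.append(f"{mutation}: no (gene, class) label supplied")
            continue
        try:
            record = mutation_occurrence(profile, mutation)
        except (CoordinateError, ReferenceMismatchError) as exc:
            errors.append(str(exc))
            continue
        table.add(gene, cls, record.observed)
    if errors:
        raise InputError("classify_mutations: " + "; ".join(errors))
    return table
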