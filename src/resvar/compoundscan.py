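"""Ordered co-occurrence of mutation pairs across alignment rows.

Compound mutations are two resistance mutations carried by the same tumour
clone.  Their evolutionary plausibility is probed by asking, for an ordered
pair (A, B): among the homologous sequences that realise A's mutant residue,
what fraction also realises B's?  Because the two marginal frequencies
differ, the resulting matrix of conditional frequencies is not symmetric —
P(B|A) can be 56% while P(A|B) is 8% — even though the underlying joint
counts are.

Gap and ambiguity characters follow the package convention: a row counts in
a denominator whenever it carries the conditioning mutant residue, but a gap
or ambiguity code at the second column never contributes to a joint count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

from .errors import InputError, ResvarError
from .msaprofile import AlignmentProfile, PointMutation, mutation_occurrence, report_percent

#: colour-bin edges in percent; the shared edge 19 goes to the higher bin
_BINS = ((10.0, "white"), (19.0, "yellow"), (50.0, "orange"))


def color_bin(conditional: float | None) -> str:
    """Map a conditional frequency to its display bin.

    Bins in percent: <10 white, [10, 19) yellow, [19, 50] orange, >50 red;
    an undefined conditional (zero denominator) is labelled "undefined".
    """
    if conditional is None:
        return "undefined"
    pct = 100.0 * conditional
    if pct < 10.0:
        return "white"
    if pct < 19.0:
        return "yellow"
    if pct <= 50.0:
        return "orange"
    return "red"


@dataclass(frozen=True)
class ConditionalCooccurrence:
    """P(second's mutant residue | first's mutant residue) over MSA rows.

    ``conditional`` is ``None`` (undefined) when no row carries the
    conditioning residue.
    """

    first: PointMutation
    second: PointMutation
    denominator: int
    joint: int
    conditional: float | None

    @property
    def bin_label(self) -> str:
        return color_bin(self.conditional)


@dataclass(frozen=True)
class CompoundMatrix:
    """All ordered-pair conditional frequencies over a mutation panel."""

    mutations: tuple[PointMutation, ...]
    cells: dict[tuple[PointMutation, PointMutation], ConditionalCooccurrence]
    n_rows: int

    def cell(
        self, first: PointMutation, second: PointMutation
    ) -> ConditionalCooccurrence:
        return self.cells[(first, second)]


def _row_indices_with(profile: AlignmentProfile, mutation: PointMutation) -> set[int]:
    column = profile.column_for(mutation.position) - 1
    residue = mutation.mut
    return {
        i for i, (_, seq) in enumerate(profile.rows) if seq[column].upper() == residue
    }


def conditional_cooccurrence(
    profile: AlignmentProfile, first: PointMutation, second: PointMutation
) -> ConditionalCooccurrence:
    """Conditional frequency of *second*'s mutant residue given *first*'s."""
    if first.position == second.position:
        raise InputError(
            f"co-occurrence requires distinct positions, got {first} and {second}"
        )
    # validate coordinates and wild types the same way single counts do
    mutation_occurrence(profile, first)
    mutation_occurrence(profile, second)
    carriers = _row_indices_with(profile, first)
    joint = len(carriers & _row_indices_with(profile, second))
    denominator = len(carriers)
    conditional = joint / denominator if denominator else None
    return ConditionalCooccurrence(
        first=first,
        second=second,
        denominator=denominator,
        joint=joint,
        conditional=conditional,
    )


def _self_cell(
    profile: AlignmentProfile, mutation: PointMutation
) -> ConditionalCooccurrence:
    count = mutation_occurrence(profile, mutation).count
    return ConditionalCooccurrence(
        first=mutation,
        second=mutation,
        denominator=count,
        joint=count,
        conditional=1.0 if count else None,
    )


def compound_matrix(
    profile: AlignmentProfile, mutations: Sequence[PointMutation]
) -> CompoundMatrix:
    """Compute every ordered pair over a panel of >= 2 mutations.

    Per-pair validation errors are collected and re-raised together after
    the remaining pairs have been computed.
    """
    if len(mutations) < 2:
        raise InputError("compound_matrix needs at least 2 mutations")
    cells: dict[tuple[PointMutation, PointMutation], ConditionalCooccurrence] = {}
    errors: list[str] = []
    for first in mutations:
        for second in mutations:
            try:
                if first == second:
                    cells[(first, second)] = _self_cell(profile, first)
                else:
                    cells[(first, second)] = conditional_cooccurrence(
                        profile, first, second
                    )
            except ResvarError as exc:
                errors.append(f"({first}, {second}): {exc}")
    if errors:
        raise InputError("compound_matrix: " + "; ".join(errors))
    return CompoundMatrix(
        mutations=tuple(mutations), cells=cells, n_rows=profile.n_rows
    )


def find_novel_compounds(
    matrix: CompoundMatrix,
    candidate_pairs: Iterable[tuple[PointMutation, PointMutation]],
) -> list[tuple[PointMutation, PointMutation]]:
    """Candidate pairs never realised jointly although each member occurs.

    A pair is novel when its joint count is zero in both orders while both
    single mutations are observed in at least one row.
    """
    novel = []
    for a, b in candidate_pairs:
        forward = matrix.cell(a, b)
        backward = matrix.cell(b, a)
        singles_present = forward.denominator >= 1 and backward.denominator >= 1
        if singles_present and forward.joint == 0 and backward.joint == 0:
            novel.append((a, b))
    return novel


def find_obligate_pairs(
    matrix: CompoundMatrix, bidirectional: bool = True
) -> list[tuple[PointMutation, PointMutation]]:
    """Unordered pairs whose mutant residues are always observed together.

    By default both conditionals must equal 1 with a non-empty joint (the
    strictest reading of "always observed together"); with
    ``bidirectional=False`` a single direction at 1 suffices.
    """
    obligate = []
    muts = matrix.mutations
    for i, a in enumerate(muts):
        for b in muts[i + 1 :]:
            forward = matrix.cell(a, b)
            backward = matrix.cell(b, a)
            if forward.joint < 1:
                continue
            cond = (
                forward.conditional == 1.0 and backward.conditional == 1.0
                if bidirectional
                else forward.conditional == 1.0 or backward.conditional == 1.0
            )
            if cond:
                obligate.append((a, b))
    return obligate


def iter_all_pairs(
    profile: AlignmentProfile, mutations: Sequence[PointMutation]
) -> Iterator[ConditionalCooccurrence]:
    """Stream all ordered pairs row-major over the input order.

    Used for full-panel exports (all combinations of a resistance panel)
    where holding every cell in memory is unnecessary.
    """
    for first in mutations:
        for second in mutations:
            if first == second:
                yield _self_cell(profile, first)
            else:
                yield conditional_cooccurrence(profile, first, second)


def write_pairs_tsv(
    records: Iterable[ConditionalCooccurrence], handle: IO[str]
) -> None:
    """Write co-occurrence records as headered TSV (one row per ordered pair)."""
    handle.write(
        "first\tsecond\tjoint\tdenominator\tconditional\treported_percent\tbin\n"
    )
    for rec in records:
        if rec.conditional is None:
            conditional = pct = "NA"
        else:
            conditional = f"{rec.conditional:.6g}"
            pct = report_percent(rec.joint, rec.denominator)
        handle.write(
            f"{rec.first}\t{rec.second}\t{rec.joint}\t{rec.denominator}\t"
            f"{conditional}\t{pct}\t{rec.bin_label}\n"
        )
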