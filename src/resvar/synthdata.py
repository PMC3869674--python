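"""Synthetic homolog families with planted, bookkept ground truth.

The alignment-based analyses in this package treat MSA rows as exchangeable
observations of per-column residue distributions, independent across columns
except for explicitly modelled couplings.  The generator emulates exactly
that structure: a gapless reference row, background column variability at a
controllable rate, planted single-site residue supports with target
frequencies, and planted pairwise couplings of stated conditional strength.
What it deliberately does not emulate is phylogenetic correlation between
rows — real homolog sets share ancestry, synthetic rows do not.

Ground truth is counted directly from the emitted residue matrix (not from
the sampling intentions), so tests can compare pipeline output against
realised counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .codonspace import AMINO_ACIDS, CodingDomain, STOP, _CODE
from .errors import InputError

_SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODE.items()):
    if _aa != STOP:
        _SYNONYMOUS.setdefault(_aa, ())
        _SYNONYMOUS[_aa] += (_codon,)


@dataclass(frozen=True)
class Coupling:
    """A planted pairwise dependency between two alignment columns.

    Among rows carrying ``res_i`` at ``pos_i``, a fraction ``conditional``
    also carries ``res_j`` at ``pos_j`` (and the rest carry the reference
    residue there), so the recovered conditional co-occurrence targets
    ``conditional`` directly.
    """

    pos_i: int
    res_i: str
    pos_j: int
    res_j: str
    conditional: float


@dataclass(frozen=True)
class SyntheticMsaSpec:
    """Recipe for one synthetic family.

    Defaults describe a mid-sized curated homolog set: 300 aligned
    sequences with 5% background column variability and no gaps.
    """

    reference: str
    n_sequences: int = 300
    reference_id: str = "reference"
    reference_offset: int = 1
    background_rate: float = 0.05
    supports: Mapping[int, tuple[str, float]] = field(default_factory=dict)
    couplings: tuple[Coupling, ...] = ()
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference or set(self.reference) - AMINO_ACIDS:
            raise InputError("reference must be a non-empty 20-letter protein string")
        if self.n_sequences < 2:
            raise InputError("need at least a reference and one other row")
        for rate, name in (
            (self.background_rate, "background_rate"),
            (self.gap_rate, "gap_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {rate}")
        span = self.positions
        for pos, (res, freq) in self.supports.items():
            if pos not in span:
                raise InputError(f"planted support position {pos} outside reference")
            if res not in AMINO_ACIDS or not 0.0 <= freq <= 1.0:
                raise InputError(f"invalid planted support at {pos}: ({res}, {freq})")
            if res == self._reference_residue(pos):
                raise InputError(
                    f"planted support at {pos} equals the reference residue {res}"
                )
        for c in self.couplings:
            if c.pos_i not in span or c.pos_j not in span:
                raise InputError(f"coupling {c} outside reference span")
            if c.pos_i == c.pos_j:
                raise InputError(f"coupling {c} uses one position twice")
            if not 0.0 <= c.conditional <= 1.0:
                raise InputError(f"coupling fraction must lie in [0, 1]: {c}")
            support = self.supports.get(c.pos_i)
            if support is None or support[0] != c.res_i:
                raise InputError(
                    f"coupling {c} requires a planted support ({c.res_i}) at "
                    f"position {c.pos_i}"
                )
            if c.res_j == self._reference_residue(c.pos_j):
                raise InputError(
                    f"coupling target at {c.pos_j} equals the reference residue"
                )

    @property
    def positions(self) -> range:
        return range(
            self.reference_offset, self.reference_offset + len(self.reference)
        )

    def _reference_residue(self, position: int) -> str:
        return self.reference[position - self.reference_offset]

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticMsaSpec":
        """Build a spec from a plain mapping (YAML-friendly)."""
        supports = {
            int(pos): (str(res), float(freq))
            for pos, (res, freq) in dict(data.get("supports", {})).items()
        }
        couplings = tuple(
            Coupling(
                pos_i=int(c["pos_i"]),
                res_i=str(c["res_i"]),
                pos_j=int(c["pos_j"]),
                res_j=str(c["res_j"]),
                conditional=float(c["conditional"]),
            )
            for c in data.get("couplings", ())
        )
        kwargs = {
            key: data[key]
            for key in (
                "reference",
                "n_sequences",
                "reference_id",
                "reference_offset",
                "background_rate",
                "gap_rate",
                "seed",
            )
            if key in data
        }
        return cls(supports=supports, couplings=couplings, **kwargs)


@dataclass(frozen=True)
class SingleTruth:
    position: int
    residue: str
    count: int
    n_rows: int

    @property
    def frequency(self) -> float:
        return self.count / self.n_rows


@dataclass(frozen=True)
class PairTruth:
    pos_i: int
    res_i: str
    pos_j: int
    res_j: str
    joint: int
    denominator: int

    @property
    def conditional(self) -> float | None:
        return self.joint / self.denominator if self.denominator else None


@dataclass(frozen=True)
class GroundTruth:
    """Realised counts, tallied from the emitted matrix itself."""

    singles: tuple[SingleTruth, ...]
    pairs: tuple[PairTruth, ...]
    n_rows: int


def _planted_residues(spec: SyntheticMsaSpec, position: int) -> set[str]:
    planted = set()
    if position in spec.supports:
        planted.add(spec.supports[position][0])
    for c in spec.couplings:
        if c.pos_j == position:
            planted.add(c.res_j)
    return planted


_AA_SORTED = sorted(AMINO_ACIDS)


def simulate_msa(
    spec: SyntheticMsaSpec,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Draw one synthetic family and tally its realised ground truth.

    Rows are drawn column-independently: each cell carries the reference
    residue, a planted support residue at its target frequency, or a
    background substitution at ``background_rate`` spread uniformly over the
    non-reference residues (excluding planted residues, so planted counts
    are not contaminated).  Couplings then rewrite the target column within
    carrier rows.  Gaps, if enabled, are injected last; the reference row is
    emitted unmutated and ungapped.
    """
    rng = np.random.default_rng(spec.seed)
    length = len(spec.reference)
    n = spec.n_sequences
    matrix = np.empty((n, length), dtype="<U1")
    matrix[0] = list(spec.reference)

    for col, position in enumerate(spec.positions):
        ref_res = spec.reference[col]
        planted = _planted_residues(spec, position)
        alternatives = [a for a in _AA_SORTED if a != ref_res and a not in planted]
        column = np.full(n - 1, ref_res, dtype="<U1")
        if spec.background_rate > 0 and alternatives:
            hit = rng.random(n - 1) < spec.background_rate
            column[hit] = rng.choice(alternatives, size=int(hit.sum()))
        if position in spec.supports:
            res, freq = spec.supports[position]
            column[rng.random(n - 1) < freq] = res
        matrix[1:, col] = column

    for c in spec.couplings:
        col_i = c.pos_i - spec.reference_offset
        col_j = c.pos_j - spec.reference_offset
        carriers = np.flatnonzero(matrix[1:, col_i] == c.res_i) + 1
        coupled = rng.random(carriers.size) < c.conditional
        matrix[carriers[coupled], col_j] = c.res_j
        matrix[carriers[~coupled], col_j] = spec.reference[col_j]

    if spec.gap_rate > 0:
        gaps = rng.random((n - 1, length)) < spec.gap_rate
        matrix[1:][gaps] = "-"

    singles = tuple(
        SingleTruth(
            position=pos,
            residue=res,
            count=int((matrix[:, pos - spec.reference_offset] == res).sum()),
            n_rows=n,
        )
        for pos, (res, _) in sorted(spec.supports.items())
    )
    pairs = []
    for c in spec.couplings:
        col_i = c.pos_i - spec.reference_offset
        col_j = c.pos_j - spec.reference_offset
        has_i = matrix[:, col_i] == c.res_i
        has_j = matrix[:, col_j] == c.res_j
        pairs.append(
            PairTruth(
                pos_i=c.pos_i,
                res_i=c.res_i,
                pos_j=c.pos_j,
                res_j=c.res_j,
                joint=int((has_i & has_j).sum()),
                denominator=int(has_i.sum()),
            )
        )
    truth = GroundTruth(singles=singles, pairs=tuple(pairs), n_rows=n)

    ids = [spec.reference_id] + [f"seq{i:04d}" for i in range(1, n)]
    rows = [(rid, "".join(matrix[i])) for i, rid in enumerate(ids)]
    return rows, truth


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Persist realised counts so tests never re-derive generator internals."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(
            "kind\tpos_i\tres_i\tpos_j\tres_j\tcount\tdenominator\tn_rows\n"
        )
        for s in truth.singles:
            handle.write(
                f"single\t{s.position}\t{s.residue}\t.\t.\t{s.count}\t"
                f"{s.n_rows}\t{s.n_rows}\n"
            )
        for p in truth.pairs:
            handle.write(
                f"pair\t{p.pos_i}\t{p.res_i}\t{p.pos_j}\t{p.res_j}\t"
                f"{p.joint}\t{p.denominator}\t{truth.n_rows}\n"
            )


def simulate_to_files(
    spec: SyntheticMsaSpec, prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.fasta`` and ``<prefix>.truth.tsv``; same seed, same bytes."""
    prefix = Path(prefix)
    rows, truth = simulate_msa(spec)
    fasta = prefix.with_suffix(".fasta")
    with open(fasta, "w", encoding="utf-8", newline="\n") as handle:
        for rid, seq in rows:
            handle.write(f">{rid}\n{seq}\n")
    truth_path = prefix.with_suffix(".truth.tsv")
    write_truth_tsv(truth, truth_path)
    return fasta, truth_path


def simulate_cds(
    protein: str,
    seed: int,
    gene_id: str = "synthetic",
    protein_start: int = 1,
) -> CodingDomain:
    """Pick one synonymous codon per residue, uniformly under *seed*.

    The translation of the result round-trips to *protein* exactly.
    """
    invalid = set(protein.upper()) - AMINO_ACIDS
    if invalid:
        raise InputError(f"invalid residues in protein string: {sorted(invalid)}")
    rng = np.random.default_rng(seed)
    codons = tuple(
        _SYNONYMOUS[aa][rng.integers(len(_SYNONYMOUS[aa]))] for aa in protein.upper()
    )
    return CodingDomain(
        gene_id=gene_id,
        codons=codons,
        protein_start=protein_start,
        protein_end=protein_start + len(codons) - 1,
    )
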