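"""Genetic-code algebra over single-nucleotide variants (SNVs).

A missense mutation observed in a tumour is, almost always, one base change
in one codon.  The set of amino acids reachable from a given codon by a
single substitution is therefore the relevant "mutational neighbourhood" of
a residue: at most nine nucleotide events, collapsing to at most nine
distinct amino acids once synonymous changes and stop codons are removed.
This module enumerates that neighbourhood and aggregates it over a coding
domain, which yields the size of the *possible* missense-SNV space that the
alignment-based modules compare against what evolution actually realised.

Only the standard genetic code is supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data import CodonTable

from .errors import InputError

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP = "*"
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODE[_stop] = STOP

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in _CODE.items() if aa != STOP)
)


def normalize_codon(codon: "Codon | str") -> str:
    """Return the canonical uppercase DNA form of *codon*.

    Lowercase letters are uppercased and RNA uracil is mapped to thymine.
    Raises :class:`InputError` naming the offending base otherwise.
    """
    if isinstance(codon, Codon):
        return codon.bases
    text = str(codon).upper().replace("U", "T")
    if len(text) != 3:
        raise InputError(f"codon must have exactly 3 bases, got {text!r}")
    for base in text:
        if base not in BASES:
            raise InputError(f"invalid base {base!r} in codon {text!r}")
    return text


@dataclass(frozen=True)
class Codon:
    """An ordered triple of DNA bases in canonical uppercase form."""

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize_codon(self.bases))

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class MissenseNeighborhood:
    """Amino acids reachable from one codon by a single base substitution.

    ``reachable`` never contains the wild-type residue (those events are
    synonymous) nor the stop marker (nonsense, not missense), so its size
    is at most 9 and counts distinct residues *at the protein level*.
    """

    source: str
    wt_aa: str
    reachable: frozenset[str]

    def __post_init__(self) -> None:
        assert self.wt_aa not in self.reachable
        assert STOP not in self.reachable
        assert len(self.reachable) <= 9


@dataclass(frozen=True)
class CodingDomain:
    """A run of reference codons with full-protein 1-based coordinates.

    ``protein_start``/``protein_end`` are inclusive, so the codon for
    position ``p`` is ``codons[p - protein_start]``.
    """

    gene_id: str
    codons: tuple[str, ...]
    protein_start: int
    protein_end: int

    def __post_init__(self) -> None:
        codons = tuple(normalize_codon(c) for c in self.codons)
        object.__setattr__(self, "codons", codons)
        n = self.protein_end - self.protein_start + 1
        if n != len(codons):
            raise InputError(
                f"{self.gene_id}: coordinate span {self.protein_start}-"
                f"{self.protein_end} covers {n} residues but {len(codons)} "
                "codons were supplied"
            )
        for i, codon in enumerate(codons):
            if translate_codon(codon) == STOP:
                raise InputError(
                    f"{self.gene_id}: internal stop codon {codon} at "
                    f"protein position {self.protein_start + i}"
                )

    @property
    def positions(self) -> range:
        return range(self.protein_start, self.protein_end + 1)

    def codon_at(self, position: int) -> str:
        if position not in self.positions:
            raise InputError(
                f"{self.gene_id}: position {position} outside domain "
                f"{self.protein_start}-{self.protein_end}"
            )
        return self.codons[position - self.protein_start]

    def translation(self) -> str:
        return "".join(translate_codon(c) for c in self.codons)


def translate_codon(codon: Codon | str) -> str:
    """Standard genetic code translation; stop codons return ``"*"``."""
    return _CODE[normalize_codon(codon)]


def missense_neighbors(codon: Codon | str) -> MissenseNeighborhood:
    """Enumerate amino acids reachable from *codon* by exactly one SNV.

    All nine single-base substitutions are generated; outcomes that are
    synonymous or that create a stop codon are discarded, and distinctness
    is taken at the amino-acid level.
    """
    text = normalize_codon(codon)
    wt = translate_codon(text)
    if wt == STOP:
        raise InputError(f"cannot enumerate missense neighbours of stop codon {text}")
    reachable = set()
    for i in range(3):
        for base in BASES:
            if base == text[i]:
                continue
            aa = translate_codon(text[:i] + base + text[i + 1 :])
            if aa != STOP and aa != wt:
                reachable.add(aa)
    return MissenseNeighborhood(source=text, wt_aa=wt, reachable=frozenset(reachable))


def count_possible_missense(domain: CodingDomain) -> int:
    """Total number of distinct missense SNVs possible across *domain*.

    The sum over codons of the neighbourhood size, i.e. the size of the SNV
    space against which observed variation is compared.
    """
    if not domain.codons:
        logger.warning("count_possible_missense: empty domain %s", domain.gene_id)
        return 0
    return sum(len(missense_neighbors(c).reachable) for c in domain.codons)


def snv_accessible(codon: Codon | str, mutant: str) -> bool:
    """True iff *mutant* is reachable from *codon* by one base substitution."""
    mutant = mutant.upper()
    if mutant not in AMINO_ACIDS:
        raise InputError(f"invalid amino-acid letter {mutant!r}")
    hood = missense_neighbors(codon)
    if mutant == hood.wt_aa:
        raise InputError(
            f"{mutant} is the wild-type translation of {hood.source}; not a mutation"
        )
    return mutant in hood.reachable
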