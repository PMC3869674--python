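"""Biochemical and conservation scoring of missense mutations.

Three complementary views of how "radical" a mutation is:

* the Grantham distance, an empirical biochemical metric built from residue
  composition, polarity and molecular volume (mean over all residue pairs
  ~100; isoleucine→leucine scores 5, cysteine→phenylalanine 205);
* position-specific scoring-matrix (PSSM) log2 odds from a conserved-domain
  alignment, comparing how probable the wild-type and mutant residues are at
  that position of the domain family;
* per-residue conservation scores of the ConSurf kind (lower/negative =
  more conserved), ingested from file — computing them is upstream of this
  package.

The canonical integer Grantham table is embedded as the source of truth;
recomputation from the published physico-chemical properties serves as a
cross-validation path only, since the published table is known to deviate
from strict recomputation by a unit for a few pairs (and by ~10 for
Asp–Trp).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CoordinateError, InputError
from .msaprofile import PointMutation

_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# canonical published integer distances, upper triangle in _GRANTHAM_ORDER
_GRANTHAM_TRIANGLE = """
110 145 74 58 99 124 56 142 155 144 112 89 68 46 121 65 80 135 177
102 103 71 112 96 125 97 97 77 180 29 43 86 26 96 54 91 101
98 92 96 32 138 5 22 36 198 99 113 153 107 172 138 15 61
38 27 68 42 95 114 110 169 77 76 91 103 108 93 87 147
58 69 59 89 103 92 149 47 42 65 78 85 65 81 128
64 60 94 113 112 195 86 91 111 106 126 107 84 148
109 29 50 55 192 84 96 133 97 152 121 21 88
135 153 147 159 98 87 80 127 94 98 127 184
21 33 198 94 109 149 102 168 134 10 61
22 205 100 116 158 102 177 140 28 40
194 83 99 143 85 160 122 36 37
174 154 139 202 154 170 196 215
24 68 32 81 40 87 115
46 53 61 29 101 130
94 23 42 142 174
101 56 95 110
45 160 181
126 152
67
"""

#: residue (composition, polarity, volume) triples from the original
#: empirical derivation
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}


def _build_table() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    rows = [r.split() for r in _GRANTHAM_TRIANGLE.strip().splitlines()]
    for i, row in enumerate(rows):
        a = _GRANTHAM_ORDER[i]
        for k, value in enumerate(row):
            b = _GRANTHAM_ORDER[i + 1 + k]
            table[(a, b)] = table[(b, a)] = int(value)
    for aa in _GRANTHAM_ORDER:
        table[(aa, aa)] = 0
    return table


GRANTHAM_TABLE: dict[tuple[str, str], int] = _build_table()


def _mean_raw_distance(
    properties: Mapping[str, tuple[float, float, float]],
    alpha: float,
    beta: float,
    gamma: float,
) -> float:
    aas = list(properties)
    total = n = 0
    for i, a in enumerate(aas):
        for b in aas[i + 1 :]:
            ca, pa, va = properties[a]
            cb, pb, vb = properties[b]
            total += math.sqrt(
                alpha * (ca - cb) ** 2 + beta * (pa - pb) ** 2 + gamma * (va - vb) ** 2
            )
            n += 1
    return total / n


@dataclass(frozen=True)
class GranthamModel:
    """Physico-chemical model behind the distance: D = rho * sqrt(
    alpha*(dc)^2 + beta*(dp)^2 + gamma*(dv)^2 ).

    ``rho`` defaults to the value that scales the mean over the 190 residue
    pairs to exactly 100, which reproduces the canonical anchors (I/L = 5,
    C/F = 205, F/H = 100) on rounding.
    """

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float | None = None

    def scale(self) -> float:
        if self.rho is not None:
            return self.rho
        return 100.0 / _mean_raw_distance(
            self.properties, self.alpha, self.beta, self.gamma
        )


def _check_residue(aa: str) -> str:
    aa = aa.upper()
    if aa not in GRANTHAM_PROPERTIES:
        raise InputError(f"non-canonical residue {aa!r} has no Grantham properties")
    return aa


def grantham_distance(a: str, b: str) -> int:
    """Canonical integer Grantham distance between two residues."""
    return GRANTHAM_TABLE[(_check_residue(a), _check_residue(b))]


def grantham_from_properties(
    a: str, b: str, model: GranthamModel | None = None
) -> float:
    """Recompute the distance from composition/polarity/volume properties.

    A validation path for the embedded table, not a replacement for it.
    """
    model = model or GranthamModel()
    a, b = _check_residue(a), _check_residue(b)
    try:
        ca, pa, va = model.properties[a]
        cb, pb, vb = model.properties[b]
    except KeyError as exc:  # custom models may be partial
        raise InputError(f"no properties for residue {exc.args[0]!r}") from None
    raw = math.sqrt(
        model.alpha * (ca - cb) ** 2
        + model.beta * (pa - pb) ** 2
        + model.gamma * (va - vb) ** 2
    )
    return model.scale() * raw


def mean_grantham_distance() -> float:
    """Mean of the 190 off-diagonal canonical distances (~100)."""
    aas = _GRANTHAM_ORDER
    values = [
        GRANTHAM_TABLE[(a, b)] for i, a in enumerate(aas) for b in aas[i + 1 :]
    ]
    return sum(values) / len(values)


def median_grantham(
    mutations: Sequence[PointMutation], per_residue: bool = False
) -> float:
    """Median Grantham distance over a mutation list.

    Each mutation counts once by default; with ``per_residue`` the list is
    first reduced to one entry per mutated position (the first listed),
    mirroring the per-residue convention used for conservation medians.
    Even-length inputs use the arithmetic midpoint.
    """
    if not mutations:
        raise InputError("median_grantham: empty mutation list")
    if per_residue:
        seen: dict[int, PointMutation] = {}
        for m in mutations:
            seen.setdefault(m.position, m)
        mutations = list(seen.values())
    return statistics.median(grantham_distance(m.wt, m.mut) for m in mutations)


@dataclass(frozen=True)
class PssmProfile:
    """Per-position log2 PSSM scores (and optional observed frequencies).

    Positions are 1-based full-protein coordinates of the reference; each
    mapped position scores all 20 residues.  Higher scores mean the residue
    is more common at that position of the conserved domain than expected by
    chance.
    """

    scores: Mapping[int, Mapping[str, float]]
    wt: Mapping[int, str]
    frequencies: Mapping[int, Mapping[str, float]] | None = None
    domain_id: str = ""

    def __post_init__(self) -> None:
        for position, row in self.scores.items():
            missing = set(GRANTHAM_PROPERTIES) - set(row)
            if missing:
                raise InputError(
                    f"PSSM position {position} lacks scores for {sorted(missing)}"
                )


@dataclass(frozen=True)
class ConservationProfile:
    """Per-residue conservation scores; lower (negative) = more conserved."""

    scores: Mapping[int, float]
    source: str = ""

    def score(self, position: int) -> float:
        try:
            return self.scores[position]
        except KeyError:
            raise CoordinateError(
                f"no conservation score for position {position}"
            ) from None


@dataclass(frozen=True)
class PssmDelta:
    """Wild-type vs mutant PSSM comparison for one mutation."""

    mutation: PointMutation
    wt_score: float
    mut_score: float
    classification: str  # mutant_less_conserved | similar | mutant_more_conserved | not_present


def pssm_delta(
    pssm: PssmProfile, mutation: PointMutation, similar_tol: float = 0.0
) -> PssmDelta:
    """Compare wild-type and mutant log2 scores at the mutated position.

    ``not_present`` overrides the score comparison whenever observed
    frequencies accompany the matrix and the mutant's frequency is zero
    (the residue was never seen in the domain alignment).
    """
    if mutation.position not in pssm.scores:
        positions = sorted(pssm.scores)
        span = f"{positions[0]}-{positions[-1]}" if positions else "(empty)"
        raise CoordinateError(
            f"{mutation}: position absent from PSSM (available: {span})"
        )
    row = pssm.scores[mutation.position]
    wt_score = row[mutation.wt]
    mut_score = row[mutation.mut]
    freq_row = (pssm.frequencies or {}).get(mutation.position)
    if freq_row is not None and freq_row.get(mutation.mut, 0.0) == 0.0:
        classification = "not_present"
    elif abs(mut_score - wt_score) <= similar_tol:
        classification = "similar"
    elif mut_score > wt_score:
        classification = "mutant_more_conserved"
    else:
        classification = "mutant_less_conserved"
    return PssmDelta(
        mutation=mutation,
        wt_score=wt_score,
        mut_score=mut_score,
        classification=classification,
    )


def median_conservation(
    profile: ConservationProfile, mutations: Iterable[PointMutation]
) -> float:
    """Median conservation score over the *residues* touched by a mutation set.

    Mutations are de-duplicated to unique positions first: several SNVs of
    one residue contribute that residue's score once.
    """
    positions = sorted({m.position for m in mutations})
    if not positions:
        raise InputError("median_conservation: empty mutation list")
    return statistics.median(profile.score(p) for p in positions)
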