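"""Binomial enrichment of resistance mutations inside observed SNV space.

If missense SNVs were evolutionarily unconstrained, a resistance mutation
would land inside the portion of SNV space already realised among homologues
with probability p = observed/possible (the background fraction pooled over
the analysed domains).  The chance that at least k of n resistance mutations
fall inside that portion is then an upper binomial tail; a very small tail
indicates that resistance mutations preferentially re-use residues evolution
has already explored, i.e. that they are subject to purifying selection.

The tail is computed by exact log-space summation (n here is tens, not
thousands, so the exact sum is both cheap and free of approximation error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InputError
from .msaprofile import MutationClassTable, SNVSpectrum


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    Terms are accumulated from log binomial pmf values so large n cannot
    underflow intermediate factors.
    """
    if not 0 <= k <= n:
        raise InputError(f"binomial_tail: k={k} outside [0, {n}]")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"binomial_tail: p={p} outside [0, 1]")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_p, log_q = math.log(p), math.log1p(-p)
    total = 0.0
    for j in range(k, n + 1):
        log_term = (
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * log_p
            + (n - j) * log_q
        )
        total += math.exp(log_term)
    return min(total, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the observed-in-MSA enrichment test."""

    n: int
    k: int
    p_background: float
    tail_probability: float

    def __str__(self) -> str:
        return (
            f"k={self.k}/{self.n} mutations observed among homologues; "
            f"background p={self.p_background:.4f}; "
            f"P(X >= k) = {self.tail_probability:.3G}"
        )


def occurrence_enrichment(
    spectra: Sequence[SNVSpectrum],
    table: MutationClassTable,
    mutation_class: str | None = None,
    stratified: bool = False,
) -> EnrichmentResult:
    """Test whether mutations fall inside observed SNV space more than chance.

    The background probability pools possible/observed counts over *spectra*;
    k and n pool occurred/total over the (optionally class-filtered) rows of
    *table*.  With ``stratified`` the tail is instead the product of per-gene
    tails, each gene using its own background fraction; the reported
    ``p_background`` remains the pooled value for reference.
    """
    if not spectra:
        raise InputError("occurrence_enrichment: no spectra supplied")
    possible = sum(s.possible for s in spectra)
    observed = sum(s.observed for s in spectra)
    if possible == 0:
        raise InputError("occurrence_enrichment: spectra have empty SNV space")
    k, n = table.occurred_and_total(mutation_class)
    if n == 0:
        raise InputError("occurrence_enrichment: no mutations in the class table")
    p_pooled = observed / possible

    if not stratified:
        tail = binomial_tail(k, n, p_pooled)
    else:
        spectra_by_gene = {s.domain_id: s for s in spectra}
        tail = 1.0
        matched = 0
        for (gene, cls), row in table.counts.items():
            if mutation_class is not None and cls != mutation_class:
                continue
            if gene not in spectra_by_gene:
                raise InputError(
                    f"occurrence_enrichment: no spectrum for gene {gene!r}"
                )
            spectrum = spectra_by_gene[gene]
            tail *= binomial_tail(
                row["occurred"], row["total"], spectrum.observed / spectrum.possible
            )
            matched += row["total"]
        if matched == 0:
            raise InputError("occurrence_enrichment: class filter matched nothing")
    return EnrichmentResult(n=n, k=k, p_background=p_pooled, tail_probability=tail)
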