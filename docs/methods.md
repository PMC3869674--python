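# Methods

## The question and the model

A resistance mutation is a somatic missense change in a drug-target kinase
domain observed in patients relapsing on a tyrosine kinase inhibitor. Under
the null model implemented here, every missense SNV of the domain is equally
probable: a mutation is a uniform draw from the domain's SNV space, and the
probability that it coincides with residue variation already present among
homologues is simply the fraction p of that space realised in the MSA. The
alternative — purifying selection constraining which mutations persist —
predicts that far more resistance mutations fall inside the realised
fraction than the null allows. The package computes both sides: the SNV
space and its realised fraction, and the exact binomial tail for the number
of mutations observed among homologues.

## Codon SNV space

Each codon admits 9 single-base substitutions. The missense neighbourhood
keeps the distinct amino acids among their translations, excluding the
wild-type residue (synonymous events) and stop codons (nonsense, not
missense). Distinctness is at the amino-acid level: e.g. AGC (Ser) has 8
non-synonymous nucleotide events but only 6 reachable residues
{R,G,C,N,T,I}. Neighbourhood sizes over the 61 sense codons average 5.80;
codon-usage-weighted natural domains land near 5.9 per codon. Only the
standard genetic code is supported; lowercase input is uppercased and U is
read as T. A CDS whose translation conflicts with a mutation's stated
wild-type residue, or with the MSA reference row, is surfaced as a
validation error rather than silently reinterpreted.

## Alignment profiles and occurrence

The MSA is ingested as aligned FASTA with one designated reference row,
assumed to span the analysed domain without internal reference gaps being
meaningful positions (reference gap columns are unmappable). Coordinates are
1-based, inclusive, in full-protein numbering; `reference_offset` anchors
the first reference residue.

Counting conventions, applied uniformly:

* the frequency denominator is **all** rows, reference included;
* gap (`-`) and ambiguity codes (X, B, Z, J, U, O) remain in denominators
  and never match a mutant residue;
* matching is case-insensitive;
* printed percentages truncate toward zero at whole percents when ≥ 1%
  (87/276 → 31%, not 32%) and at one decimal below 1% (1/276 → 0.3%). The
  truncation convention is the only one consistent with all three published
  worked ratios (87/276→31%, 146/276→52%, 51/276→18%).

A mutation "occurred" when its mutant residue appears in ≥ 1 row at the
mapped column; otherwise it is "novel". The observed SNV spectrum applies
the same rule to every reachable residue of every domain position. An
optional per-column confidence track (GUIDANCE-style, values in [0,1]) can
mask low-confidence columns out of spectra; the default is off, since
nothing indicates masking changed any published count.

## Compound mutations

For an ordered pair (A, B), the denominator is the number of rows carrying
A's mutant residue and the joint count is the number also carrying B's; the
conditional is their ratio, undefined (reported NA) at denominator 0. Joint
counts are symmetric; conditionals are not. Integer counts are kept
alongside the ratio so the chain rule joint = P(B|A)·count(A) =
P(A|B)·count(B) holds exactly.

* **Novel pairs**: joint = 0 in both orders while each single mutation has
  count ≥ 1.
* **Obligate pairs**: conditional = 1 in both directions with joint ≥ 1.
  "Always observed together" is directionally ambiguous; the bidirectional
  reading is the strictest and is the default, with a one-directional mode
  behind a flag.
* Display bins (percent): <10 white, [10,19) yellow, [19,50] orange, >50
  red. The published bin edges overlap at 19; the overlap is resolved in
  favour of the higher bin.
* Full-panel exports stream ordered pairs row-major over the input mutation
  order rather than materialising the matrix.

No phylogenetic correction is attempted: rows are treated as exchangeable,
so shared ancestry and co-selection are indistinguishable here by design.

## Grantham distances

The canonical published 20×20 integer matrix is embedded as the source of
truth (symmetric, zero diagonal, maximum 215 for Cys–Trp, off-diagonal mean
99.97). The empirical formula

    D(a,b) = ρ · [ α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)² ]^½

with composition c, polarity p, volume v and α = 1.833, β = 0.1018,
γ = 0.000399 is kept as a cross-validation path. ρ defaults to the value
scaling the 190-pair mean to exactly 100 (≈ 50.790; the commonly quoted
50.723 is slightly too small to reproduce Cys–Phe = 205 on rounding).
Recomputation agrees with the embedded table within ±1.1 units for 189 of
190 pairs; the exception is Asp–Trp, published as 181 but recomputing to
≈ 190.8 — a known internal inconsistency of the published matrix, which is
why the table, not the formula, is canonical.

Medians over mutation sets count each mutation once by default; a
per-residue mode de-duplicates to unique positions first (the convention
used for conservation medians). Even-length sets take the arithmetic
midpoint.

## PSSM and conservation scoring

Conserved-domain PSSMs are read in the NCBI ASCII dialect (position, wild
type, 20 integer log2 odds, optional 20 observed-frequency percents;
trailing information/weight columns ignored). The mutant is classified
against the wild type by score comparison: greater → `mutant_more_conserved`,
equal → `similar` (exact equality by default, integer scores; a tolerance
flag exists), less → `mutant_less_conserved`; a mutant with observed
frequency 0 is `not_present` regardless of scores. Conservation scores
(lower/negative = more conserved) are ingested from a (position, score[,
grade]) TSV and never computed — the evolutionary-rate estimation that
produces them is upstream of this package. Conservation medians are
per-residue: multiple SNVs of one residue contribute its score once.

## Enrichment statistic

`binomial_tail(k, n, p)` sums the exact binomial pmf from k to n, with each
term evaluated in log space (lgamma) before exponentiation, so the sum is
exact to double precision at any n. The pooled construction takes p =
Σobserved/Σpossible over the analysed domains and (k, n) from the pooled
occurred/total of the mutation class under test. A stratified variant
(product of per-gene tails, each with its own background) is available
behind a flag because the pooled construction is one of several defensible
readings; for the published pooled totals (p = 3382/4676, k = 52, n = 55)
the exact pooled tail is 3.12×10⁻⁵ — the same decade as, but not digit-equal
to, the published 5.6×10⁻⁵, whose exact construction is not recoverable.
The statistic is treated as an order-of-magnitude quantity throughout.

## Synthetic families

The generator emulates exactly the statistical structure the analysis
assumes: exchangeable rows, independent columns except planted couplings.
Per column, a non-reference row carries the reference residue, a background
substitution with probability ε (default 0.05) uniform over the non-planted
alternative residues, or the planted support residue at its target
frequency. A coupling (i, a, j, b, f) then rewrites column j within rows
carrying a at i: fraction f get b, the rest revert to the reference residue,
so f is directly the conditional P(b at j | a at i) the compound scan should
recover; f = 0 plants a jointly-forbidden pair, f = 1 (with b arising
nowhere else) an obligate one. Planted residues are excluded from background
draws at their columns so realised counts are uncontaminated. Gaps are
injectable per cell (default 0) to exercise denominator rules; the reference
row is always emitted unmutated and ungapped.

Defaults (n = 300 rows, ε = 0.05) describe a mid-sized curated homolog
family of the kind the analysis targets. Ground truth is tallied from the
emitted matrix itself and written beside the FASTA as TSV, so tests compare
pipeline output to realised counts exactly rather than to sampling targets.
The same seed yields byte-identical outputs.

What the generator does **not** emulate: phylogenetic correlation between
rows, alignment errors, indel structure beyond uniform gaps, or codon-level
mutation processes. Tests passing on synthetic families therefore validate
the counting and statistical machinery, not the biological adequacy of
treating homolog sets as independent draws.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: families of
300–400 rows, 20-seed recovery sweeps, domains of a few hundred codons —
sizes at which binomial standard errors are small enough for 3σ planted-
parameter checks to be discriminating. Recovery tolerances are binomial:
|f̂ − f| < 3·σ per seed with σ² = f(1−f)/n, and mean bias < 2σ/√20 across
20 seeds. Medians of even-length sets use midpoints; percentage strings
truncate, never round; conditional frequencies divide realised integer
counts, so chain-rule identities hold exactly in floating point.

## Known limitations

* Published MSA-dependent counts (the occurred/novel splits, raw
  87/276-type counts, the compound-mutation matrix values) depend on the
  original homolog sets and cannot be re-derived without them; synthetic
  planted-truth checks stand in for them.
* The domain-total possible-SNV counts (1508/1627/1541) require the cited
  CDS accessions; the package reproduces the per-codon mean (~5.9) on
  simulated CDSs instead.
* The pooled enrichment tail reproduces the published order of magnitude
  only (see above).
* Alternative genetic codes, codon-usage weighting and transition/
  transversion asymmetry are out of scope.
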