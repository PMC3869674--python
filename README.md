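# resvar

Evolutionary analysis of drug-resistance missense mutations in kinase drug
targets.

Tumours treated with tyrosine kinase inhibitors (imatinib, erlotinib,
crizotinib, ...) frequently relapse through somatic missense mutations in the
drug target (EGFR, ALK, Abl1). Almost all of these are single-nucleotide
variants (SNVs). `resvar` asks whether such resistance mutations are
evolutionarily *unconstrained* — free to land anywhere in the SNV-accessible
space of the kinase domain — or whether they preferentially re-use residue
variation that already exists among evolutionarily related proteins, which
would indicate purifying selection on the mutational landscape.

The pipeline, given a protein MSA with a designated reference row and the
reference coding sequence:

1. **Codon SNV space** — for each codon, enumerate the amino acids reachable
   by exactly one base substitution (≤ 9 nucleotide events, collapsing to ≤ 9
   residues once synonymous and nonsense outcomes are removed); sum over a
   domain to get the *possible* missense-SNV count.
2. **Occurrence classification** — map each mutation's full-protein position
   to its alignment column and count homologues carrying the mutant residue:
   "occurred" (count ≥ 1) vs "novel". Denominators include every row; gaps
   and ambiguity codes never match. Percentages are truncated toward zero
   (87/276 → "31%").
3. **Observed SNV spectrum** — per position, which of the reachable residues
   appear in ≥ 1 homologue; totals give the observed fraction
   p = observed/possible of the SNV space.
4. **Compound mutations** — ordered conditional co-occurrence
   P(mut B | mut A) across MSA rows; the matrix is generally asymmetric.
   Detects *novel* pairs (each single observed, never jointly) and *obligate*
   pairs (conditional 1 in both directions).
5. **Biochemical / conservation scoring** — Grantham distances (canonical
   20×20 table; property-formula cross-check), conserved-domain PSSM
   wild-type vs mutant log2 scores, and per-residue conservation medians.
6. **Enrichment statistic** — if resistance SNVs were unconstrained, each
   would fall inside the observed portion of SNV space with probability p;
   the chance that ≥ k of n do so is the exact upper binomial tail
   P(X ≥ k) = Σ_{j=k..n} C(n,j) p^j (1−p)^{n−j}.

A synthetic-family generator (`resvar.synthdata`) produces alignments with
planted column frequencies and pairwise couplings plus a realised
ground-truth file, so the whole pipeline is testable without downloads.

## Worked example

Simulate a 300-row family around a 33-residue reference, planting a Y5F
variant at 25% frequency and a coupling so that 60% of F-carriers also carry
P at position 12, then run the analyses:

```sh
resvar simulate --spec spec.yaml --out fam
resvar occurrence --msa fam.fasta --ref reference --mutations "Y5F,I12P,K2Q"
```

```text
mutation  observed  count  n_rows  frequency  reported_percent
Y5F       true      75     300     0.25       25%
I12P      true      44     300     0.146667   14%
K2Q       false     0      300     0          0.0%
```

Y5F was realised in 75 of 300 rows (the planted 25%); K2Q is novel — no
homologue carries Q at position 2. The compound scan shows the asymmetry of
conditional frequencies:

```sh
resvar compound --msa fam.fasta --ref reference --mutations "Y5F,I12P"
```

```text
first  second  joint  denominator  conditional  reported_percent  bin
Y5F    Y5F     75     75           1            100%              red
Y5F    I12P    44     75           0.586667     58%               red
I12P   Y5F     44     44           1            100%              red
I12P   I12P    44     44           1            100%              red
```

58.7% of F-carriers also carry P (planted 60%), while *every* P-carrier
carries F, because P arises only on the coupled haplotype — the matrix is
not symmetric. Biochemical severity of a mutation set:

```sh
resvar grantham --mutations "T315I,E255K,M244V"
```

```text
mutation  grantham
T315I     89
E255K     56
M244V     21
median    56
```

T315I (Thr→Ile, the Abl1 gatekeeper) is moderately radical at 89 Grantham
units; M244V (21) is conservative; the set's median is 56. Finally, the
enrichment tail for pooled kinase-domain totals — 3382 of 4676 possible
missense SNVs observed among homologues, and 52 of 55 resistance mutations
falling inside that observed portion:

```sh
resvar enrich --possible 4676 --observed 3382 --k 52 --n 55
```

```text
3.120E-05
```

A ~3×10⁻⁵ probability of that much agreement by chance: resistance
mutations are strongly enriched inside the evolutionarily realised part of
SNV space.

## Layout

- `src/resvar/codonspace.py` — genetic-code SNV algebra
- `src/resvar/msaprofile.py` — alignment profiles, occurrence, spectra
- `src/resvar/compoundscan.py` — ordered co-occurrence matrices
- `src/resvar/biochem.py` — Grantham / PSSM / conservation scoring
- `src/resvar/enrichstats.py` — exact binomial enrichment tail
- `src/resvar/synthdata.py` — synthetic families with planted ground truth
- `src/resvar/io.py`, `src/resvar/cli.py` — parsers, writers, CLI
- `docs/methods.md` — models, conventions, parameter choices, limitations
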