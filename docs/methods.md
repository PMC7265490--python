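# Methods

This note documents the models, conventions and numerical choices behind
`mirtail`, and what the synthetic-data tests do and do not establish about
real libraries.

## Read assignment by central motif

Reads are assigned to miRNAs by exact containment of a *central motif*: a
substring of the mature sequence of length `motif_len` (default 13 nt),
centered inside the window `[head_guard, L − tail_guard)` (defaults 2 and
5; centering ties break toward the 5′ side). The guards keep the motif
away from both ends, so 5′ offsets up to `head_guard` and 3′ trimming up
to `tail_guard` never disturb the match; mismatches are tolerated only
outside the motif. At 13 nt a random hit occurs about once per
4¹³ ≈ 6.7×10⁷ nt, so cross-assignment between a handful of references is
negligible. A read matching zero or ≥ 2 motifs is excluded (counted
`unassigned` / `ambiguous`); two references with identical motifs are both
flagged ambiguous at load time. This containment rule is a deliberate,
deterministic substitute for aligner-based assignment: it is exact inside
the motif by design, which makes every downstream decomposition
oracle-checkable.

## Greedy-templated 3′ decomposition

Each assigned read is decomposed as
`read = mature[o₅ : L + min(t₃,0)] + flank3[: max(t₃,0)] + tail`.
The walk starts at the motif's 3′ boundary and classifies every base that
matches the template (mature sequence, then the genomic 3′ flank) as
templated; the non-templated tail begins at the first mismatch. This
maximizes the templated span (property-tested against exhaustive search
over all splits) and makes the convention explicit for the genuinely
ambiguous case: an added nucleotide identical to the next genomic base is
counted as templated extension, never as tail. The cost is a known blind
spot — a true added U over a genomic U is invisible — which the simulator
compensates for by never planting such tails (below).

Reads whose 5′ region mismatches the mature sequence, whose start lies
upstream of the canonical 5′ end, or in which the motif occurs twice
cannot be decomposed losslessly from `(mature, flank3)` alone and are
excluded as `refused`. The five read fates (annotated, ambiguous,
unassigned, refused, dropped-at-adapter-stripping) always partition the
input; this conservation is asserted on every simulated fixture. Reads
with |5′ offset| > 2 are annotated but excluded from 3′ statistics by
default (`max_offset5`): larger shifts indicate a distinct 5′ species
rather than a 3′ isomiR.

## Tail statistics

* **Canonical read** = the single most abundant fully-templated class
  (tail = ""), whatever its length; ties break toward the unmodified
  class, then the smaller |t₃|. Canonical % and isomiR % are computed on
  raw read counts within a profile; CPM appears only as an expression
  column.
* **k** = number of *occurrences* of a nucleotide anywhere in the tail
  ("UAU" has k=2 for U), not the longest run.
* **Cumulative oligo-tail curve**: over reads with k ≥ `min_oligo`
  (default 1 for curves), the percent with ≥ k occurrences, from longest
  to shortest tails; starts at 100 and is non-increasing.
* **Weighted oligo-U mean**: Σ count·k / total reads of the miRNA, where
  reads with k < `min_oligo` contribute 0. `min_oligo` defaults to 2 for
  means and U-scores: mono-addition is a biologically distinct process,
  and the exact oligo cutoff is surfaced as a parameter rather than
  hard-coded. The denominator is all reads of the miRNA (not only tailed
  reads); this is a declared convention, switchable upstream by filtering
  the profile.
* **U-score** = weighted oligo-U mean (test) − weighted oligo-U mean
  (control); antisymmetric by construction.
* **Group comparisons**: paired two-sided Wilcoxon signed-rank (exact null
  for n ≤ 25 without ties or zeros, normal approximation with corrections
  otherwise; all-zero differences ⇒ p = 1), unpaired two-sided Welch t.
  Both require n ≥ 5. miRNAs under `min_reads` (default 50) are flagged
  low-coverage and excluded from cross-miRNA comparisons. p values are
  reported raw (no multiple-testing layer).

## Authentic-tail calling

Treatment (3′-exposed) vs control (3′-protected) libraries are compared
per (nucleotide, k) class with pseudocounted within-miRNA frequencies
`(count + ψ)/(total + ψ)` (ψ = 0.5) and `enrichment = log₂` of their
ratio. A class is called authentic when enrichment ≥ 1 (2-fold) and
freq_treat ≥ 10⁻³. The log-ratio is symmetric, scale-free and robust to
library-size differences; all three constants are configuration
parameters. Classes for all four nucleotides are always emitted so
depletion is visible, and an `exact_tails` flag switches from composition
classes to full tail strings. Because the call criterion is a plain 2×
frequency ratio, it is only statistically meaningful when per-class
background counts are large enough that Poisson fluctuation sits well
below a factor of two; the recovery tests therefore use 5×10⁴ reads per
condition for a single-miRNA library (real IP libraries of one
overexpressed miRNA are deeper still).

## Duplex MFE model

Hybridization is scored by dynamic programming over antiparallel,
non-crossing, intermolecular-only pairings (Watson–Crick + G:U):

E(structure) = initiation (+4.1 kcal/mol)
  + Σ stack terms for adjacent pairs (embedded nearest-neighbor table,
    Turner-style 37 °C values; G:U stacks approximate, symmetric
    completion with a weak −0.5 default for unparameterized wobble
    combinations)
  + affine penalties for bulges (3.8 + 0.3·size) and internal loops
    (1.7 + 0.4·size).

"No duplex" is returned when the optimum is positive. There are no
dangles, terminal-AU penalties or loop-asymmetry terms, so absolute
energies differ from full Turner-2004 implementations; the screen's output
is the *ranking*, which agrees with a full-featured model on the
discriminating contrast (extensive 3′ pairing vs seed-only, cross-checked
against RNAduplex when ViennaRNA is installed). The DP is exact for this
model: it equals exhaustive enumeration on all pairs ≤ 8 nt, and extending
either strand with non-pairing context can only lower the optimum (no
end effects). Energies are evaluated on a window of the seed site plus
30 nt upstream flank (where 3′-supplementary pairing lies on the
transcript) and 5 nt downstream; the window and seed definition
(7mer-m8 default, 7mer-A1 optional) are parameters because reasonable
choices differ between studies.

## Synthetic-data generator

Per read: a miRNA drawn from log-normal expression weights; with
probability `p_canonical` the exact mature sequence; otherwise a
(trim, tail) pair resampled until the read is genuinely modified — trim
from a truncated geometric (max 6), tail length geometric with
continuation probability `q` (mean q/(1−q), capped at 20 nt on a ~21-nt
body), tail bases i.i.d. from composition π over (A, C, G, U). Two design
points keep planted truth aligned with the annotation conventions:

1. the *first* tail base is drawn from π renormalized to exclude the next
   templated base, so the greedy rule recovers the planted boundary
   exactly (otherwise truth and convention disagree on genomically
   ambiguous tails and exact-agreement tests are meaningless);
2. the modified branch resamples until trim > 0 or tail ≠ "", so the
   planted `p_canonical` is the expected canonical-read fraction.

With probability `noise_rate` the tail is replaced by a ligation-noise
fragment (uniform length 1–15, uniform bases, exempt from rule 1 — noise
is junk); substitutions are applied per base at `seq_error`; the 3′
adapter is appended; qualities are constant Q37. Condition presets (WT,
F2L3, dPAZ, TUT7KO, DIS3L2KO) differ only in `p_canonical`, `q` and π and
are illustrative settings for protected, progressively exposed, and
tailing/decay-deficient states — not fits to any dataset.

What the generator does *not* emulate: PCR duplication, ligation sequence
bias beyond the flat noise rate, 5′ isomiRs, expression-dependent error
profiles, or multi-mapping between paralogous miRNAs. Passing recovery
tests therefore demonstrates correctness of the computation under the
stated generative model, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

Recovery and property tests run at desk scale, chosen so each check is
statistically meaningful: 10⁵ reads for lossless decomposition and
parameter recovery (planted canonical fraction recovered within ±2 points,
weighted oligo-U mean within ±5% relative), 10⁴ reads per condition × 40
seeds for the U-score sign, 5×10⁴ reads per condition × 40 seeds for
authentic-tail calling, 100 decoys × 40 seeds for trigger ranking, 10³
random pairs ≤ 8 nt for the duplex oracle. Percent sums are asserted to
1e-9; energy comparisons to 1e-9 kcal/mol; Wilcoxon exactness is checked
against full 2ⁿ enumeration for n ≤ 10. All stages are deterministic
given seed and configuration (byte-identical reruns), with every random
draw routed through one seeded generator per stage.

## Known limitations

* A non-templated addition identical to the genomic flank is counted as
  templated extension (greedy rule); uridylation over a genomic U run is
  systematically underestimated.
* Motif assignment requires the motif intact: trimming deeper than
  `tail_guard` (or an error inside the motif) makes a read unassigned
  rather than annotated-as-trimmed, slightly undercounting extreme
  trimming.
* Duplex energies are not comparable in absolute value to full
  Turner-2004 implementations; use rankings and within-run contrasts only.
* The enrichment caller tests each (nt, k) class marginally with a fixed
  fold-change rule; it does not model count uncertainty, so shallow
  libraries can produce false calls by Poisson fluctuation.
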