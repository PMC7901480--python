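# Methods

## The quantification model

Each sample receives five synthetic internal standards at nominal
concentrations x₁ > x₂ > … > x₅ spanning 10⁴–10⁸ copies g⁻¹ in 10× steps.
After sequencing, spike-in read counts yᵢ are assumed log-linear in the
added amount:

    log₁₀ yᵢ = a · log₁₀ xᵢ + b + εᵢ,   εᵢ ~ N(0, σ²)

The regression is fitted in the observational direction (reads on
concentration, matching how the data are generated) by ordinary least
squares and inverted for quantification:

    x̂ = 10^((log₁₀ y − b·d) / (a·c))

An errors-in-variables treatment was considered and rejected: the nominal
gradient values are design constants, not noisy measurements, and keeping
the fit direction consistent with the generative model keeps the inversion
unbiased at σ → 0 (verified by the zero-noise round-trip tests).

**Calibration (c, d).** Plasmid spike-ins and microbial genomes are not
identical templates through DNA extraction and amplification. Fitting qPCR
standard curves (CT = a·x + b) for spike-ins and for cultured microbes and
comparing them by one-way ANOVA yields multiplicative corrections: c = 1
when the slope ANOVA finds no difference at α (the observed situation;
otherwise c is the ratio of mean slopes — our extension of the decision
rule, since the significant-slope branch is never exercised by the
reference data), and d = mean microbial intercept / mean spike-in intercept,
using unweighted per-curve means. d is rounded to 3 decimals for reporting;
the unrounded value is kept in provenance. With the reported group means
(spike-ins 45.118; bacteria 36.251; fungi 39.529 cycles) this yields
d = 0.803 and 0.876.

**Flags.** Inverted estimates outside the fitted gradient span are
extrapolations and flagged (`extrapolated_low/high`) rather than dropped:
the log-linearity is only demonstrated inside the gradient. Zero-read cells
are reported as 0 with `below_detection`; no pseudocounts are added anywhere
(a pseudocount would bias the log-log fit at the low end). Spike-in
standards with zero reads are excluded from the fit (minimum three usable
points) with a warning.

**Detection limit.** The concentration whose calibrated curve value equals
one read. With the default simulator depth this lands at ~10^4.2 copies
g⁻¹, inside the 10⁴–10⁵ working floor expected for this gradient.

## Internal standard design

A standard is a 472-bp construct: 336F (16S V3–V4 forward) · 10-bp spacer ·
ITS3 · 324-bp stuffer · rc(ITS4) · 55-bp stuffer · rc(806R). Nesting the
fungal (ITS2) amplicon inside the bacterial one lets a single molecule spike
both libraries. Degenerate positions in 806R are instantiated with a fixed
concrete choice (W→A, B→T, D→G — the realization used in the shipped
standards); anchor re-detection is IUPAC-aware, so any valid realization is
recognised.

Stuffers are random sequences constrained to: GC within ±1 percentage point
of the community-matched target (0.46 by default), homopolymers ≤ 10 bp,
exact repeats ≤ 16 bp, self-complementary regions ≤ 10 bp. Repeat screening
is exact-substring detection (binary search over lengths with a k-mer
index) — deterministic and strictly stricter than a heuristic aligner at
these scales. Self-complementarity is defined as any substring whose
reverse complement occurs anywhere in the sequence (overlaps and
palindromes count) — a conservative superset of hairpin/dimer definitions.
These constraints apply to stuffer segments only; the fixed universal
scaffold necessarily contains conserved sites, so full-sequence checks are
limited to the homopolymer bound and anchor presence/order. Whether the GC
window should apply to the stuffer or the whole construct is ambiguous in
principle; we apply it to the stuffer (the designable part) and report
full-sequence GC alongside.

Specific recognition primers are drawn from the construct interior under
composition rules (18–24 bp, Tm 55–65 °C and pairwise ΔTm ≤ 5 °C, GC
0.40–0.60, homopolymers ≤ 3 bp, self-complement ≤ 5 bp) and screened for
exact-match uniqueness (either strand) against sibling standards and an
optional user-supplied background set; an in-silico cross-amplification
matrix over the designed set must be diagonal. Melting temperatures use
nearest-neighbor thermodynamics (unified 2004 duplex parameters, 50 mM
monovalent salt, 25 nM per strand, entropic salt correction); parameters are
module constants, and the test suite cross-checks the implementation
against an independent route to < 0.01 °C. The shipped IS1–IS5 do not carry
published specific-primer annotations, so detection for them defaults to
amplicon-region matching; freshly designed standards get primer-pair
recognition.

## Spike-in detection

A read is assigned to a standard iff its recognition sequence occurs on
either strand within a Hamming bound (default 2 mismatches). The mismatch
model is substitution-only: indels at primer-recognition sites are rare in
amplicon data and Hamming search keeps detection O(reads × standards).
Reads matching ≥ 2 standards are ambiguous — excluded from all counts and
reported separately, never double-counted; counts + residual + ambiguous
equals the input size exactly. Feature-to-standard assignment for clustered
tables uses global edit-distance identity (threshold 0.97 by default).
Quality scores are ignored; quality filtering belongs upstream. Raw counts
are used throughout — per-sample curve fitting makes cross-sample depth
normalisation unnecessary for quantification, though cross-sample
comparability of the raw counts themselves is an assumption the user's
pipeline must carry.

## The simulator

`simdata` generates the staggered two-mock benchmark: ten organisms (five
bacteria, five fungi) at one decade each over 10⁴–10⁸ copies g⁻¹, the second
mock inverting the stagger, plus the five-standard gradient. Reads are drawn
as round(10^(a_true·log₁₀(copies·recovery) + b_true + ε)) with ε ~ N(0, σ);
the lognormal form is chosen because the analysis is linear in log-log
space. Defaults: a_true = 0.95, σ = 0.1 log₁₀ units, b_true = −4.0 so the
one-read detection limit lands at 10^4.2 copies g⁻¹. Recovery fractions are
drawn uniformly per class from the observed solid-substrate ranges
(spike-ins 0.7002–0.8390, bacteria 0.7187–0.8710, fungi 0.7045–0.8612),
independently per observation. Counts are rounded to integers, so zero
reads occur at the low end and exercise the detection-limit path; tests
that assert exact round trips therefore run at b_true = 0, where counts are
large and rounding is negligible. qPCR simulation adds Gaussian CT noise to
true lines at each dilution × replicate. Read simulation samples windows
from the amplicon on a random strand with iid substitutions.

Not emulated: PCR amplification bias, chimeras, quality-score profiles,
taxonomic misassignment, and nominal-vs-true spike-in offsets (the
simulator treats nominal concentrations as true; a sensitivity offset can
be emulated by scaling the gradient design). Passing tests demonstrate the
estimator chain is correct under the stated noise model, not that wet-lab
recovery will match.

## Numerical and design choices

- One integer seed drives every simulation (`numpy.random.default_rng`);
  derived seeds stay below 2³¹.
- Coordinates are 0-based half-open; sequences are stored uppercase with U
  mapped to T.
- ANOVA degenerate cases are explicit: zero between-group variation gives
  F = 0, p = 1; zero within-group variation with real differences gives
  F = ∞, p = 0 (relative tolerance 1e-12 on the sums of squares).
- Stuffer generation draws the GC count uniformly from the integers inside
  the tolerance window (GC holds by construction) and rejects on the other
  constraints; an infeasible constraint set fails loudly with rejection
  diagnostics rather than looping.
- The single-standard mode assumes slope 1 through one point (ratio
  scaling). It exists to quantify the perturbation a single spike-in causes
  when the true slope differs from 1: at slope 0.85, estimates for taxa
  three decades from the standard are biased 10^0.45 ≈ 2.8-fold, while the
  gradient fit stays unbiased.
- Problem sizes in the test-suite simulation studies (100-seed correlation
  sweep, 500-seed parameter recovery, 300-replicate calibration bias, 2,000
  ANOVA null draws) were chosen as the smallest sizes at which the asserted
  proportions are stable, keeping the default suite fast.

## Known limitations

- Specific-primer uniqueness is screened by exact matching against sibling
  standards and user-supplied background sequences, not against a public
  nucleotide database; for production designs an external database screen
  is still advisable.
- Secondary-structure energetics are not modelled; the self-complement
  length bound is a proxy, not a folding calculation.
- The calibration's significant-slope branch (c ≠ 1) follows the stated
  decision rule but has no reference data to validate against.
- Detection assumes reads at least as long as the recognition region and no
  indels; long-indel platforms would need an alignment-based detector.
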