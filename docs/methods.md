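# Methods

## Correction model

A SIRM dataset for one molecule is a dense n-dimensional nonnegative
array `I_data`, one dimension per tracer isotope (1–3 supported), indexed
by heavy-label counts `x` with `0 ≤ x_e ≤ N_e`, where `N_e` is the atom
count of the tracer's element in the molecular formula. Unobserved
isotopologues are zeros; the array always spans the full `0..N_e` range
even when observations stop earlier, because natural abundance can move
intensity into any admissible index.

The model assumes: (i) peaks are isotopically resolved and correctly
identified, so each array cell is one isotopologue and there is no
overlap between molecules; (ii) natural heavy-isotope incorporation is
independent and identically distributed across the unlabeled atoms of
each element, giving the binomial term `P[n][k] = C(n,k) p^k (1−p)^(n−k)`;
(iii) incorporation is independent across elements, so the n-dimensional
kernel factorizes, `K(x,i) = Π_e P_e[N_e−i_e][x_e−i_e]`; (iv) the tracer
itself is 100% enriched (tracer impurity correction is out of scope, as
are elements with more than one heavy isotope, e.g. Se).

Forward contamination is `I(x) = Σ_{i≤x} I_clean(i) K(x,i)`; since each
clean cell's contributions sum to 1 over the full index space, total
intensity is conserved. Because `i ≤ x` componentwise implies `i` precedes
`x` lexicographically, the flattened kernel matrix is lower triangular,
and the exact inverse (when nonnegativity never binds) is one ascending
sweep:

    corr(x) = (data(x) − Σ_{i<x} corr(i) K(x,i)) / K(x,x)

`K(x,x)` is the survival factor `Π_e (1−p_e)^(N_e−x_e)`. Real data carry
noise, and a peak can observe less intensity than the NA contamination
arriving from below it; the sweep then goes negative and the estimate is
clamped at zero as it is produced. Clamping makes the sweep inexact, so
the estimate is refined iteratively: re-contaminate the estimate, form
the residual against the observation, add an unclamped sweep of the
residual to the estimate, clamp the combined estimate at zero, and repeat
while the sum-of-absolute residual strictly decreases. The iterate with
the smallest residual is returned, together with its re-contaminated
reconstruction and residual. The procedure is fully deterministic.

Design choices made where the design was genuinely open:

- **Error metric**: sum of absolute residuals. Robust, scale-covariant,
  and imposes no distributional assumption on peak noise.
- **Stop rule**: strict decrease, arg-min iterate returned,
  `max_iterations` default 100 (noiseless inputs converge in one cycle;
  noisy real data typically need around a dozen).
- **Clamping**: applied to each entry of the initial sweep as produced and
  to the combined estimate each cycle, never to the residual increment.
  This keeps the noiseless case exact in one cycle while preventing
  negative mass from propagating upward.
- **Units**: intensities are processed unnormalized; normalization is the
  caller's choice.

## Binomial numerics

The default P-term evaluation ("org") interleaves one coefficient factor
`(n−k+j)/j` with one `p` factor and, while any remain, one `(1−p)` factor
per loop step, appending leftover `(1−p)` powers singly. Intermediates
thus stay near the final magnitude instead of forming a huge binomial
coefficient times a denormal-small power. Four alternatives are shipped
purely as a cross-check: exact integer factorials, scipy's exact
multiplicative coefficient, a log-gamma formulation, and a base-10
logarithmic version of the interleaving. Over the full grid
`0 ≤ k ≤ n ≤ 500` at `p = 0.00015` the maximum pairwise disagreement is
~5.6e−14 (dominated by log-gamma); the two exact-integer methods agree
bit-for-bit and sit within 1e−15 of the interleaved product.

P tables (2-D, rows normalized to 1 within 1e−12) and S tables (1-D,
monotone, `S[N] = 1`) depend only on (element count, abundance), so a
cache keyed by (isotope label, abundance, size) reuses them across all
molecules and replicates sharing an element count. Abundance is part of
the key so user overrides never collide with defaults; a cache hit
returns the identical table objects, and disabling the cache is
observationally transparent (byte-identical output files).

Default abundances: ¹³C 0.01109, ¹⁵N 0.0037, ²H 0.00015. All are
configuration-overridable per run.

## Quality control

Input: a peak whose label count exceeds its formula's atom count, or a
peak duplicating an isotopologue index already seen in its dataset
(first in file order wins), is annotated and excluded from the correction
array but still echoed to the output with the message appended.
Unparseable rows are annotated `malformed_row` likewise. QC never alters
an intensity.

Output: the reconstruction `I_datacalc` predicts what every isotopologue
should have shown. With a threshold configured — a percent of the
minimum, maximum, or average *observed nonzero* intensity, over the
collection or per dataset — predicted-but-unobserved isotopologues at or
above the cutoff (boundary inclusive) are appended as `PREDICTED` rows.
Implicit zeros from densification are not peaks and never enter the
statistics.

## Synthetic data

The generator emulates the gross statistics of real SIRM peak tables:
per-molecule isotopologue sparsity (default 0.3 of admissible indices
observed, at least one), long-tailed log-normal intensities, plausible
small-metabolite formulas (C2–29 with proportional H, N0–6, O1–14),
replicate sample groups, and — on request — injected duplicates,
out-of-range counts and unparseable cells for QC testing. Everything is
deterministic per seed, down to file bytes.

It does **not** model m/z values, mass accuracy, resolution-limited peak
overlap, detector noise, or tracer impurity. Passing round-trip tests on
synthetic data therefore demonstrates the algebraic correctness and
numerical stability of the correction, not robustness to
mis-identification or instrument artifacts, which must be handled before
this package in a real pipeline.

Two fixed reference vectors (a 9-carbon and a 6-nitrogen normalized clean
distribution) anchor the validation suite: their forward contaminations,
and the recovery of their outer product (10×7) after contaminating each
factor, reproduce the published reference values to printed precision,
with the multi-isotope round trip exact to below 1e−16.

## Numerical and degenerate cases

- `p = 0` makes every operation the identity (correction returns the data
  in one cycle with zero residual).
- An element absent from a formula gives a length-1 dimension (only count
  0), handled uniformly.
- Empty collections (header only) produce an empty output and a
  zero-count report.
- One-dimensional data take a flat-indexed fast path; it is
  floating-point-identical to the general tuple-indexed path (same
  arithmetic, cheaper indexing).
- Non-finite or negative input intensities are rejected at the API
  boundary; at the file boundary they annotate the row instead.

## Problem sizes

The validation suite runs on the published 18-point single-label vector,
10×7 two-label matrices, random arrays up to three dimensions (~50
cells), the full 501-row binomial grid, and synthetic collections of
dozens of molecules; a full suite run takes well under a minute. The
collection pipeline itself is linear in the number of datasets and has
been exercised at hundreds of datasets per second for typical metabolite
shapes.

## Known limitations

- No correction for tracer enrichment below 100%.
- Single heavy isotope per element only.
- No handling of unresolved/overlapping peaks; identification and
  resolution are upstream responsibilities.
- The iterative refinement is a heuristic descent on the residual; it is
  exact for noiseless data and matches a generic triangular solve when
  clamping never binds, but carries no global-optimality guarantee under
  heavy clamping.
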