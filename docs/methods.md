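# Methods

This note records the models, numerical choices and limitations behind
`evscreen`. It is written for a reader who wants to know exactly what the
code computes and why, not just how to call it.

## Barcode design

Barcodes are fixed-length DNA words (default 15 nt) satisfying four rules:
GC fraction within [0.40, 0.60] (inclusive at both ends, evaluated on
integer GC counts to avoid float-boundary artifacts); no homopolymer run
longer than 3 (so AAAA, CCCC, GGGG, TTTT are all excluded); no occurrence
of the cloning enzymes' recognition sites (EcoRI `GAATTC`, MfeI `CAATTG`,
BlpI `GCTNAGC`, BstXI `CCANNNNNNTGG`, IUPAC-expanded and scanned on both
strands, since the enzymes cut double-stranded DNA); and pairwise Hamming
distance ≥ 4 within a set. The distance floor is what makes decoding
error-tolerant: on the 14-nt prefixes used for read assignment it implies
distance ≥ 3, hence unique nearest-neighbour decoding of any
single-substitution read.

The designer is rejection sampling plus greedy code growth: uniform random
candidates are filtered by the single-sequence rules, then accepted iff
they keep distance ≥ 4 to everything accepted so far. Candidates and
accepted barcodes are packed into one-hot `uint64` words so the distance
check is an XOR + popcount over the accepted set; a 10⁶-candidate budget
completes in about 1.5 minutes on one core and yields a set of ~1.5×10⁵
barcodes — two orders of magnitude beyond the 2,500-barcode test-library
scale and comfortably past genome-wide library sizes. Greedy growth makes
no optimality claim (it is not a maximal code), but it is simple,
reproducible given the seed, and empirically monotone in the constraint
parameters. An optional strict mode additionally enforces the distance
floor against reverse complements of accepted barcodes; the default does
not, since barcode reads are strand-defined.

## Hairpin and cassette assembly

The mature product is `barcode + GGAGGAG` (22 nt at the default length).
The pri-miRNA-style hairpin is assembled as 5′ context, sense arm
(barcode + EXO motif), loop, passenger arm (exact reverse complement),
3′ context. The loop and flanking context shipped as defaults are
**synthetic placeholders** — valid DNA kept free of the cloning sites —
because the construct's real miR-601-derived loop and miR-30a context are
figure-level data not reproduced here; production users supply them via
`HairpinConfig`. Mismatch variants substitute the single passenger base
paired with the first barcode base (stem position 1), using the pairing
A-C, T-C, G-A, C-A keyed on that first base; this mimics the bulge at the
base of the native miR-30 hairpin that licenses Drosha processing, and by
construction never alters the mature sequence. Cassettes concatenate
primer flank, sgRNA, BlpI site, EcoRI site, hairpin, primer flank; a
validation pass reports any stray enzyme site between the flanks, and
strict mode turns that into an error.

## Deconvolution

RNA reads are trimmed to their first 14 nt (the barcode minus its last
base; the trailing EXO motif is constant and carries no information) and
compared against all barcode prefixes by Hamming distance. Every element
at the minimum distance is incremented when that minimum is ≤ 2 — best
hit within two mismatches, ties all counted, so multi-mapping reads
contribute to every tied element and column sums may exceed the
assigned-read count (both are tracked per sample). `N` bases count as
mismatches rather than discarding the read. sgRNA (DNA) reads are matched
exactly — zero mismatches — after locating a constant 5′ anchor
(default `CACCG`). The matcher is an index-free packed-popcount scan;
at library sizes up to a few 10⁵ barcodes this is faster than building
and maintaining an external aligner index, and it makes the tie-counting
semantics explicit.

## Scoring model

Enrichment: ρᵢ = log₂((tᵢ+ψ)/(rᵢ+ψ)) − median over retained elements,
with pseudocount ψ = 0.5 and elements dropped when the reference count is
below 10. The filter is applied to the reference sample only (detection is
defined by the unperturbed pool); log base 2 is the screen-analysis
convention and sets the scale of all effect sizes and cutoffs.

Null: Gaussian KDE over the control (non-targeting + safe-targeting)
enrichments, Scott's-rule bandwidth with a 10⁻³ floor, evaluated on a
0.01-spaced grid padded 9 log₂-units beyond the control range (so shifted
arguments ρ − t·e stay on-grid for the full ±8 effect grid), floored at
10⁻¹² and renormalised to integrate to one. At least 50 controls are
required post-filter; a degenerate (zero-spread) control set falls back to
a floored-bandwidth normal with a warning.

Gene effect: effect grid −8…8 in steps of 0.05; efficacy grid of m = 21
uniform points on [0, 1]. Per-element log-likelihood curves
log[(1/m)Σₜ f₀(ρᵢ − t·e)] are precomputed once as a matrix; a gene's
curve is the sum of its rows, ê its argmax (ties broken toward smaller
|e|, then negative — conservative and deterministic), and the score is
2(ℓ(ê) − ℓ(0)) floored at 0. Because t is marginalised, ℓ plateaus gently
for |e| beyond the elements' spread instead of decaying quadratically;
consequences worth knowing: ê sits at or slightly above the strongest
consistent enrichment (a "maximum plausible phenotype" estimator), and
combining two replicates with exactly opposite effects yields a
mirror-symmetric curve whose argmax is ±|e| with the score halved — the
direction is reported as unidentifiable evidence, not averaged to zero.

Permutations: for each distinct gene size k, 10,000 random k-element sets
are drawn from the pool of all targeting-element curves and scored
identically; p = (1 + #{perm ≥ observed})/(n_perm + 1). Sets are drawn by
sampling the pool with replacement — at pool sizes ≥ 10³ the collision
probability within a k = 10 draw is negligible and the draw vectorises.
Null distributions are cached per k and all draws derive from one seed.
Raw permutation p-values are used directly with the −log₁₀ p thresholds
(1.5 focused, 2.5 genome-wide); no FDR step is applied, matching the hit
definition the screen uses. Replicates combine by summing ℓ curves
element-wise over elements detected in all replicates, and the permutation
pool combines the same way, so a combined p-value is computed from the
combined evidence rather than by meta-combining per-replicate p's.

## Synthetic screens

The generator draws, per element: cellular abundance `exp(N(0, σ_cell²))`
(σ_cell = 1, a realistic ~2-fold-sd expression spread on the natural-log
scale); EV packaging bias `exp(N(0, σ_pack²))` applied in EV compartments
only, modelling sequence-intrinsic exosomal sorting; and guide efficacy
t ~ Uniform[0.5, 1] ("some guides work better than others" — every guide
works at least half-maximally). Gene EV effects act multiplicatively as
2^(t·e) on EV output in Cas9 cells only; independent growth effects act
the same way on cellular abundance between the 0 h and 48 h cellular
samples. Counts are multinomial at the configured depth (defaults to 500
reads per element per sample), which at fixed depth is the exact
finite-depth analogue of per-element Poisson sequencing noise.

Two structural facts make the screen work, and both are reproduced here:
the packaging bias cancels exactly in the Cas9-vs-WT EV ratio because the
two genotypes share barcodes, and the bias makes cellular and EV
abundances nearly uncorrelated. The default σ_pack = 2.4 comes from the
closed form R² ≈ σ_cell²/(σ_cell² + σ_pack²) ≈ 0.15, the weak-correlation
regime the platform operates in; `tune_bias` calibrates σ_pack by
bisection against a measured R² band (R² is monotone decreasing in
σ_pack), and reports the achievable range when a band cannot be reached.

Read-level simulation emits mature-bEXOmiR reads (barcode + EXO motif +
3′ adapter, truncated to the read length) for EV samples and
anchor + protospacer reads for cellular/DNA samples, with iid per-base
substitution errors (default 10⁻³) and a truth table of read origins.

What the generator does **not** model: PCR amplification bias, UMI-less
duplicate structure, quality-score-correlated errors, indels, adapter
read-through variability, guide off-target effects, and any mechanistic
EV biology (the bias term is a static per-barcode multiplier, not a
sorting mechanism). Passing tests therefore demonstrate that the pipeline
recovers what this statistical structure encodes — they do not guarantee
performance on library preps whose artifacts fall outside it.

## Problem sizes used in the test suite

The statistical acceptance checks run at 2,000 genes × 10 guides with
1,000 controls and 10,000 permutations; type-I calibration uses 500
reads/element and the recovery check 2,000 reads/element (the latter so
that ~75–80% of guides clear the low-count filter, mirroring the high
recovery a well-covered screen achieves). Planted effects are
{−3, −2, +2, +3} with the default efficacy range. Decoding fidelity is
checked on a 1,000-element library with 10⁴ single-substitution reads.

## miRNA profiling toolkit

Cellular normalization divides each sample by the geometric mean of its
top-100 raw counts and rescales by the across-sample mean factor; the +1
offset inside the geometric mean is applied only when zeros occur among
the top-N, which keeps the transform exactly idempotent and exactly
depth-invariant (up to the single global mean factor) on positive data.
EV normalization divides each EV sample by its spike-in count and rescales
to the mean spike level, leaving the spike row constant. The detection
filter keeps miRNAs exceeding mean + 2 SD (sample SD, ddof = 1) of the
negative-control probes in **every** sample of a fraction — the
operationalisation chosen for "consistently detected above
signal-to-noise", with the multiplier exposed as a parameter.
Percent-of-control pairs experiments positionally, flags miRNAs with a
zero control count, and reports the across-experiment mean. ΔCt
quantitation is 2^−(Ct_target − Ct_reference).

## Known limitations

* The gene-effect likelihood is a reconstruction of the casTLE family of
  estimators from its published description, not a port; exact numerical
  agreement with other implementations is not expected, and differences
  are confined behind `gene_effect`.
* Greedy barcode design gives no guarantee of maximal set size, and the
  designed sets depend on the seed.
* The refinement step drops elements but does not automatically design
  replacement barcodes; `design_barcodes(avoid=...)` supports callers who
  need top-ups.
* sgRNAs are opaque random strings here — guide activity modelling and
  on/off-target scoring are out of scope.
* Hairpin defaults are placeholders (see above); no RNA secondary-
  structure prediction is performed on assembled hairpins.
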