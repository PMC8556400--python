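# Methods

## Scope and data model

`hicdelta` compares two conditions across the standard Hi-C readouts
(compartments, insulation/TADs, loops) and associates ChIP-seq peak changes
with differential expression. All contact analyses are cis-only; matrices
are stored dense per chromosome with 0-based bins and half-open intervals.
Reading/writing uses plain-text formats only: sparse upper-triangle count
triples (TSV) plus a bin table for matrices, BED/bedGraph/BEDPE for
intervals and tracks, JSON for planted truth and reports.

## Synthetic data generator

The generator is the package's study substrate: it plants structure that
the analysis stages must recover.

The expected count of a bin pair factorizes as

    E[count(i,j)] = scale · max(|i−j|,1)^(−α) · comp(i,j) · tad(i,j) · loop(i,j)

with Poisson sampling around the expectation and `scale` chosen so the
expected total equals the requested depth.

* `comp` multiplies homotypic pairs by the A–A or B–B multiplier (baseline
  1 + c_comp) and heterotypic pairs by 1 − c_comp; labels alternate in
  blocks (checkerboard, default 20 bins = 500 kb).
* `tad` attenuates a pair by (1 − d_ins) once, at the deepest boundary it
  crosses. Applying the attenuation per crossed boundary (multiplicatively)
  was rejected: it makes long-range signal decay with the boundary count,
  swamping the compartment checkerboard and rendering PC1 unrecoverable.
  With the max-rule, long-range pairs nearly all cross some boundary, so
  the attenuation is absorbed by the distance expectation and insulation
  remains a local feature, as in real data.
* `loop` multiplies a planted anchor pixel by k_loop with a 1-bin halo at
  half effect (so donut scores tolerate off-by-one anchor binning). Anchors
  are drawn 12–60 bins apart, pairwise separated by > 8 bins, and — a
  deliberate design choice — in locally homogeneous context, at least
  4 bins from any planted boundary or compartment edge. A focal enrichment
  superimposed on a structural discontinuity is not separately identifiable
  by a local-background filter (the flank maximum absorbs it), so loops in
  such context would be unrecoverable by construction; the generator
  therefore measures loop-calling performance where the question is well
  posed. Correspondingly, recall figures do not speak to loops at TAD
  corners in real data.

Default conditions: one 15-Mb chromosome at 25-kb bins, α = 1, c_comp =
0.5, d_ins = 0.6, 30 loops at k_loop = 4, and 5×10⁶ expected reads per
replicate (10⁷ pooled per condition) — the coverage class required for
single-pixel loop statistics at this resolution. The KO-like perturbation
scales A–A multipliers by 1 + ΔAA (default −0.2), B–B by 1 + ΔBB (+0.2),
insulation depths by 1 − Δins (Δins = 0.4), and drops a uniform 30% of
loops, recording the dropped set.

ChIP peaks get log-normal strengths; "weak" peaks (lowest 30% of strength)
collapse to flank background in condition 2 with probability 0.8 (strong
peaks 0.02). Expression tables flag genes within ±25 kb of a lost peak as
DE with probability `frac_linked` (default 0.8) against a 5% background;
adjusted p-values are drawn on the matching side of 0.05 so flags and
p-values agree by construction. Differential-binding p-values for the
synthetic chain come from a conditional binomial (Poisson exact) test on
pooled per-condition counts — a stand-in for whatever upstream
differential-binding caller a real analysis would use; the association
stage only consumes the p-value column.

TSS are placed uniformly by `make_genome`; `bias_tss_to_a` then re-places
75% of them into A-labelled bins. Without gene-rich A blocks the
TSS-density sign rule for PC1 orientation would be a coin flip.

## Normalization choices

Balancing is iterative correction (ICE): multiplicative per-bin weights
driving unmasked row sums to 1, tolerance 10⁻⁵, 200 iterations max. Bins
with zero marginal plus the lowest-coverage 1% per chromosome are masked
once, globally.

**Caveat that matters:** the KO-like perturbation (A–A down, B–B up, A–B
fixed) is within ~2% of a rank-1 row scaling, which is exactly the family
of transformations ICE removes. On balanced obs/exp the planted corner
signs are unrecoverable — for any block composition, the balanced
representatives of the baseline and perturbed class matrices differ only
at the percent level, in the same direction for both corners. Because the
generator has uniform bin visibility (there is no coverage bias to
correct), the pipeline quantifies compartments and intra-TAD contrast on
**raw-count obs/exp** (`ContactMatrix.obs_over_exp(balanced=False)`); the
mask from balancing still applies. For real data, where marginals mix
coverage bias with biology, balanced obs/exp is the appropriate default
and the same caveat applies in reverse: genuine uniform changes in
per-class contact totals are partially absorbed by balancing.

Insulation uses the balanced matrix (it is a local, ratio-based score and
insensitive to the above). P(s) curves use raw counts normalized to unit
sum, log-binned at factor 1.3, with the log-log derivative taken by central
differences after a 3-bin rolling mean.

## Analysis parameters

| stage | parameter | default | note |
|---|---|---|---|
| compartments | PC1 matrix | Pearson corr. of obs/exp | per chromosome, ≥10 unmasked bins |
| | saddle quantiles | 50 | corner = 20% (10 of 50) |
| insulation | window | 250 kb at 25-kb bins | diamond mean, log2 vs chromosome geometric mean |
| | boundary strength | > 0.1 | prominence: lower flanking max within ±window minus the minimum |
| boundaries | merge radius | 3 bins | greedy by strength desc., ties by position |
| TADs | overlap ratio | > 0.5 of the potential TAD | denominator = potential-TAD length |
| | min length | 6 bins | |
| | differential gate | p ≤ 0.05 and \|log2FC\| > 0.15 | paired two-sided t, pairing by replicate index; df = 1 with 2 replicates (low power by construction); no multiple-testing correction, deliberately |
| loops | IFnorm class | 10 kb | class mean over all pairs, zeros included |
| | donut p, w | 50 kb / 100 kb (function defaults); 25 kb / 75 kb in the pipeline | resolution-matched: at 25-kb bins the 25/75 geometry makes the peak square one planted loop + halo; the 50/100 square at this resolution dilutes a single-pixel loop below detectability |
| | null | values shuffled within distance classes, 200 permutations (100 in tests) | pixel called above the per-class 1−α null quantile; α = 0.01 |
| | differential | z on diff(score), \|z\| > 1.5 | sample sd (n−1); non-loop score = 1.0; common regions matched within 2 bins |
| chip | flanks | ±10 kb, peak bases subtracted, merged | shared flank bases counted once |
| | size factors | median-of-ratios | regions with any zero excluded |
| | downsampling | retention min(q)/q_x | binomial thinning; smallest-background sample kept whole |
| | gene window | TSS ± 25 kb | peak contributes −log10 p / n_c |
| | ventiles | 20 equal-rank bins | ties broken by gene id |
| enrichment | min term size | 10 | BH correction (a conservative stand-in for a π₀-fitted q-value) |

The mHG statistic is the minimum over rank prefixes of the hypergeometric
upper tail; its exact p-value comes from the O(N·B) lattice dynamic
programme (walk the list, track P(prefix length, successes) and absorb the
mass of states whose tail already beats the observed statistic). The
hypergeometric tail itself is summed in log space.

Donut-filter geometry is frozen in `donut_kernels`: peak |di|,|dj| ≤ p;
donut = annulus p < max(|di|,|dj|) ≤ w minus the width-1 cross arms;
vertical/horizontal flanks are the strips beyond p within the peak's
column/row band. The three flank estimates overlap spatially by design;
maxFlank takes their maximum. Scores are computed via summed-area-table
box sums, verified in the test suite against direct mask convolution.

## Determinism and numerics

Every stochastic step takes an explicit seed; the pipeline fans a single
seed out through named SHA-256 sub-seeds (< 2³¹) so stages are individually
reproducible. Degenerate inputs are reported, not guessed at: zero-variance
paired differences give an absent p and no flag; empty distance classes,
truncated donut geometry, and masked bins propagate as absent (NaN) values
excluded from aggregates; a structureless map yields an unreliable
compartment track instead of arbitrary labels.

## What passing tests do and do not show

The generator draws independent Poisson counts around a factorized
expectation. Real Hi-C libraries are overdispersed, carry fragment- and
mappability-driven coverage bias, trans contacts, and loops that sit at
TAD corners; none of these are emulated (no overdispersion knob in this
version). Recovery rates measured here (label agreement, boundary and loop
recall, differential-flag sensitivity) therefore characterize the
correctness and calibration of the procedures under their stated model,
not expected performance on sequencing data. Problem sizes in the test
suite and acceptance script (10-Mb chromosome, 100-permutation nulls,
3–10 simulation seeds per check) were chosen as the smallest instances at
which the planted effects are comfortably identifiable.
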