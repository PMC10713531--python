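# Methods

This note documents the statistical procedures, defaults, and design
choices behind `proxirank`, and what the synthetic fixtures do and do not
establish about real data.

## Input model and identity

The pipeline consumes protein-group tables in the MaxQuant dialect
(tab-separated; identifier, unique-peptide count, contaminant/reverse
flags, one value column per channel). Column names are configurable per
design file because export settings vary between searches; the defaults
are `Protein IDs`, `Unique peptides`, `Potential contaminant`, `Reverse`
and `Reporter intensity corrected <i>`. A reporter intensity of 0 or an
empty cell is recorded as missing (MaxQuant emits 0 for undetected
reporters); an H/L ratio is missing only when empty. All cross-table set
operations key on the *leading accession* (first semicolon-separated token
of the group id), because protein-group memberships drift between searches
while the leading accession is stable.

Standard pre-filters: contaminant and reverse-decoy rows are removed, and
proteins must carry at least 2 unique peptides. Both filters are
idempotent subsets and commute; the suite verifies this property-based.

## Dimethyl branch

Each pairwise experiment compares a heavy (anti-NFASC) sample to a light
control (-1Ab, NeuN, or MAP2) as a per-protein H/L ratio, in triplicate.
Rules, applied after the pre-filters:

* coverage — quantified in ≥ 2 of 3 replicates (the boundary case, exactly
  2, is kept);
* -1Ab cutoff — H/L strictly > 1.5 in *every replicate where quantified*,
  combined with the coverage rule. The cutoff is per-replicate; a protein
  missing in one replicate is not auto-excluded, since coverage is policed
  separately;
* three-way intersection of the surviving id sets.

Reference-pair ratios are normalized by subtracting the per-column median
of log₂(H/L) ("median centering"): the bulk of unenriched proteins then
sits at 0, and enrichment is read as a shift. The centering statistic is
the median (50th percentile, linear interpolation for even counts); a
mean-centering alternative is exposed via the `center="mean"` switch.
Averaged normalized ratios are arithmetic means over non-missing
replicates.

## TMT ranking branch

Condition-level quantities default to **ratio of means**: replicate
channels of a condition are averaged (skipping missing channels; a
condition is missing only when all its channels are), and ratios are
formed from the condition means. This is stabler than mean-of-ratios when
reference conditions carry duplicate channels; a `mean_of_ratios` mode
(geometric mean of per-replicate log ratios, wrapping replicate pairing)
is available for designs where per-replicate pairing is meaningful.

Filters and ranking:

* negative-control filter: mean(NFASC)/mean(-BP) > 2 **and**
  mean(NFASC)/mean(-1Ab) > 2, strict inequalities. A protein detected in
  NFASC but missing from a negative passes that negative's test (the
  ratio is effectively infinite); a protein undetected in NFASC cannot
  pass.
* per-reference enrichment: log₂(mean(NFASC)/mean(ref)), median-centered
  per column over its finite values. A protein detected in NFASC but not
  in a reference receives +∞ and therefore rank 1 in that reference —
  the most favorable reading, consistent with retaining NFASC-only
  detections in the developmental branch.
* ranks: descending per reference. Two rank variants are kept: fractional
  ranks (ties share the mean of the tied positions) feed the average rank
  score; integer ranks (residual ties broken by leading-accession
  lexicographic order) make each column an exact permutation of 1..n and
  the output order-independent and deterministic.
* overall rank: ascending rank of the mean of the three fractional
  per-reference ranks, ties again broken lexicographically.
* high-confidence set: intersection of the per-reference top-N lists
  (default N = 200, applied after the negative filter). N larger than the
  table falls back to the full table with a warning.

Replicate reproducibility is reported as squared Pearson correlation on
log₁₀ intensities over proteins quantified in both channels of a pair
(MS intensities are approximately log-normal, so the correlation is
computed on the log scale), together with the common-element count.

Median centering makes all ranks invariant to a global intensity rescaling
and to row order; both invariances are tested.

## Developmental branch

Two 10-plex experiments bridge three stages (TMT1: DIV7 + DIV14; TMT2:
DIV21 + DIV14), each stage with 2×NFASC, -1Ab, NeuN, MAP2 channels.

* Stage filter: mean over NFASC replicates of log₂(NFASC) − log₂(-1Ab)
  strictly above the stage cutoff — 3.5 at DIV7/DIV21, 1 at DIV14 (the
  looser DIV14 cutoff reflects the different background separation in
  those runs, calibrated on the endogenous-biotin distribution). Proteins
  detected in NFASC but absent from -1Ab are retained outright.
* The DIV7, both DIV14, DIV21 (and optionally a prior standalone DIV14)
  id sets are intersected.
* PCCA anchoring: every NFASC channel is rescaled so the endogenously
  biotinylated carboxylase PCCA (default accession `P14882`, a config
  field) equals 1. PCCA is captured at full strength regardless of
  labeling, so it serves as a per-channel loading control; anchoring is
  idempotent and commutes with per-channel rescaling. No additional
  inter-experiment batch factor is fit — the DIV14 bridge plus the anchor
  is the only cross-experiment normalization.
* Change filter: a protein is dynamic when max/min of its three
  PCCA-anchored stage means exceeds 1.2 (strict); the criterion is
  symmetric in stage order and scale-invariant. The alternative
  earlier-stage-relative reading (|a−b|/a > 0.2) is available via a
  switch. The 549→534-style filtering operates on anchored values.
* Profiles are z-scored per protein across the three stages (population
  SD; numerically constant profiles map to zero), then clustered by
  agglomerative hierarchical clustering, Euclidean distance, complete
  linkage, tree cut into exactly k = 6 clusters — the default behavior of
  R's `hclust`/`cutree` used by heatmap packages; distance, linkage and k
  are configurable. Cluster ids are relabeled 1..k by descending size
  (ties by first appearance) so output labels are deterministic. Cluster
  summaries report size, percentage of clustered proteins (always summing
  to 100%) and a trend label (monotone-up / monotone-down / peaked) from
  the cluster's mean z-profile.
* Volcano statistics: per protein, log₂FC = log₂(mean_b/mean_a) of
  anchored intensities and a pooled-variance (Student) unpaired two-tailed
  t-test on log₂ values; calls `up`/`down` require |log₂FC| > 1 and
  p < 0.05. DIV14 pools all four NFASC channels across the two
  experiments — n = 2 per experiment admits no within-stage test, so
  pooling is the only computable reading. Degenerate zero-variance groups:
  equal means give p = 1; unequal means give the smallest positive float
  with a warning. Swapping the stage order negates every fold change and
  leaves p-values unchanged (tested).

## Imaging metrics

Corrected mean fluorescence (CMF) is region mean minus same-image
background; negative CMF is returned with a warning. Specificity
(AIS/soma) and polarity (AIS/dendrite) are CMF ratios, undefined (error)
for non-positive denominators, and invariant to a shared additive offset.

Periodicity: local maxima of a line profile are detected with
`scipy.signal.find_peaks` using a prominence floor of 20% of the profile's
interquartile intensity range and a minimum separation of 100 nm —
safely below any plausible spectrin-skeleton period (~190 nm) yet high
enough to reject noise wiggles; both thresholds are configurable because
any automated criterion only approximates a manual maximum-to-maximum
reading. The reported value is the mean of successive peak-to-peak
distances times the pixel size. No subpixel interpolation by default; an
optional 3-point parabolic refinement helps when the pixel size does not
divide the period. The metric is invariant to amplitude scaling and to
reversing the profile.

## Synthetic study conditions

The generators emulate the designs above: base abundances are log-normal
(log₁₀ mean 6, SD 0.8 — a typical proteinGroups dynamic range; only the
relative structure matters downstream), AIS proteins are enriched
8-fold in NFASC channels, reference-enriched proteins 4-fold in their own
reference, negative channels receive 10% of each protein's abundance
(non-specific adsorption) plus the full endogenous-biotin signal, channel
noise is multiplicative log-normal with SD 0.25 on the log₂ scale,
values drop to missing at rate 0.02 (the PCCA anchor is exempt — it is
the loading control), and decoy rows are flagged half contaminant, half
reverse. A 5% sliver of background rows carries a single unique peptide to
exercise the peptide floor. Dimethyl fixtures put background and
endogenous-biotin proteins at H/L ≈ 1 everywhere, AIS proteins at the
planted fold against references and fold/background-fraction against
-1Ab, and compartment-enriched proteins *depleted* against their own
reference — in the anti-NFASC vs -1Ab comparison a non-AIS protein's
capture is pure background on both sides, so only AIS proteins clear the
1.5 cutoff. Developmental fixtures assign planted proteins to six
expression templates (up, down, peak/dip at DIV14, late-up, early-down)
as NFASC-channel multipliers.

Every generator is a pure function of its spec (including the seed) and
emits ground-truth labels; recovery tests compare pipeline output to
those labels, never to hard-coded lists.

**What passing tests show.** Planted-signal recovery, partition recovery
and type-I calibration demonstrate that the implemented statistics do what
they claim under the generative model: log-normal noise, multiplicative
enrichment, missingness at random. Real proximity-labeling data add
features the generator does not model — intensity-dependent missingness,
ratio compression from TMT co-isolation interference, correlated
peptide-level noise, protein-inference ambiguity — so synthetic recovery
rates are upper bounds, not estimates, of performance on real tables. The
published filter-chain counts can only be checked against the original
deposited tables (see README).

## Problem sizes and numerical notes

Default test and acceptance problem sizes — 2000 background proteins, 20
planted AIS proteins, 60 developmental profiles, 1000 null proteins for
calibration, 12-period line profiles — are chosen so every planted effect
is comfortably detectable at the stated noise levels while the whole suite
runs in seconds; they mirror the scale of the corresponding real designs
(a few thousand quantified proteins per 10-plex).

All cutoffs are strict inequalities; boundary-equal values are excluded.
Medians use linear interpolation for even counts. Infinite sentinels never
enter a median. Ties anywhere resolve by leading-accession lexicographic
order, making every output a deterministic function of the input set, not
its order.
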