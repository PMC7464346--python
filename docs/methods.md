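# Methods

## The classification procedure

The pipeline treats a serum ESI-MS profile as a vector of unit-m/z peak
areas and asks whether two groups of sera separate when each sample is
classified, peak by peak, against statistics built without it.

**Preprocessing.** Profile traces (m/z 400–2000) are normalized so every
non-overlapping 10-m/z window sums to 100 intensity units; windows are
half-open `[a, a+10)` anchored at the low end of the mass range (the anchor
is configurable — the convention has to be fixed somewhere, and the range
start is the only natural choice). Windows with zero raw signal stay zero
rather than becoming 0/0. Peaks are then centroided valley to valley:
interior local intensity minima, runs of zeros and the trace endpoints
delimit peaks; the area is the trapezoidal integral between valleys and the
centroid the intensity-weighted mean m/z. Centroids are assigned to unit
bins by `floor(centroid)`; co-binned areas are summed and the three
replicate maps averaged arithmetically, a bin absent from a replicate
counting as area 0. The full sequence is applied identically to every
sample; normalization precedes centroiding.

**Per-fold statistics.** Within a fold (one sample held out), each bin is
screened with a pooled-variance two-sample Student's *t*-test, one-tailed
in the direction of the observed left-in difference — equivalent to
two-sided screening at 2α. No multiple-testing correction is applied; the
per-peak α = 0.05 threshold is used as such, since the procedure aggregates
peaks rather than interpreting them individually. Each significant bin
receives a *peak classification value* (PCV). The PCV formula is a genuine
design point: we use the midpoint of the two left-in group means — the
simplest threshold that lies between the means, with the higher side owned
by the higher-mean group — and expose it so alternatives (e.g. a
pooled-SD-weighted boundary) can be swapped in. Ties at the PCV go to the
non-owner group ("at or below" is a non-disease call). Bins with zero
variance in both groups and equal means are uninformative and excluded. A
held-out sample missing a significant bin entirely is scored with area 0
there.

**Scores, cut-off, metrics.** A sample's % LOOCV score is the percentage
of significant peaks at which it classifies into the disease group, so
swapping the disease label maps every score s → 100 − s exactly. The group
cut-off sits an equal number of group-specific SDs from each score mean:
k = (m_hi − m_lo)/(s_hi + s_lo), cutoff = m_hi − k·s_hi. The cut-off is
evaluated with the exact multiplier — so the two SD-distances agree by
construction — and both k and the cut-off are reported rounded to two
decimals. (Rounding k *before* placing the cut-off changes the full-cohort
worked example from 41.71 to 41.73 against a published 41.68 computed from
unrounded data; evaluating exactly is both principled and closer.) If both
SDs are zero the cut-off degrades to the midpoint of the means and k is
undefined. Cohen's d uses the root-mean-square of the two SDs,
d = |m₁ − m₂| / √((s₁²+s₂²)/2) — the only standard variant that reproduces
all four published effect sizes (5.46, 6.52, 7.66, 2.43) from the printed
means/SDs; the pooled, df-weighted variant gives 5.26 for the first of
them. The ROC AUC is the rank-sum formulation (ties count ½), invariant
under monotone score transforms.

**Separation p-value.** The run-level p-value is a pooled Student's
*t*-test on the two groups' scores, one-tailed in the disease > control
direction. The directional choice matters: leave-one-out with per-fold
feature selection is biased *against* the held-out sample — selection
conditions on bins where that sample's absence made the left-in difference
look large, so under the null (shuffled labels, or no true effect) held-out
samples systematically classify into the opposite group and the score gap
*inverts*. A two-tailed test flags these inverted separations as
significant; the directional test correctly reports them as null, at the
cost of halving the p-value of a real separation. The agnostic two-sided
variant remains available (`group_separation_pvalue(..., alternative=...)`,
`run_loocv(..., p_alternative=...)`). Even one-tailed, the randomized-label
p-value is a diagnostic, not a calibrated test: scores are correlated
across folds (any two folds share all but two training samples), and a
shuffle retains residual signal proportional to its chance overlap with the
true labels (hypergeometric SD ≈ 1.6 samples for 29 + 17), so occasional
shuffled p < 0.05 occur even when the score clouds visibly overlap. In
repeated experiments at the default conditions, roughly 85% of shuffles
exceed p = 0.05.

**Blind and cross-group classification.** Blind samples are scored against
significant peaks and PCVs derived once from the full training set (no
leave-out — the blind sample never enters the statistics) and called
disease above the training cut-off. A third cohort is handled the same way
against a two-group classifier built from all A and B samples, then placed
on a side of the A-vs-B cut-off.

**Degenerate folds** (no significant peak) leave the sample's score
undefined (NaN); they are flagged, logged, and excluded from the score
summaries, cut-off and metrics, and the run continues.

## The synthetic cohort generator

The generator emulates the study design: two groups (defaults 29 vs 17,
the published cohort sizes), three profile spectra per sample over m/z
400–2000, 160 occupied unit-m/z bins of which 110 differ between groups
(the published analyses used 106–118 significant peaks). Demographics
default to the published table (66% vs 41% male; ages 26.9 (7.2) vs
34.0 (9.2) years) and feed only the randomization module's balancing.

Per-bin baseline areas are log-normal across the spectrum (median 50 area
units, log-SD 0.5 — the absolute scale cancels under segment
normalization). Sample-level areas multiply the baseline by a log-normal
factor with log-SD `base_sigma_log`; group effects are multiplicative, a
`effect_log2` fold change applied to the higher group at each
discriminative bin (direction drawn per bin) *before* replicate noise;
replicate noise is log-normal with linear-scale CV `replicate_cv` (default
0.08, a typical replicate-injection CV). Serum ion intensities are strictly
positive and right-skewed, which motivates the multiplicative model
throughout; the true distribution of serum peak areas is not documented,
so the log-normal is a modelling stand-in, not an inference.

`base_sigma_log` defaults to 0.8. This was calibrated against the
published score summaries: with much smaller sample-level variability the
synthetic LOOCV scores come out near 85%/15% with Cohen's d ≈ 19 —
far cleaner than the published 55.09 (4.84) vs 31.81 (3.58), d = 5.46 —
while log-SD 0.8 yields 75.6/23.7, d ≈ 14, and 113–117 peaks used per
fold, inside the published 106–118 band, and still recovers ≥ 80% of
ground-truth bins in every fold. Larger values (1.0–1.2) match the
published effect size even better but drop per-fold recovery below 80%.

Two geometric choices are forced by the normalization step. A lone peak in
a 10-m/z window would be rescaled to exactly 100 units in every sample,
erasing any between-group difference, so the generator clusters peaks (up
to 4 per occupied window, mimicking real serum spectra where every window
holds many ions) and keeps at least one non-discriminative "anchor" bin
per window whenever the counts allow, letting fold changes survive as
share changes. And ions are rendered at bin *centers* (b + 0.5 under floor
binning) at window offsets 1–8, so no peak straddles a window boundary and
no centroid sits on a bin edge where a rounding error could flip its bin.

Rendered peaks are Gaussians (σ = 0.15 m/z, sampled at 0.05 m/z) whose
numeric integral equals the requested area; unit-spaced ions remain
valley-separated (adjacent tails overlap below 0.5% of amplitude at the
midpoint). The simulator deliberately omits chemical noise, isotope
envelopes, charge states and instrument resolution functions — so passing
tests demonstrate the *procedure* recovers planted multiplicative effects
under log-normal noise, not that it would perform identically on real
serum spectra with correlated chemical background.

## The randomization control

Labels are permuted uniformly within sex strata, which preserves group
sizes and per-group sex counts exactly; the first draw whose per-group age
means fall within `age_tol` (default 5 years) of the originals is
accepted, with a bounded retry and a best-effort fallback (flagged) when
the tolerance is unreachable. The published control was a single shuffle;
`--n-reps` extends it to a null-distribution characterization and is
flagged as an extension.

## Numerical and interface choices

- Unit-m/z binning uses `floor(centroid / width)` with a 10⁻⁶ guard for
  centroids a rounding error below a bin edge.
- Replicate counts other than 3 are averaged with a warning rather than
  rejected; pre-centroided peak tables (CSV) can bypass centroiding
  entirely, which is how lower-resolution instrument data enters.
- The centroid noise floor (`min_area`) defaults to 0; the valley-detection
  floor of the original vendor software is undocumented, so it is exposed
  as a knob.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configs are bit-reproducible.
- Test-suite problem sizes: the study-sized cohort (29 vs 17, 160 bins) is
  generated once per session; oracle-equivalence checks run 1000 random
  small instances per statistic; the shuffle control uses 20 seeds.

## Known limitations

- The PCV formula and the exact test behind the published run-level
  p-values are not documented in the source material; the midpoint PCV and
  the pooled t on scores are this package's choices, exposed as options.
- The randomized-label p-value inherits the selection-bias inversion and
  fold-correlation effects described above; treat it as a qualitative
  over-fitting diagnostic (do the score clouds overlap?) rather than a
  calibrated error rate.
- Published headline numbers that depend on the undeposited patient
  spectra (the 4.6 × 10⁻²² separation, the specific 106–118 peak list, the
  9/10 blind calls) are reproducible only in structure, not in value.
- The simulator's independence assumptions (bins independent given the
  window, samples i.i.d. within group) understate the correlation of real
  serum spectra.
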