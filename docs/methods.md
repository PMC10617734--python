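# Methods notes

## Data model and time conventions

A record is a sequence of half-open 30-min bins of non-negative integer
beam-break counts, labelled by bin start time. Time is tracked in hours
since recording start; circadian time (CT) = `start_ct` + elapsed, with
CT 0 = subjective dawn from the pre-recording LD 12:12 entrainment.
Subjective day is CT 0–12 (mod 24), subjective night CT 12–24; the
anchor is configurable per collection but defaults to this convention,
which is also what ties the half-day segmentation of the zero-run
inclusion rule and the amplitude segments to CT rather than to the
record start.

## Trimming and inclusion

Leading all-zero bins are removed entirely (the CT anchor advances by
the removed duration). A trailing zero run longer than 12 h is
truncated so that exactly 12 h (24 bins) of zeros remain — a literal
reading of "trimmed after 12 h of zeros"; the retained allowance is
configurable. Trimming is idempotent and never alters a retained count.
Inclusion requires trimmed duration ≥ 5 × 12.4 h = 62 h (the duration
proxy for "five tidal cycles" — the only operationalisation available
without visual scoring, and flagged as such in the QC report), total
counts ≥ 400, and no run of more than five consecutive all-zero CT-aligned
half-days. Partial edge half-days count toward the zero-run rule when
the covered part is all zero.

## CLEAN spectral estimation

The mean-subtracted series is Fourier-transformed onto a frequency grid
oversampled 4× relative to the natural resolution 1/T, covering periods
from 4 h up to min(50 h, T/2) (the long-period edge is bracketed by one
extra grid frequency so the reported grid spans the full range). The
spectral window of the sampling pattern is computed on the doubled
grid. CLEAN then iterates: find the largest residual amplitude, estimate
its complex component accounting for the mirrored negative frequency,
subtract `gain` (default 0.5) times that component convolved with the
window, and accumulate it. Iteration stops at `max_iter` (default 100)
or when the residual peak drops below `stop_sigma` (default 2.0) times
the residual RMS — for pure noise that floor is reached immediately, so
noise spectra are essentially the dirty spectra. Components are restored
with a Gaussian beam of FWHM 1/T and the final residual is added; the
reported density is the squared amplitude of the restored spectrum.
Densities are computed batched across series (the original plus its
shuffles share the transform basis), which is what makes the
400-replicate calibration runs cheap.

The peak period handed to classification is refined by parabolic
interpolation of the density in frequency around the grid maximum;
without it the cohort mean period would inherit up to half a grid step
(~0.1 h at 12.4 h for 8-day records) of discretisation bias.

## Randomization null

The null is the unrestricted random permutation of bin counts: it
destroys all temporal structure while preserving the marginal count
distribution, which is the natural reading of "random iterations of the
original data" for count series (phase randomization would instead
preserve the full spectrum modulus; the choice is configurable). The
99% confidence limit is a single global value — the 0.99 quantile,
linearly interpolated between the two largest order statistics, of the
100 per-shuffle spectral maxima — i.e. family-wise over the whole grid,
matching the single dotted confidence line of conventional spectral
plots. Because the original series is exchangeable with its shuffles
under the null, the unshuffled maximum exceeds CL₉₉ in ≈2% of pure-noise
records (the interpolated quantile of 100 maxima sits slightly below the
ideal 99th percentile); the calibration check accepts 0–4%.

## Correlogram

Biased (divide-by-N) normalization keeps |r| ≤ 1 and matches the
large-sample white-noise band ±2.576/√N used as the constant 99% line.
A consequence worth knowing: the correlogram of a finite cosine carries
a (1 − k/N) taper, so per-cycle peak-to-trough amplitudes decay
linearly with lag even without noise; they are equal only after
dividing the taper out. Peaks and troughs are picked on a 3-bin
moving-average smoothed copy (raw correlograms of count data are
jagged), ties to the smaller lag; reported r values are unsmoothed.
"Consistent period" between the two analyses means within 10%
(configurable) of the spectral period or of twice it — the doublet lag
may carry the significant autocorrelation for a circatidal call. The
10% default cleanly separates 12.4 h from 24.8 h.

## Classification

Band peaks are strict local maxima of the density within the circatidal
(10–14 h) and circalunidian (20–28 h) bands — wider than the observed
12–13 h / 24–26 h ranges so knockdown-shifted periods stay inside.
Doublet power strictly greater than singlet power switches the call to
the doublet with period halved; an exact tie keeps the singlet.
Rhythmic requires power > 1 *and* autocorrelation support. Arrhythmic
animals report max(singlet, doublet) power; when neither band contains
a local maximum ("no obvious peak", operationalised exactly as that),
the density at 12.4 h over CL₉₉ is reported with a fallback flag.

## Phenotypes

Segment amplitudes use only full 12-h CT-aligned segments (partial edge
segments carry no meaningful peak), at most 16 per animal. All-zero
segments substitute 1 → log₁₀ = 0. The adjusted amplitude is
log₁₀(peak − min) per segment; the alternative reading
(log₁₀ peak − log₁₀ min) sits behind a flag. MI is the mean over all
(night, following day) consecutive pairs — the minimal aggregation
consistent with a per-animal index; rows with no complete pair are
flagged undefined rather than zero-filled. Tidal pooling shifts each
record so bin 0 is the first high tide at or after its recording start
(the reference tide is per-record, so collections with different tide
phases superpose constructively) and averages across animals per bin.

## Cohort statistics

Unbalanced two-way ANOVAs use Type II sums of squares (robust for main
effects when the interaction is small; Type III available behind the
statsmodels fit). η² = SS_term/SS_total, with partial η² also emitted.
Dunnett many-to-one and Tukey all-pairs come from scipy's multivariate-t
implementations. The normality screen runs Anderson–Darling,
D'Agostino–Pearson (n ≥ 20), Shapiro–Wilk and Lilliefors-corrected
Kolmogorov–Smirnov; pass = at least two tests with p > 0.05, failing
conservatively for constant or tiny samples. Contingency tests compute
Pearson χ² (headline), the G statistic, and a hand-written exact
conditional test for 2×k tables (enumeration over tables with fixed
margins, summing probabilities ≤ the observed table's); all three are
reported side by side because published analyses label these tests
loosely.

## Synthetic cohorts

The generator emulates what the analysis assumes about real records:
rate λ(t) = baseline + amplitude · [(1−w)·h(t; τ) + w·h(t; 2τ)] ·
(1 + M·night(t)), with h a half-wave-rectified cosine raised to
`waveform_sharpness` (sharpness 2 gives realistically peaked swimming
bouts), counts Poisson per bin, phases jittered ±1 h around the
collection's tide phase, exponential dropout producing the trailing
zeros that exercise trimming, and a fraction of animals flattened to
their time-average rate (arrhythmic at matched mean). The circalunidian
period is locked to exactly twice the tidal period, which is what makes
the doublet-halving identity exact. Defaults — peak rate 60 events/bin
(≈ 2.0 log₁₀ night amplitude), M = 1.5 (night ≈ 2.5× day, MI ≈ 0.3),
lunidian weight 0.2, 10% arrhythmic, 8-day records from CT 96, mean
dropout 150 h — reflect a summer control cohort of the kind the
pipeline targets; knockdown-like groups are expressed as multiplicative
`GroupEffect`s.

What the generator does not model: the seasonal circatidal/circalunidian
switching seen in real profiles, temperature effects, overdispersion
beyond Poisson (a parameter slot exists but the default is pure
Poisson), and within-animal period drift. Passing tests therefore show
the pipeline recovers the assumed structure, not that real data satisfy
those assumptions.

One subtlety: with the lunidian component present (w > 0), its 24.8-h
peaks beat against the 24-h day/night grid with a ~15-day beat period,
so over an 8-day record the cohort mean MI at M = 0 is biased by
~0.09 rather than ~0. The unbiasedness check therefore uses the
pure-tidal construction (w = 0), where day/night symmetry holds by
construction; defaults are unchanged.

## Problem sizes and determinism

Validation runs use 50-animal cohorts for period recovery and
false-positive rates, 400 replicates at 4-day length and 2× oversampling
for null calibration, and 100 shuffles throughout — sizes at which the
Monte-Carlo error is comfortably inside the asserted tolerances.
All randomness flows from explicit integer seeds (`numpy`
`SeedSequence`-derived per-animal substreams, so results are independent
of cohort ordering); repeated runs are bit-identical.

## Known limitations

- The duration proxy for "five tidal cycles" admits animals with long
  quiescent gaps that a visual actogram reading might exclude.
- The exact-conditional contingency test enumerates tables; it is
  exponential in k and intended for k ≤ 4 groups.
- Dunnett p-values depend on the multivariate-t quantile implementation
  and may differ from other software in the third decimal.
- The spectral grid is uniform in frequency, so period resolution
  degrades toward long periods; circalunidian peaks are localised about
  4× less precisely than circatidal ones at equal record length.
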