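# Methods

This note documents the models and procedures behind `cachalot`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not establish about real recordings.

## The acoustic size model

A sperm whale click is a decaying pulse packet p0, p1, p2, … generated by
reverberation in the spermaceti organ; p1 carries most of the energy. The
inter-pulse interval (IPI) is the p1→p2 delay and scales with head, hence
body, length. Two published regressions convert IPI (ms) to animal size AS
(m): a quadratic for animals under 11 m (stated valid for IPI < 4.250 ms)
and a linear fit for animals over 11 m (stated valid for IPI > 4.184 ms).
The stated limits overlap; `size_from_ipi` switches strictly at 4.250 ms.
Over the doubly-covered interval the two curves differ by at most 0.105 m
(at 4.184 ms: 10.895 vs 10.999 m), so the choice of switch point moves no
animal across a class boundary and changes nearest-metre roundings not at
all. The hard switch does make the forward map jump from 10.990 to
11.083 m at 4.250 ms; lengths inside that 9 cm band have no exact
preimage, and the inverse (`ipi_from_size`, used by the generator — smaller
quadratic root, the physical branch) maps them to the switch point. Outside
the band the round-trip is exact to 1e-9 m over 5.5–20 m.

Class thresholds: immature below 2.9 ms (< 9 m), adult female or juvenile
male from 2.9 to 5.0 ms inclusive (9–12 m), adult male above 5.0 ms
(> 12 m). Equality at a threshold is assigned to the middle class; the
boundary IPIs map through the conversion to 9.04 and 12.03 m.

Per-individual estimates average up to ten per-click measurements, sampled
evenly across the recording (the field protocol reads the beginning, middle
and end to avoid surface-echo contamination). Means below 2.0 ms are
rejected — a prolonged p1 can fake a short interval — unless the presence
of a calf was confirmed visually, in which case the estimate stands (a
1.90 ms animal converts to 7.59 m). Estimates carry warning flags when
fewer than ten measurements were usable or their SD exceeds 0.2 ms.

## Per-click IPI measurement

The primary estimator is the envelope method: the magnitude of the analytic
signal, smoothed with a short moving window; the IPI is the sub-sample
(parabolically interpolated) distance from the dominant peak p1 to the
secondary peak p2 within a 1–10 ms search window (10 ms bounds the largest
plausible head). A bare "largest subsequent peak" rule is not robust at low
SNR — with noise at 10 dB below the p1 peak, background envelope excursions
regularly outgrow the ~0.45-relative p2 — so three layers make the
measurement conservative rather than wrong:

* the waveform is band-passed to 3–7 kHz, the band holding the click's
  dominant energy, before envelope extraction (~9 dB of processing gain
  against broadband noise);
* the p2 search is anchored by the peak lag of the envelope
  autocorrelation, which pools evidence from every pulse pair in the packet
  (p0·p1, p1·p2, p2·p3) instead of a single amplitude comparison;
* the candidate is accepted only if a corroborating pulse is visible — p0
  one interval before p1 or p3 one interval after p2, three robust sigmas
  above the envelope background — and the measurement is stable to within
  0.08 ms across smoothing scales of 0.15, 0.25 and 0.35 ms (noise peaks
  are scale-unstable; pulses are not).

A measurement failing any gate, or with p2/p1 quality below 0.1, returns
nothing — the automated analogue of only recording intervals whose pulses
are clearly visible. At 10 dB SNR roughly half of single clicks are
measurable and the measured ones carry a mean absolute error near 0.04 ms;
at 20 dB essentially all clicks pass with ~0.01 ms error; on noiseless
clicks the estimate is exact to well under one sample at 96 kHz. Sub-2-ms
intervals are deliberately measurable here; the floor is applied at the
averaging stage where the calf override lives.

The independent cross-check is the real cepstrum of a Hann-windowed
segment around the click: a pulse repeated at delay d ripples the log
spectrum with period 1/d, concentrating at quefrency d. The cepstral peak
must stand eight robust sigmas above the in-band cepstral background; on
clean clicks the two methods agree to ~0.001 ms across 2–7.5 ms. The two
paths share no code beyond the windowing.

## Detection and the click-train ethogram

Recordings are high-pass filtered at 1 kHz (order-4 Butterworth, applied
forward-backward so click times do not shift; two-pass attenuation at
500 Hz is ~48 dB and the passband above 2 kHz is flat to well under 1 dB).
Detection thresholds the smoothed envelope at median + k·1.4826·MAD with
k = 6; the 1.4826 factor makes the MAD a consistent sigma estimate, keeping
the false-alarm rate on pure noise negligible. Envelope peaks closer than a
2 ms refractory are merged by the peak finder, and peaks within 10 ms of
each other — the span of one multipulse packet, since no IPI exceeds
7.8 ms — are grouped into a single click event timed at the strongest pulse
(p1). Stereo recordings are detected per channel and deduplicated within
0.5 ms, keeping the higher-SNR event. On synthetic trains at 12 dB SNR the
detector's recall and precision both exceed 0.99 over 550 clicks.

Trains are split wherever the gap between clicks exceeds 2.0 s (the top of
the regular-click ICI range) and classified by a fixed priority: **coda**
if 3–20 clicks spanning 0.2–2 s with median ICI under 0.5 s; else **buzz**
if the median ICI lies in [0.02, 0.2] s; else **regular** if it lies in
[0.5, 2] s; else unknown. The priority resolves the genuine overlap between
short fast trains and buzzes in the coda's favour. One ambiguity is
irreducible without rhythm templates: a sparse coda (say four clicks over
1.7 s) has a median ICI inside the regular regime and is indistinguishable
from a brief regular series by count, duration and ICI alone; the
classifier calls it regular, and synthetic tests that demand exact recovery
draw codas with median ICI below 0.5 s.

Behaviour decoding: hunting requires at least one regular train **and** at
least one buzz (search plus capture attempt); socialising requires a coda;
moving and resting are assigned only from visual notes. Behaviours can
co-occur on one aggregation.

## Aggregations and habitat attributes

Same-day sightings within 1 km of each other form one aggregation.
"Within 1 km of each other" is implemented as single-linkage connected
components — chaining allowed, matching the field practice of merging
nearby GPS points taken for sub-groups — with complete linkage available as
an option. Distances are haversine on a 6,371,000 m sphere. The
implementation (sparse-graph connected components) is tested against a
brute-force BFS oracle on hundreds of random instances.

Depth at a point is bilinear in the four surrounding cells, degrading to
nearest-cell beside missing (land) cells. Slope over a 500 m window is
100·|∇depth| from central differences at ±250 m north-south and east-west,
classed light (< 10 %), medium (10–20 %), steep (≥ 20 %). If along either
axis the two half-window slopes both exceed 5 % with opposite signs the
point sits on a plateau between opposing inclines — a shelf edge — and no
single slope exists: the attribute is undefined and such points drop out of
slope analyses only. Distance to coast densifies the coastline polyline to
≤ 50 m vertex spacing before taking the minimum haversine distance, so the
result is accurate to better than 100 m regardless of input vertex spacing.
One geometric caveat: on a lat/lon grid the east-west metre width of a cell
varies with latitude, so a ramp built to be exactly 20 % at the grid origin
can measure 19.99 % a few kilometres away — relevant only when a value sits
exactly on a class boundary.

## The statistical battery

All tests are two-sided at α = 0.05. Group comparisons use the
pooled-variance t (the coefficient test of a one-factor linear model), not
Welch. Count models are log-link Poisson GLMs; overdispersion is checked as
Pearson χ² over residual df with an upper-tail χ² p (the ratio is near 1
for equidispersed data and its df equals observations minus parameters —
e.g. 19 aggregations and 2 parameters give 17). Term significance uses
Type-II analysis of deviance (likelihood-ratio against the term-dropped
model; rank-deficient designs are rejected). Permutation tests permute
response rows against the fixed design, recompute the model F via an
orthonormal basis of the centred design (vectorised over all resamples),
and report p = (1 + #{F\* ≥ F}) / (B + 1) with B = 1,000 by default — the
add-one convention bounds p away from zero and the seeded generator makes p
exactly reproducible. Holm's step-down is the multiple-comparison
correction for pairwise contrast matrices; adjusted p-values are reported
alongside raw ones. Normality of residuals is Shapiro–Wilk (3 ≤ n ≤ 5000).
Type-I error of the permutation test calibrates to 0.03–0.07 at α = 0.05
across 500 null datasets, and null p-values of the deviance and
Shapiro–Wilk tests are uniform across seeded replicates.

## The synthetic-data generator

The generator exists so every stage is testable against exact truth.

* **Clicks**: each pulse is a Gaussian-windowed 5 kHz tone burst (band
  2–8 kHz, ~0.5 ms long); pulse amplitudes default to (0.3, 1.0, 0.45, 0.2)
  relative to p1, a monotone decay after the dominant pulse. Ambient noise
  is white Gaussian; SNR is defined as p1 peak amplitude over noise RMS in
  dB (infinite = noiseless), with an optional low-frequency "vessel"
  component to exercise the high-pass stage. Pulse centres sit at exact
  sample-grid multiples of the IPI, so truth is exact.
* **Trains**: ICIs drawn uniformly inside the requested regime (regular
  0.5–2 s, buzz 0.02–0.2 s); codas fix total duration (0.2–2 s, 3–20
  clicks) and rescale the drawn intervals to it. Emitted click times equal
  the returned truth exactly.
* **Bathymetry**: a piecewise-linear shelf–slope profile versus offshore
  distance — narrow shelf (2 km to 100 m), then a drop to 2,500 m over
  15 km — constant alongshore, optionally incised by a Gaussian canyon,
  with the zero-depth coastline along the east edge. Depth increases
  monotonically offshore outside the canyon.
* **Surveys**: aggregations of 1–9 animals are placed between the 1,000 and
  2,000 m isobaths with centres ≥ 2 km apart and members scattered within
  300 m, so the 1 km rule recovers the partition exactly. The default
  composition reproduces the recovered study population: 19 aggregations,
  74 individuals — 16 immature, 31 female/juvenile male, 27 adult male.
  Class IPIs are drawn 0.1 ms clear of the 2.9/5.0 ms boundaries, and all
  IPIs within one aggregation are kept ≥ 0.25 ms apart (group compositions
  are reshuffled until that is feasible): the field definition of an
  aggregation requires its members to be acoustically distinguishable, and
  0.25 ms comfortably exceeds the 0.15 ms single-linkage tolerance used to
  count vocal individuals. Each animal gets its own recording — a
  ten-click regular train, plus a buzz when the group hunts and a coda when
  it socialises — which emulates the manual step of attributing clicks to
  individuals before measuring them. Survey dates span January–May so the
  two-period contrast (January–March vs April–May) is exercised. Default
  survey audio is noiseless: recovery tests compare the pipeline to truth
  without confounding detection errors, and noise robustness is
  established separately at the click and train level.

What passing these tests does **not** show: performance on real clicks with
frequency-dependent propagation, surface echoes, overlapping animals in one
recording, coda rhythm structure, or hydrophone directionality — none of
which the generator emulates. The generator's clicks are also
phase-coherent between pulses, which flatters correlation-based processing;
the envelope estimator does not rely on that coherence.

## Problem sizes and runtime choices

The shipped tests use the sizes the analyses were designed around: the
end-to-end scene at the study scale (19 aggregations / 74 individuals),
200 clicks for IPI recovery, 300 trains for regime classification, 200
random instances for the clustering oracle, and 500 null datasets at
B = 1,000 for permutation calibration. The whole suite runs in a few
minutes on one CPU; the permutation machinery is vectorised precisely so
that calibration at full B stays cheap.

## Known limitations

* Repeated sightings of the same animal across days are not deduplicated
  (per-day and pooled summaries are both derivable from the tables).
* The coda classifier uses only count, duration and ICI; stereotyped
  rhythm patterns are out of scope, so sparse codas are reported as
  regular series.
* Very fast buzzes from very large animals (ICI near 0.02 s with IPI near
  7.8 ms) can overlap adjacent pulse packets; the pulse-merge window then
  undercounts clicks. The regimes used in the tests keep packets disjoint.
* GeoTIFF rasters are not read; bathymetry is exchanged as ESRI ASCII
  grids in WGS84 with square cells.
* The length regressions are treated as exact calibration; their own
  fitting uncertainty is not propagated into per-animal intervals.
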