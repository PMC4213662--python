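# Methods

## The experiment being modeled

A 3′-truncated `lepB` mRNA is immobilized in a zero-mode waveguide with a
30S pre-initiation complex assembled on it. At t = 0, Cy3B-labeled 50S
subunits, Cy5-labeled SRP (100 nM) and the elongation mixture are
delivered. The donor channel steps up when the 50S joins, translation
proceeds codon by codon, and SRP binding appears as FRET between the
ribosome-bound donor and SRP-bound acceptor. In calibration experiments
the Phe-tRNA is Cy3.5-labeled, producing fluorescence pulses while a
labeled tRNA occupies the ribosome at landmark codons (5, 25–27, 55–57,
85–87 on the 95-codon `cWT` construct). Observation ends at donor
photobleach or end of record.

## Generative model

**Translation clock.** 50S joining is exponential (mean 5 s after
delivery). Per-codon dwell times are independent exponentials: mean
6.3 s/aa at 750 nM EF-G, 7.9 s/aa at 250 nM (elongation speed scales
with EF-G), and 10 s at labeled-Phe codons (the labeled ternary complex
is supplied at only 200 nM). At run-off the ribosome stalls with the
chain at full length. A tRNA pulse spans a maximal run of consecutive
landmark codons, from the start of decoding of the run's first codon to
completion of its last; a single-codon pulse therefore averages one Phe
dwell (~10 s) and a triple-codon pulse three (~30 s).

**SRP binding.** A two-state (unbound/bound) continuous-time process.
The association hazard is `kon(chain(t)) × [SRP]`, piecewise constant
between codon completions, which makes exact Gillespie sampling within
each codon interval possible. `kon` is 3.4×10³ M⁻¹s⁻¹ before the signal
sequence reaches the exit-tunnel mouth (40 aa), 1.8×10⁶ M⁻¹s⁻¹ once it is
fully presented (55 aa), and log-linear in between; constructs with a
defective signal sequence stay at the slow rate at all lengths. The
pre-exposure rate was set so that ~9% of first arrivals occur before
40 aa; the post-exposure rate is the measured association rate.

The dissociation rate of an event is drawn from the chain-length bin in
which the event *starts* (s⁻¹: <40 aa 0.067; 40–50 0.0288; 50–60 0.0134;
60–70 0.0265; ≥70 0.03 — reciprocals of the measured per-bin residence
lifetimes) and held constant for the event: the binding mode is locked
in at engagement. The alternative — re-drawing the hazard as the chain
grows under the event — systematically shortens events relative to the
lifetime measured for their start bin and cannot reproduce the per-bin
lifetimes those rates came from; the locked-mode model is the one the
per-bin parameterization implies.

**Heterogeneity (stalled mode).** For stalled-RNC experiments the chain
length is pinned at full length and each RNC's kon and koff are scaled
by independent lognormal factors (log-sd configurable, default 1.0 for
the heterogeneous case), reproducing the orders-of-magnitude
molecule-to-molecule dispersion of arrival and residence times seen for
stalled complexes.

**Optics.** Donor emits `donor_amp·(1−E)` and the acceptor
`zmw_quench·donor_amp·E` during a bound event whose efficiency E is
drawn once per event from a two-component normal mixture
(0.26/0.42 ± 0.05, equal weights — two unresolved binding conformations).
The ZMW aluminum walls attenuate the acceptor (quench 0.65), mapping the
corrected 0.33–0.5 efficiency range onto the observed 0.2–0.32 range.
tRNA channel: 200 AU during occupancy. All channels get independent
Gaussian noise (30 AU) per 100 ms frame; partial-frame overlap is
pro-rated. Donor bleach is exponential (mean 5000 s, so ~88% of cWT
trajectories finish translating before bleaching); records last 1200 s.
No independent acceptor bleaching and no spectral crosstalk by default
(a crosstalk hook exists, default 0).

## Detection

All detectors median-filter the channels (9 frames) and segment with
hysteresis thresholds plus minimum-duration rules; thresholds were tuned
against simulator ground truth, not against any target statistic:

* joining — donor+acceptor ≥ 0.5·donor_amp persisting ≥ 10 frames;
* bleach — last time donor+acceptor is above the same threshold;
* binding events — ratiometric E = A/(A+D) (intensity floor guards dark
  frames), enter at E ≥ 0.15, exit at E < 0.03, minimum 5 frames, events
  separated by < 0.5 s merged. The low exit threshold and the merge gap
  exist because the low-FRET bound state (observed E ≈ 0.19) sits only
  ~4σ above baseline after filtering: with the thresholds at (0.15, 0.08)
  a 70 s event fragments ~2 times on average, which corrupts residence
  and gap statistics. At the defaults, measured against ground truth:
  99.4% of ≥0.5 s events recovered, 0.036 false events/trace,
  0.10 fragments/event, total bound time recovered to 0.4%;
* tRNA pulses — 0.5/0.3 of the tRNA amplitude, 1 s merge gap.

Events touching the bleach or record end are flagged censored and enter
all lifetime fits through the censored MLE; they are never dropped.

## Calibration and QC

Anchors: (joining, codon 0) plus (pulse start, first codon of the k-th
landmark run) — pulse onset marks accommodation of the run's first
labeled tRNA. Position is piecewise-linear between anchors,
extrapolated at the last segment's rate beyond the final anchor, and
capped at the construct length. Events are assigned the chain length at
their *start*. Length-resolved analyses (per-bin residence, occupancy)
keep only traces with exactly one detected pulse per landmark run
(4 for cWT); arrival-time analyses are not pulse-filtered. Per-index
pulse statistics also use these QC traces, since pulse indices only
align with landmark runs when all pulses were seen.

## Estimators

* **Half-time**: smallest t at which the empirical CDF reaches 50% of
  its plateau F∞ = fraction of RNCs showing the event within the record
  (not forced to 1). Arrival curves are multi-step and deliberately not
  fitted with exponentials.
* **First arrival**: first event start − joining. **Subsequent
  arrivals** (2nd–10th): previous event end → next event start (unbound
  waits; start-to-start would conflate residence with association).
  Events beyond the 10th are excluded from arrival statistics only.
* **Lifetimes**: right-censored exponential MLE,
  τ̂ = Σ durations / #uncensored, with likelihood-ratio 95% CIs. Bins
  are 10 aa, left-closed.
* **Occupancy**: an RNC counts as occupied in a bin if any bound
  interval overlaps its *transit* through that bin's chain-length range;
  the run-off stall at full length is not "translating" the final bin.
* **Association rate**: k̂ = 1/(censored-MLE mean unbound wait × [SRP]),
  on gaps starting at ≥ 55 aa (post-exposure).
* **E_FRET mixture**: two-component Gaussian EM (scikit-learn) with a
  deterministic quantile initialization; degenerate inputs are rejected
  and collapsed fits flagged.

## Problem sizes and numerical choices

The standard analyses in the test suite and in `scripts/acceptance.py`
use 500 traces per condition (~460 analyzable first arrivals, ~4000
pooled gaps, ~600 events in the 50–60 aa bin), 200 traces for the
noise-free detection oracle, and 300 for the mutant-specificity
comparison — sizes at which the recovered statistics are stable to a few
percent while a full run stays under a minute. Master seed → per-trace
seeds via `numpy.random.SeedSequence.spawn`, so datasets are
bit-reproducible regardless of execution order. Ratiometric E uses an
intensity floor of 0.2·donor_amp to avoid 0/0 on dark frames; float
serialization uses shortest round-trip decimals to make TSV output
byte-stable.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: the
donor step, chain-length-gated association with realistic arrival
half-times, per-bin residence lifetimes, landmark-locked tRNA pulses,
photobleach censoring, ZMW quenching and frame noise. It does **not**
emulate: sub-100-ms encounter intermediates (below both the distance and
time resolution of the assay), donor/acceptor spectral crosstalk
(default 0), correlated or multiplicative noise, real `lepB` codon
identities or codon-specific tRNA abundances (a single Phe-dwell
parameter stands in), or conformational substates beyond the two-level
E mixture. Passing tests therefore validate the estimator chain under
idealized photophysics, not detector artifacts of real instruments.

## Known limitations

* With i.i.d. exponential per-codon dwells, the interpolated position
  estimate has ~2–4 aa jitter mid-segment between pulse anchors. Sparse
  bins adjacent to dense ones inherit events across the boundary: the
  40–50 aa residence fit is biased upward (~42 s against a generative
  34.7 s) because ~16% of its events actually started beyond 50 aa.
  A sub-exponential (multi-step) elongation clock would shrink this
  jitter; the simulator deliberately keeps the simpler exponential law.
* Subsequent-arrival waits are exponential by construction, so their
  half-time is ln2 × mean ≈ 3.9–4.5 s; real gap distributions are
  heavier-tailed, and ratios of first to subsequent half-times come out
  near ~70 rather than ~50.
* At the default record length both EF-G conditions accumulate many
  binding events per RNC, so the fraction of RNCs with >2 events
  saturates (~0.9) and no longer separates the two elongation speeds.
* Per-bin occupancy for the signal-sequence mutant sits at 2–4% (the
  slow association rate integrated over a ~65 s bin transit), above a
  strict 2% reading of "virtually absent", though ~30-fold below the
  functional construct's post-exposure occupancy.
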