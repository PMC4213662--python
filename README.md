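# srptrace

Simulation and kinetic analysis of single-molecule SRP binding to actively
translating ribosomes.

The signal recognition particle (SRP) targets ribosome–nascent-chain
complexes (RNCs) that expose a signal sequence to membrane translocation
channels. Zero-mode-waveguide (ZMW) fluorescence experiments can watch this
happen in real time: a donor dye on the 50S subunit reports subunit joining
and photobleaching, FRET to an acceptor dye on SRP reports binding events,
and fluorescent Phe-tRNA produces pulses at known codon positions that
calibrate elapsed time against the number of amino acids translated.

`srptrace` packages both halves of such an experiment for people who build
or analyze single-molecule translation assays:

* a **stochastic simulator** of three-channel traces — exponential per-codon
  elongation (slow labeled-tRNA codons included), a two-state SRP
  binding process whose association rate ramps up log-linearly as the signal
  sequence emerges (k_on from ~3.4×10³ M⁻¹s⁻¹ before 40 aa to ~1.8×10⁶
  M⁻¹s⁻¹ at 55 aa), chain-length-dependent dissociation, donor photobleach,
  ZMW acceptor quenching, and additive Gaussian noise;
* the **blind analysis chain** — median-filter + hysteresis event detection
  on the ratiometric FRET efficiency E = A/(A+D), joining/bleach step
  detection, tRNA-pulse detection, pulse-anchored time→amino-acid
  calibration, QC filtering, and the kinetic estimators: arrival-time
  distributions and their 50%-of-plateau half-times, right-censored
  single-exponential residence lifetimes per 10-aa bin, chain-length
  occupancy profiles, association rates (k̂ = 1/(mean unbound wait × [SRP])),
  two-component Gaussian E_FRET mixtures, and the Förster conversions
  E = 1/(1+(r/R₀)⁶).

Ground truth is carried in a sidecar that the analysis never reads, so every
estimator can be validated end-to-end against the generative parameters.

## Worked example

```python
import srptrace as st
from srptrace.pipeline import headline_statistics

config = st.FullConfig(kinetics=st.default_kinetics(750))   # 750 nM EF-G
dataset, ground_truth = st.simulate_dataset(config, 200, seed=0)
result = st.analyze_dataset(dataset)                        # sidecar-blind
h = headline_statistics(result)
```

With 200 traces of the 95-codon calibration construct (`cWT`, landmark
codons at 5, 25–27, 55–57, 85–87) this prints:

```
first-arrival half-time   : 329 s (n = 188 RNCs)
2nd-10th arrival half-time: 4.7 s
residence 50-60 aa        : 75.4 s
residence 40-50 aa        : 52.7 s
first arrivals in 40-55 aa: 67 %
first arrivals < 40 aa    : 9.2 %
tRNA pulse lifetimes      : 11.7 s (single), 31.3 s (triple)
post-exposure k_on        : 1.53e+06 /M/s
```

Reading: the first SRP arrival waits for ~50 codons of translation
(~330 s) while subsequent arrivals take only seconds — the association
rate jumps ~50-fold once the signal sequence leaves the exit tunnel.
Residence is longest for 50–60 aa chains; two-thirds of first arrivals
land in the 40–55 aa window. The single-codon tRNA pulse is ~3× shorter
than the triple-codon pulses, confirming the translation calibration.

The same pipeline runs from a shell:

```
srptrace simulate --n 500 --seed 1 --out data/
srptrace analyze  --data data/ --out results/
srptrace report   --results results/ --out plots/
```

`simulate` writes one TSV per trace plus a JSON manifest and the
ground-truth sidecar; `analyze` writes events, pulses, calibration
anchors, per-bin residence fits, occupancy, dispersion tables, a QC log
and a summary; both record config, seed and per-file checksums in a
`run_record.json` (identical invocations are bit-identical).

## Layout

| module | contents |
| --- | --- |
| `srptrace.constructs` | mRNA constructs, kinetic/optical configs, k_on ramp |
| `srptrace.simulate` | trajectory + trace simulation (`simulate_dataset`) |
| `srptrace.trace_io` | TSV/JSON dataset formats, ground-truth sidecar |
| `srptrace.detection` | E_FRET, joining, bleach, binding-event and pulse detection |
| `srptrace.calibration` | pulse-anchored time→aa maps, QC filter |
| `srptrace.kinetics` | half-times, censored-MLE lifetimes, occupancy, rates, mixtures |
| `srptrace.pipeline` | end-to-end analysis, headline statistics |
| `srptrace.cli` | `srptrace simulate / analyze / report` |

See `docs/methods.md` for the model, its assumptions, and known
limitations.
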