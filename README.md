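# ictalwave

Multimodal analysis of hippocampal seizures recorded simultaneously with a
planar microelectrode grid (local field potentials, LFP) and two-photon
calcium imaging of pyramidal cells. The package quantifies, for each
seizure:

- **cellular recruitment** — per-cell ΔF/F onset times against
  mean + k·SD baseline thresholds, recruitment duration (last minus first
  onset), and the reproducibility of the recruitment order across seizures
  (pairwise Spearman r, Kendall's W with a permutation null, and a 2-D
  onset-direction vector from first- to last-recruited centroids);
- **oscillatory coupling** — high-γ (80–150 Hz) amplitude events and
  multiunit spikes (300–3000 Hz, threshold −4·median(|x|/0.6745)) referenced
  to the instantaneous 4–30 Hz phase, with circular statistics
  (Watson–Williams, common-median fallback, Hodges–Ajne omnibus);
- **the traveling wave** — per-channel discharge peaks grouped across the
  grid (≤150 ms apart, >60% of functional channels) and fitted with a plane
  t = a·x + b·y + c; direction = atan2(b, a), speed = 1/‖(a, b)‖;
- **speed prediction** — bagged regression-tree ensembles mapping ten
  windowed single-site features (five ephys: mean/SD high-γ amplitude,
  fractional 4–30 and 80–150 Hz power, phase-locking value
  PLV = |N⁻¹ Σₙ exp(i(φ₄₋₃₀[n] − φₐ(₈₀₋₁₅₀)[n]))|; five calcium: mean ΔF/F,
  mean line length Σ|dΔF/F|, mean SD of the ΔF/F derivative, mean and SD of
  pairwise Pearson correlations) to the per-window median wave speed, with
  out-of-bag permutation importance and first-vs-last-25% feature evolution.

Because raw recordings of this kind are rarely public, the package ships a
seeded synthetic generator (`ictalwave.synth`) that plants plane waves,
phase-locked bursts/spikes, and a reproducible cell-recruitment order with
indicator-like kinetics — so every stage is testable by parameter recovery.

Intended users: systems-neuroscience and epilepsy labs analyzing paired
MEA + calcium-imaging seizure data, and methodologists who need a
ground-truthed testbed for seizure traveling-wave pipelines.

## Worked example

```bash
$ printf 'synth:\n  duration_s: 60.0\n' > cfg.yaml
$ ictalwave simulate --config cfg.yaml --seed 1 --out seizure.h5
wrote seizure.h5: 16 channels, 20 cells
$ ictalwave wave seizure.h5 --out discharges.csv
99 discharges, median speed 465.0 mm/s; wrote discharges.csv
$ ictalwave onsets seizure.h5 --out onsets.csv
recruitment_duration_s=1.200; wrote onsets.csv
$ ictalwave phase seizure.h5 --channel 0 --out phase.json
83 high-γ events; wrote phase.json
```

The simulated minute-long seizure plants discharges propagating at
500 mm/s with 2 ms timing jitter: the recovered median speed (465 mm/s,
0.465 m/s) is biased slightly low because timing noise inflates the fitted
gradient norm and speed is its inverse. The 20 cells are recruited over a
planted 1.2 s span, recovered exactly as `recruitment_duration_s=1.200`.
The 83 high-γ amplitude events are strongly phase-locked to the 4–30 Hz
rhythm (`phase.json` reports a Hodges–Ajne uniformity p ≈ 2e-23).

`ictalwave all --seed 0 --out runs/demo` runs the full pipeline (simulate →
onsets → phase coupling → traveling waves → windowed features → bagged-tree
speed model → feature-evolution comparison) and writes per-stage CSV/JSON
outputs plus a run report.

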