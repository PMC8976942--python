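# thermoresp

Thermography-based respiration monitoring for free-ranging animals, and
statistical detection of **vocalization-correlated respiratory movements
(VCRMs)**.

Breathing is visible in thermal video: inhaled ambient air cools the
nostril, exhaled air warms it. Given per-frame nostril detections from a
thermal camera (30 frames s⁻¹), `thermoresp` converts raw sensor counts to
temperature, extracts a nostril temperature trace, segments it into
respiration phases, aligns it with an individually recorded audio track,
and tests whether calling perturbs breathing — all with a synthetic-trace
simulator so every stage can be validated against known ground truth.

It is aimed at behavioural ecologists and physiologists who record
animals (the motivating system is wild meerkats emitting soft "sunning
calls") with a radiometric camera plus a directional microphone.

## The method

1. **Radiometric conversion.** Raw counts → temperature via the standard
   FLIR-style chain: water-vapour atmospheric transmittance
   τ(T_atm, RH, d), emissivity/reflection correction, and the Planck
   inversion T = B / ln(R1/(R2(S + O)) + F) − 273.15. The nostril signal
   is the median intensity of a 10×5 px region of interest.
2. **Quality control.** Analyzable segments need ≥ 150 frames (5 s — at
   least three cycles at the mean respiration rate of 0.603 Hz:
   3 × 1.6 s × 30 fps = 144), detection gaps ≤ 5 consecutive frames, and
   both nostrils detected at confidence ≥ 0.95 (front-view head pose).
3. **Phase segmentation.** The trace is smoothed with a zero-phase
   second-order Butterworth filter (critical frequency 1/5). Local
   temperature minima mark maximum inspiration; from each minimum the
   curve is walked outward until the local slope becomes negligible,
   delimiting the expiratory pause. Each phase — inspiration,
   expiration, expiratory pause — is quantified by duration (s),
   amplitude (Δ°C) and slope (amplitude/duration).
4. **Cycle typing.** Synchronization markers map audio time to video
   frames. Cycles containing a focal call onset are *Call*; immediate
   neighbours are *Pre-call* / *Post-call*; the rest are *Quiet* (with a
   2 s audio window beyond segment edges). Phases of Quiet cycles are
   additionally labelled *NF heard* when a non-focal conspecific call
   falls in or just after them.
5. **Statistics.** Group differences in phase metrics use the Δmean
   statistic (difference in group means) with a within-individual
   permutation test: labels are reshuffled against values independently
   inside each individual (10,000 permutations), and the two-tailed
   pseudo-P is `(1 + #{|Δperm| ≥ |Δobs|}) / (N + 1)`. A Spearman test
   relates call duration to the magnitude of respiratory change.

## Worked example

Simulate a small field campaign (5 individuals, 30 breathing cycles and
3 sunning calls each) and run the complete pipeline:

```python
from thermoresp import pipeline as pl
from thermoresp.pipeline import PipelineConfig

pl.stage_simulate("demo/data", n_individuals=5, cycles_per_individual=30,
                  calls_per_individual=3, seed=7)
results = pl.run_all("demo/data", "demo/out", PipelineConfig())
for key in ("expiration.amplitude_C", "expiratory_pause.duration_s"):
    r = results[key]
    print(f"{key}: delta_mean={r['delta_mean']:+.3f}  "
          f"pseudo_p={r['pseudo_p']:.4f}  (n_Call={r['n_A']}, n_Quiet={r['n_B']})")
```

prints

```
expiration.amplitude_C: delta_mean=+0.417  pseudo_p=0.0057  (n_Call=15, n_Quiet=105)
expiratory_pause.duration_s: delta_mean=-0.491  pseudo_p=0.0129  (n_Call=15, n_Quiet=102)
```

Read: expiration amplitude during Call cycles exceeds Quiet cycles by
0.42 °C on average (calling expels more warm air), and the expiratory
pause after a call is about 0.49 s shorter (the respiratory drive is
elevated after the extra expenditure) — both effects unlikely under the
within-individual permutation null.

The same stages are available as shell commands:

```bash
thermoresp simulate --out-dir demo/data --n-individuals 5 --cycles 30 --calls 3 --seed 7
thermoresp run-all --data-dir demo/data --out-dir demo/out
thermoresp qc --detections det.csv --out segments.csv     # single stages
```

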