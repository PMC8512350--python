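# perclos

Eye closure-associated driver-fatigue indicators from facial video.

Camera-based drowsiness monitors watch a driver's eyes and raise an alarm when
closures become long or frequent. This package implements the complete
software side of such a monitor, plus the statistical machinery used to
evaluate one against subjective fatigue ratings:

1. **Eye-state classification** — each video frame is matched against
   open-eye template patches (one pair per eye, up to K pairs) using the
   normalized correlation coefficient. An eye is *open* as soon as any
   template scores ≥ 0.68; if all K scores fall below, the eye is *closed*.
   The frame counts as closed only when **both** eyes are closed. Frames with
   no detected eye landmarks stay unclassified and can be resolved from a
   manual-override CSV.
2. **Event segmentation** — maximal runs of closed frames become closure
   events; events lasting ≤ 200 ms (12 frames at 60 fps) are ordinary blinks
   and are excluded from every indicator.
3. **Windowed indicators** over consecutive 30 s windows (N = 1800 frames at
   60 fps), counting only qualifying (longer-than-blink) closures:
   - `PERCLOS = N_closed / N` — fraction of window time closed; fatigue above 0.15;
   - `ECD = N_closed / n` — mean closure duration (frames or ms); fatigue above 400 ms;
   - `FEC = n` — number of closures; fatigue above 5 per window.
4. **Statistical evaluation** — paired t-tests with a dependent-samples
   Cohen's *d*, ROC analysis with a stratified bootstrap CI, and a
   **three-level linear mixed model** for subjective fatigue (FSS-S raw
   score): measurement occasions nested in rested/drowsy sessions nested in
   drivers, with random intercepts at both grouping levels, plus ICCs,
   Nakagawa marginal/conditional R², per-level ΔR², and likelihood-ratio
   model comparison.
5. **Synthetic generators** — ground-truthed eye-aperture sessions, rendered
   eye-region image sequences, and three-level FSS-S datasets, so the whole
   pipeline is testable end to end without camera data.

## Worked example

Simulate a drowsy 60 s drive, render it to PNG frames, analyse the rendering,
and compare against the generator's ground truth:

```bash
perclos simulate --preset drowsy --duration 60 --seed 7 --render --out demo/sim
perclos analyze --video demo/sim/frames --calibration demo/sim/calibration.yaml --out demo/ana
```

which prints

```
3600 frames, 27 events; outputs in demo/sim
3600 frames -> 2 complete windows; outputs in demo/ana
```

and `demo/ana/indicators.csv` begins

```
window_index,start_frame,n_frames,closed_frames_qualifying,n_clusters,perclos,...
0,0,1800,153,5,0.085,30.6,510,5,False,True,False,0,True,False
1,1800,1800,206,7,0.11444...,29.428...,490.47...,7,False,True,True,0,True,False
```

Window 0: 153 of 1800 frames inside qualifying closures, so PERCLOS = 0.085
(below the 0.15 fatigue threshold); 5 closures averaging 30.6 frames = 510 ms,
so the ECD flag fires (> 400 ms) while FEC = 5 does not (needs > 5). These
values match `demo/sim/expected_indicators.csv`, computed independently from
the generator's ground-truth events — on rendered synthetic video the
classifier recovers the true closed mask exactly.

The same objects are available as a library:

```python
import perclos

aperture, truth = perclos.generate_session(perclos.DROWSY_PROFILE, 60, seed=7)
series = perclos.series_from_mask(aperture < 0.25)
windows = perclos.window_indicators(series, perclos.segment_and_label(series))

df = perclos.generate_fss_dataset(perclos.FssSimConfig(n_subjects=30, seed=2))
fit = perclos.SubjectiveFatigueModel(df, ("time", "indicator"), indicator_col="ecd").fit()
print(fit.summary())
print(perclos.r2_nakagawa(fit))
```

`perclos stats --table fss.csv --out report/` fits the full model ladder
(intercept-only, + time, + one model per indicator) and writes a comparison
table with AIC, −2 log-likelihood, likelihood-ratio χ², ICCs, R² and ΔR².

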