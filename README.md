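# ringmig

Run-and-rest analysis of single-cell migration in ring-shaped microlanes.

Cells confined to ring-shaped adhesive lanes (radius *R* = 50 µm, PLL-PEG
outside) migrate quasi-one-dimensionally and stochastically alternate
between directionally persistent **runs** and localized, diffusive
**rests**. `ringmig` quantifies this bimodal motion from nucleus-centroid
tracks and is aimed at labs running micropatterned single-cell migration
assays who want a compact, comparable readout per condition:

* project tracks to the arc coordinate and compute the signed tangential
  velocity `v_i = R (φ_{i+1} − φ_i)/Δt`;
* split each velocity series into run and rest states by iterative CUSUM
  change-point analysis (permutation-calibrated) plus MSD-slope
  classification (run: slope ≈ 2, rest: ≈ 1, cut at 1.5);
* estimate the run speed `v_run = ⟨|⟨v⟩_state|⟩` and the persistence times
  `τ_run`, `τ_rest` from the exponential tails of the state-duration
  survival functions `S(t) = P(T > t)` (fit windows 5–20 h and 2.5–20 h,
  20-h censoring rule);
* quantify interactions with a PEGylated gap of width `d_gap`: turning
  probabilities with exact Clopper–Pearson intervals, the transit law
  `P_trans(d_gap) = (1 − P_turn(0)) · e^{−d_gap/μ_trans}`, run/rest
  occupancy versus distance to the barrier, and the invasion-depth law
  `S_inv(d) = s0 · e^{−d/μ_inv}`;
* assemble the five-parameter **migratory fingerprint**
  {`v_run`, `τ_run`, `τ_rest`, `P_turn(8)`, `P_turn(0)`} and render
  comparative radar charts.

A synthetic two-state trajectory generator (exponential dwells, confined
rest diffusion, optional barriers, ground-truth labels) makes the entire
pipeline testable without experimental data; its defaults are the
reference MDA-MB-436 conditions (τ_run = 13.6 h, τ_rest = 6.5 h,
v_run = 30.2 µm/h, 48-h tracks at 10-min frames). See `docs/methods.md`
for the model details and known limitations.

## Worked example

The `analysis/` scripts run the full study on synthetic data, writing
tables under `results/` (step 01 regenerates the track CSVs, which are not
checked in):

```sh
python analysis/01_simulate_tracks.py      # ensembles + ground truth
python analysis/02_segment_states.py       # CUSUM + MSD state table
python analysis/03_motility_parameters.py  # v_run, v_mean, tau fits
python analysis/04_barrier_transit.py      # P_turn, mu_trans, mu_inv
python analysis/05_fingerprint.py          # radar chart + vertex JSON
```

Step 03 prints, for the default 200-track ensemble:

```
v_run  = 29.8 +- 0.1 um/h (547 run states)
v_mean = 24.7 +- 0.2 um/h (200 cells)
tau_run  = 14.5 h  (99% CI 14.3-14.8)
tau_rest = 7.9 h  (99% CI 7.7-8.0)
```

`v_run` exceeds `v_mean` because rest periods dilute the whole-track mean
but not the run-state mean; the fitted persistence times sit a little above
the generating 13.6 h / 6.5 h because states shorter than ~2 frames are
unresolvable at 10-min sampling and merge their neighbors (see the methods
note), and this particular 200-track draw runs high. Step 04 prints the
barrier side:

```
P_turn(0) = 0.208 (pooled 95% CI 0.198-0.219)
mu_trans = 8.6 um (95% CI 7.5-9.7)
mu_inv = 11.3 um (95% CI 11.3-11.4), s0 = 0.94
```

i.e. roughly one spontaneous reversal per five zone passages even without a
barrier, a transit probability that falls e-fold per 8–9 µm of gap, and a
matching typical lamellipodium invasion depth — the mechanistic link the
transit model encodes.

As a library:

```python
import ringmig as rm

params = rm.SimulationParams(seed=0)            # reference conditions
tracks, truth = rm.simulate_tracks(params, 200)
result = rm.analyze_ring_ensemble(tracks, config=rm.SegmentationConfig(seed=0))
print(result.params["tau_run"], result.params["v_run"])
```

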