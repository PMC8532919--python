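# roamkit

Analysis pipeline for long-term RFID home-cage monitoring of group-housed
mice, centred on **roaming entropy**: how much of a multi-level enclosure an
animal actually uses, night after night, and how individual and stable that
usage is.

A semi-naturalistic enclosure is instrumented with *k* ring antennas (27 on
5 levels in the emulated setup); every pass of a transponder-tagged mouse is
logged as `(timestamp, antenna, animal)`. From each animal's dark-phase
contact distribution `p_{i,·,t}` the nightly roaming entropy is

```
RE_{i,t} = − Σ_j p_{i,j,t} · log p_{i,j,t} / log k          ∈ [0, 1]
```

(0 = all contacts at one antenna, 1 = uniform use of all *k*), and the
cumulative roaming entropy is the running sum
`cRE = RE_{i,t1} + RE_{i,t2} + …`, whose slope measures sustained spatial
activity and whose cross-animal spread measures behavioural individuality.

On top of that the package provides:

* **Activity raster** — an animal is *active* in a 15-min clock bin when it
  contacted ≥ 2 different antennas in it; day × bin counts of active animals
  give the colony heatmap.
* **Repeatability** — one-way ANOVA intraclass correlation
  `R = σ²_among / (σ²_among + σ²_within)` of nightly RE in sliding 4-week
  windows (stepping 1 week; 20 analysed weeks → 17 windows), with
  animal-level bootstrap CIs (500 runs) and permutation p-values (100 runs).
* **Resting metabolic rate** — the cumulative-frequency curve of an
  indirect-calorimetry V̇O₂ trace is fitted with a continuous two-segment
  regression `y = β₀ + β₁x + β₂(x−ψ)₊`; the breakpoint ψ separates rest from
  activity and RMR is the mean sub-threshold V̇O₂ (mL min⁻¹ kg⁻¹).
* **Synthetic colony** — a seeded generator of RFID event streams (biased
  random walk on the antenna graph, circadian rate modulation, home-range
  preferences, aging decline) and of two-state V̇O₂ traces, with exported
  ground truth for parameter-recovery testing.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
colony (20 mice, 27 antennas, 140 nights; all seeds fixed in the scripts):

```bash
python analysis/01_simulate.py
python analysis/02_roaming_entropy.py
python analysis/03_activity_heatmap.py
python analysis/04_repeatability.py
python analysis/05_metabolic_rate.py
python analysis/06_correlations.py
```

`02_roaming_entropy.py` prints, for the bundled seed:

```
140 nights, 20 animals
night 1   RE: 0.087 ± 0.018 (CV = 21.0%, max = 0.110, min = 0.046, n = 20)
night 140 RE: 0.065 ± 0.027 (CV = 41.7%, max = 0.160, min = 0.028, n = 20)
final cRE  : 10.316 ± 2.058 (CV = 19.9%, max = 15.389, min = 5.532, n = 20)
mean RE over nights: slope=-0.0001826, F(1|138)=720.00, p=1.29e-56, adj. R2=0.84
RE variance trend : slope=-7.998e-07, F(1|138)=11.28, p=0.00101, adj. R2=0.07
cRE variance trend: slope=0.03131, F(1|138)=3573.08, p=1.57e-100, adj. R2=0.96
```

Read: nightly roaming entropy starts near 0.09 (mice use a small, individual
fraction of the enclosure), declines with age, and its cross-animal variance
shrinks — while cumulative roaming entropy fans out (variance trend strongly
positive), i.e. animals settle into persistently different routines.
`05_metabolic_rate.py` recovers each simulated animal's resting V̇O₂ within
≈1% of its generating rest-state mean (`RMR 39.180 ± 3.326, CV = 8.5%`).

The same stages are scriptable via the thin CLI
(`roamkit simulate|compute-re|activity-heatmap|repeatability|rmr|correlate|run-all`),
which writes byte-identical outputs for a fixed config and seed.

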