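# sporekernel

Dispersal distance kernels for fungal spores carried by a mycophagous
mammal, estimated from GPS telemetry and spore gut-retention curves.

Many truffle-like (sequestrate, often ectomycorrhizal) fungi depend on
mammals that eat their fruiting bodies: spores survive gut passage and are
deposited in faeces wherever the animal has moved in the meantime.  The
distance a spore travels from its point of ingestion is therefore set by
two ingredients: how long it stays in the gut, and how far the animal moves
in that time.  `sporekernel` combines the two into the *dispersal distance
kernel* — the probability distribution of spore displacement — for any
tracked mycophagist, and ships a synthetic-data generator so every stage
can be exercised with known ground truth.

## Model

**Gut passage.**  A marker-spore feeding trial gives counts of marker
spores per scat-collection interval.  The cumulative proportion defecated
is fitted with a two-parameter logistic by nonlinear least squares,

&nbsp;&nbsp;&nbsp;&nbsp;C(t) = A / (1 + exp(−(t − t₅₀)/s)),&nbsp;&nbsp;A = 1 by default,

where t₅₀ is the time of 50% cumulative defecation (h) and s a scale (h).

**Movement.**  GPS tracks (fixes every 15–30 min over tens to hundreds of
hours) are cleaned — a fix-quality filter and a 60-min post-handling
warm-up discard — and every fix with at least W = 69 h of track remaining
(the maximum observed ingestion-to-defecation time) is treated as a
hypothetical ingestion point.  Displacement from that anchor is the
great-circle distance at each subsequent fix.

**Kernel.**  Within each 69-h ingestion window the displacement at each fix
is weighted by the probability that defecation happens in the interval
ending at that fix, ΔC = C(tᵢ) − C(tᵢ₋₁), renormalised within the window.
The per-trial-animal gut curves are averaged within each window, windows
are averaged within each tracked animal, and animals are averaged (1/n
each) into the overall kernel.  Summaries are weighted empirical quantiles
(lower convention), the maximum support distance with positive mass,
binned densities, and an across-animal envelope.

## Worked example

```python
import sporekernel as sk

# synthetic study: 6 animals, 9 tracking periods, 2 feeding trials
tracks, obs = sk.simulate_study(sk.StudyConfig(seed=11, n_spores=2000))

frame = sk.simulate.observations_to_frame(obs)
gut = [sk.GutPassageModel.from_dataframe(frame, trial).fit()
       for trial in ("trialA", "trialB")]
print(gut[0].summary())

results = sk.SporeDispersalModel(tracks, gut).fit()
print(results.summary())
```

```
Logistic gut-passage fit
========================================
trial animal:       trialA
n points:           20
time basis:         interval_end
converged:          True
RSS:                0.000344033
----------------------------------------
t50 (h):            24.2103  (SE 0.0476)
s (h):              4.9394  (SE 0.0421)
asymptote:          1.0000

Spore dispersal kernel
==============================================
animals:                 6
tracking periods:        9
ingestion windows:       3141
gut-passage curves:      2
window length (h):       69
----------------------------------------------
 25.0% of spores within        276.1 m
 50.0% of spores within        441.2 m
 75.0% of spores within        655.2 m
 95.0% of spores within       1019.5 m
maximum distance:            1868.5 m
```

The fitted t₅₀ ≈ 24.2 h and s ≈ 4.9 h recover the generator's (24, 5).
The kernel says half of all ingested spores are predicted to be deposited
within ~440 m of the ingestion point, 95% within ~1 km, and the single
most extreme window reaches ~1.9 km — the scale follows directly from the
simulated home-range radius (σ = 300 m per axis).

The same pipeline runs from the shell:

```bash
sporekernel simulate --seed 11 --out study/
sporekernel build-kernel --telemetry study/telemetry.csv \
    --excretion study/excretion.csv --out kernel/ --plots
```

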