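# watertrips

Segmentation and mixed-model analysis of **central-place foraging trips**
in GPS telemetry of water-dependent herbivores.

During the dry season, animals such as African elephants must return to a
handful of water-retaining waterholes every day or two while foraging in a
landscape where food close to water is depleted. Their movement track is
therefore naturally organised into *foraging trips*: the segments between
two consecutive drinking events. This package turns hourly GPS fix tables
into trip-level data and asks the questions that framework makes
answerable — how long are trips and how far from water do they reach, is
within-trip travel speed driven by the spatial context (distance to
water) or the behavioural context (progression through the trip), and do
animals drink at the closest waterhole?

It is written for movement ecologists working with Movebank-style
telemetry, and ships a synthetic central-place-foraging track generator
with known ground truth so the whole pipeline is testable without any
data download.

## Method

**Segmentation.** Each trajectory is cut at every *visit* to a
water-retaining waterhole. Because hourly sampling rarely catches the
animal exactly at water, a fix counts as "at" a waterhole when it lies
strictly closer than a threshold *d* (default 1 km; sensitivity range
0.8–1.2 km); a run of consecutive sub-threshold fixes collapses to the
single closest-to-water fix. A trip whose fixes span an acquisition gap
longer than 1.5 h is removed when a detour from the last fix via the
nearest waterhole back to the next fix would have required less than
3 km/h — an unobserved drink cannot be ruled out. Trips are *looping*
(same waterhole at both ends) or *commuting* (different waterholes);
trips under 12 h are flagged for review.

**Trip-level models.** For each retained trip we compute the distance
traveled, the mean speed, and the maximum distance to the start/end
waterhole, and fit linear mixed models

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>ij</sub>* = β₀ + β₁·commuting + β₂·duration + β₃·commuting·duration + *b<sub>i</sub>* + ε<sub>ij</sub>

with individual identity *i* as a random effect on intercept and slopes.

**Within-trip speed.** Step speed is modelled against either distance to
water or *progression* (elapsed time as % of trip duration), entered
linearly or quadratically and fully crossed with trip type and duration,
with a random intercept per individual. The four candidates are fitted by
maximum likelihood on the identical step table and ranked by AIC.

**Uncertainty.** 95% confidence intervals come from a parametric
bootstrap (default 10 000 samples): simulate a new response from the
fitted model (fresh random effects + residual noise), refit, take
percentile intervals; a term is significant when its interval excludes
zero.

## Worked example

The numbered scripts under `analysis/` run the full study on the bundled
generator (seed 1):

```sh
python analysis/01_simulate_tracks.py 1
python analysis/02_segment_trips.py
python analysis/03_trip_metrics.py 1
python analysis/04_fit_models.py 1 500
```

which prints, among other output:

```
145 trips built; 17 removed by the gap rule; 128 retained; 22 flagged short (<12 h)
duration bins (<=12 / 12-36 / 36-60 / 60-84 / >84 h):
  17.2% / 47.7% / 28.9% / 3.9% / 2.3%
looping vs commuting duration distributions: chi2=4.50, P=0.342
trips not ending at the closest waterhole: 60.2% (mean extra 2.93 +/- 2.69 km)
dry-season speed 0.40 vs wet 0.31 km/h (t=6.74, P=1.8e-11)
AIC ranking of within-trip speed models:
  prog_quadratic   AIC    3479.7
  dist_quadratic   AIC    4678.5
  dist_linear      AIC    4740.5
  prog_linear      AIC    4994.8
```

Read: of 145 trips cut from ten 3-week trajectories, 128 survive the
gap-plausibility filter; trip durations are multimodal (most trips last
one or two days); looping and commuting trips have statistically
indistinguishable duration distributions; a majority of turning points
are not resolved to the nearest waterhole but the extra distance is a few
km; dry-season movement is faster than the wet-season baseline; and
within-trip speed is far better explained by a U-shaped function of trip
progression than by distance to water (ΔAIC ≈ 1200) — animals speed up
when leaving water and, especially, when returning to it. The fitted
coefficient table (`results/model_tables.txt`) recovers the generator's
U-shape: progression −0.025 [−0.030, −0.020], progression² 2.7·10⁻⁴
[2.2·10⁻⁴, 3.2·10⁻⁴].

The same pipeline runs on real fix/waterhole CSVs via the CLI:

```sh
watertrips segment --fixes F.csv --waterholes W.csv --threshold-km 1.0
watertrips run --out results/run --seed 1 --nboot 1000
```

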