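# grazemap

Spatial-temporal mapping of sheep grazing intensity from GPS collar
trajectories.

Rangeland managers need to know not just *how much* a flock eats but
*where*: repeated heavy use of the same patches degrades semi-arid
grassland long before the paddock-average stocking rate looks
problematic. `grazemap` estimates a per-cell grazing-intensity surface
F (grams of fresh forage removed per m²) from 2-minute collar fixes,
for ecologists and grazing-systems researchers working with collared
flocks on fenced paddocks.

## The model

A collar day is a spatial-temporal sequence C = [(P₁,T₁), (P₂,T₂), …].
The pipeline:

1. **Zone exclusion.** A Gaussian kernel density over all fixes is
   classified into five grades; connected high-grade clusters are
   classed as *rest* (pens; near-stationary dwell), *drinking*
   (contains the water point) or *grazing*. Fixes inside rest and
   drinking zones remove no forage and are excluded.
2. **Constant-rate intake allocation.** Daily fresh intake is a fixed
   fraction of body weight, IZ = 0.076·W (equivalently: dry-matter
   intake 2–4 % of W at a dry-to-fresh ratio of 0.39). With effective
   grazing time TZ and feeding-time fraction a = 0.86, each segment of
   duration Tᵢ takes intake Iᵢ = (IZ/TZ)·Tᵢ·a, spread over the 13-m
   analysis grid through a 3-m half-width rectangular buffer around
   the segment line, weighted by overlap area. Cell intensity is
   F = (allocated grams)/S with S the cell area; days and animals
   superpose by cellwise summation. The published closed form
   F = IZ·Tᵢ·Cᵢ/(ΣCᵢ·TZ·S) is also available (`mode="literal_eq5"`);
   it double-weights occupancy and is kept for fidelity, while the
   conservative mode guarantees Σ F·S equals the summed segment
   intakes to machine precision.
3. **Intensity regression.** Eight per-segment covariates — duration
   T, walking distance C, slope P, elevation E, aspect D, NDVI,
   weight S and temperature — are z-scored and fed to a
   single-hidden-layer feedforward network (tanh/linear) trained by
   back-propagation on a 70/15/15 train/validation/test split, with
   R² = 1 − Σ(Wᵢ−Wᵢ₁)²/Σ(Wᵢ−Wᵢ₂)² and MSE reported on the test set.
   Nine fixed factor combinations X1–X9 are screened to find the
   smallest informative subset.

No collar data are deposited with the original study, so a synthetic
generator (`grazemap.synthetic`) reproduces the study conditions — a
~210 ha paddock, 06:00–18:00 grazing days at 2-min fixes, pen/water
dwells, NDVI-biased grazing loops, a 200-head flock with 70 % of
weights in 40–60 kg — and plants a known intake field for recovery
tests.

## Worked example

```python
import grazemap as gm

cfg = gm.SimulationConfig(seed=1)
traj, truth = gm.simulate_trajectory(cfg, animal_weight=50.0)
print(len(traj))                      # 361  (06:00-18:00 at 120 s)

segs, n_glitch = gm.segmentize(traj)  # speed-filtered consecutive pairs
print(len(segs))                      # 360

iz = gm.daily_intake(50.0)            # 3800.0 g  (7.6 % of 50 kg)
ig = gm.allocate(segs, iz, cfg.grid_spec(), feeding_fraction=0.86)
print(round(ig.total_allocated(), 1)) # 3268.0 g  (= IZ x a = 3800 x 0.86)
print(round(ig.values.values.max(), 2))  # 2.73  peak cell intensity, g/m2
```

The map total is exactly the daily intake times the feeding-time
fraction: the conservative allocator never loses or invents grams. The
peak cell (2.73 g/m²) marks the most intensively grazed 13-m cell of
that day.

The full pipeline (simulate → preprocess → allocate → features →
screen → map) runs from the command line and writes every intermediate
artifact plus a hash manifest:

```bash
grazemap run --seed 1 --outdir runs/demo
```

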