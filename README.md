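# territoria

Territory-size estimation from intrusion (playback) experiments.

Many territorial animals advertise from central sites but defend a much
larger area.  Mapping only the advertisement positions therefore
underestimates the territory; an *intrusion experiment* instead presents a
conspecific cue (e.g. playback of an advertisement call) from a chosen
direction and records where the focal animal stops its approach — a point on
the edge of the defended area.  Repeating this in several directions "spans
up" the territory with a small number of trials.  This package provides the
estimators and the simulation machinery needed to analyse the resulting
point patterns, for behavioural ecologists planning or evaluating such
experiments:

- **Simulation benchmarks** — virtual territories (convex to highly concave
  outlines, known true area *A*), simulated trial sets of 360 random central
  starts paired with 360 equiangular edge endpoints, and exhaustive
  enumeration of all 810 equiangular trial subsets whose sizes divide 360.
- **Area estimators** — minimum convex polygon (MCP); a detailed
  (characteristic/chi-shape) hull with edge-length threshold λ that peels
  long Delaunay boundary edges, so DH(λ=∞) = MCP; bivariate normal kernel
  densities, fixed and adaptive, with h_ref = √((s²ₓ+s²ᵧ)/2)·n^(−1/6) and
  least-squares cross-validation bandwidths; and *k*-LoCoH utilization
  distributions with an automated minimum-spurious-hole-covering (MSHC)
  choice of *k*.
- **Stretch-the-centre (STC)** — a rubbersheet estimator that fits a kernel
  to the calling positions only (a pattern kernels handle well), then
  stretches all of its isoclines out to the trial endpoints through a
  piecewise-linear (TIN) spatial adjustment driven by correction links
  (99%-isocline → endpoint, along each trial axis) and identity links
  pinning every calling position.
- **Evaluation machinery** — percent-of-true-area tables,
  area-accumulation curves with mean ± SD over all equiangular offsets,
  rank-order stability of territory size with increasing trial count,
  stepwise-change tables, and isopleth coverage statistics against a
  reference hull.
- **Field-protocol support** — the semi-random 12-direction (every 30°)
  trial scheduler and trial-record validation, with CSV/GeoJSON I/O.

## Worked example

```python
import territoria as tt
from territoria import evaluate as ev

territory = tt.make_virtual_territory("circle")        # true area 200.04
trials = tt.simulate_trialset(territory, seed=1)       # 360 simulated intrusions
pts = trials.points()

for name in ("MCP", "DH", "LoCoH"):
    area = ev.estimator_area(pts, name)
    print(f"{name:6s} area {area:7.2f}  ({ev.percent_of_true(area, territory):.0f}% of true)")

tab = ev.accumulation_table(territory, trials, "DH", ks=(6, 12, 20, 60, 360))
print(tab.round(2).to_string(index=False))
```

prints

```
MCP    area  200.03  (100% of true)
DH     area  200.03  (100% of true)
LoCoH  area  200.03  (100% of true)
  k  n_offsets  mean_area  sd_area  percent_of_true
  6         60     131.30    44.12            65.64
 12         30     191.03     0.00            95.49
 20         18     196.77     0.00            98.36
 60          6     199.68     0.00            99.82
360          1     200.03     0.00           100.00
```

With all 360 trials every estimator recovers the circular territory exactly
(to integer percent); the accumulation table shows how the detailed-hull
estimate climbs towards the true area as the number of equiangular trials
grows — by 12 trials it is within 5%, and beyond 20 trials consecutive
steps change the mean estimate by well under 2%.

The same pipeline is available from the shell:

```sh
territoria simulate --shape circle --seed 1 --out-dir runs/
territoria estimate hull --method dh --in points.geojson --out hull.geojson
territoria stc --calling calls.geojson --trials trials.csv --out stc.geojson
territoria report --estimator DH --seed 1 --out-dir runs/
```

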