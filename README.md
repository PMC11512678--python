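# pigeontrack

Analysis pipeline for the initial homing behaviour of GPS-tracked pigeons
released at unfamiliar sites, built around a 2×2 passive-exposure design:
birds are exposed to the visual and olfactory cues of one of two release
sites, then released the next day either at the same site (experimental
group) or at the other site (control group).  The package answers the
question "does passive exposure to a site improve subsequent homing?" with
the full statistical procedure, and ships a synthetic track generator so
every stage is testable without field data.

## What it computes

From each bird's 1 Hz fix stream (latitude, longitude, timestamp, logger
speed) the pipeline:

1. removes the initial fixes within a 500 m *escape radius* of the release
   point, drops fixes slower than 5 km/h (stops), and truncates the track at
   its **final exit** from an analysis radius (2 km and 5 km) — loops back
   into the circle are kept, so the segment ends at the true point of no
   return;
2. screens all bird pairs for **following** (time-aligned separation
   ≤ 100 m sustained ≥ 120 s): one bird of a same-group dyad is excluded at
   random, both birds of a cross-group dyad;
3. computes four per-bird metrics on the segment:
   * **virtual vanishing time** — seconds from release to the final radius
     exit;
   * **mean vector length** `r = ‖(mean cos θᵢ, mean sin θᵢ)‖` of the
     home-relative step directions θᵢ = bearing(fixᵢ→fixᵢ₊₁) −
     bearing(fixᵢ→home);
   * **efficiency index** — straight-line displacement over path length;
   * **homing efficiency index** — reduction of distance-to-home over path
     length (1 = straight flight home, negative = net movement away);
4. compares directional distributions between groups with two-sample
   **Hotelling T²** tests on the birds' mean-vector points
   (x, y) = (r·cos θ̄, r·sin θ̄), with `F = (n−3)/(2(n−2))·T²` on (2, n−3) df;
5. fits, for each metric × radius, the Type II linear model
   `metric ~ treatment group + release site` (vanishing times natural-log
   transformed) and reports F, df, p, partial η², the fitted mean
   difference with 95% CI, and Cohen's d `d = t·√(1/n₁+1/n₂)` with a
   noncentral-t 95% CI;
6. computes analytic post hoc **power** for the treatment term from a target
   partial η²: `f² = η²/(1−η²)`, noncentrality `λ = f²·N`, power =
   P[F′(1, N−3; λ) > F₀.₉₅(1, N−3)].

The simulator (`pigeontrack.simulate`) generates biased correlated random
walks: each second the heading is a von Mises draw centred on a mix of the
previous heading and the (site-bias-deflected) home direction, with weight
w on home.  Release-site bias, stop episodes, an escape phase, GPS noise
and follower dyads reproduce the structure the analysis has to cope with.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_preprocess_tracks.py --seed 1
python analysis/03_compute_metrics.py --seed 1
python analysis/04_statistical_inference.py --seed 1
python analysis/05_power_analysis.py
python analysis/06_figures.py --seed 1
```

Output of steps 02 and 04 with seed 1:

```
49 birds in; 8 following events -> 12 birds excluded for following
  analysed at 2000 m: 37 birds
  analysed at 5000 m: 37 birds

Hotelling release_site @2000 m: N=37, T2=15.60, F=7.58, p=0.002
Hotelling treatment    @2000 m: N=37, T2=2.56, F=1.24, p=0.301
efficiency_index @2000 m (n=37): treatment F(1,34)=3.11 p=0.087 eta2p=0.084;
                                 site F=8.04 p=0.008 diff=-0.100
```

Read: with no simulated treatment effect the treatment terms stay
non-significant, while the built-in release-site handicap produces the
strong site effects — site-2 birds orient more weakly and less efficiently
(negative fitted site differences for efficiency) and take longer to leave.
The power grid printed by step 05:

```
 partial_eta_sq  power_n31_pct  power_n34_pct
           0.01            8.4            8.8
           0.06           27.4           29.8
           0.14           58.3           62.5
           0.26           89.0           91.7
```

The same pipeline runs from the command line (`pigeontrack run --simulate`,
`pigeontrack power -n 31 -n 34`, …) or on real fix streams in the
`bird_id,datetime,lat,lon,speed_kmh` CSV dialect or GPX 1.1 via
`pigeontrack run --tracks fixes.csv --manifest manifest.csv`.

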