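# barreltree

Quantitative analysis of dendritic-tree refinement in neonatal mouse
barrel-cortex layer 4, and of the "patchwork" spontaneous activity that
drives it.

During the first postnatal week, layer-4 spiny stellate (SS) neurons at
the edge of a barrel reorient their basal dendrites (BDs) toward the
barrel center, where thalamocortical axons (TCAs) cluster. Longitudinal
two-photon imaging shows this happens not by smoothly bending branches but
by relentless *tree turnover*: whole BD trees are born and eliminated every
few hours, trees born on the barrel-center side survive far more often,
and the few stabilized "winner" trees elaborate steeply. `barreltree`
implements the measurements behind that picture for anyone working with
traced longitudinal morphologies (SWC) and calcium-imaging movies:

- **Morphometry** — dendritic-segment partition (processes > 5 µm),
  the orientation bias index
  `OBI = (inner BD segment length) / (total BD segment length)`
  about the boundary through the soma perpendicular to the soma→barrel-center
  direction, barrel-edge vs barrel-center soma classification (12.5 µm
  rule), and apical-dendrite (AD) trajectory classification: Group 1
  (retracting AD; prospective SS) vs Group 2 (continuously extending AD;
  star pyramid).
- **Session registration** — rotation-only least-squares alignment
  (θ = atan2(Σ a′×b′, Σ a′·b′) on centered soma coordinates) and
  mutual-nearest-neighbour identity tracking of neurons and tree origins,
  yielding a presence/absence matrix of every tree over every session.
- **Turnover & survival** — per-tree lifetimes in 8-h imaging frames,
  Kaplan–Meier curves with log(−log) 95% bands, log-rank tests
  (inner vs outer trees), one-frame elimination fractions, fate classes,
  and length-vs-survival profiles.
- **Calcium activity** — ΔF/F against a quiescent-frame F0, activated-zone
  segmentation (Gaussian σ = 10 px, ΔF/F > 100%, 8-connectivity, 2500 µm²
  area filter), boundary heat maps, 5×8 ROI-grid traces, rasters
  (ΔF/F > 50%), correlation matrices and PCA ordering.
- **Statistics** — Welch/paired t, Brunner–Munzel, Wilcoxon signed-rank,
  two-sided variance-ratio F test, Hedges' g / r effect sizes, Holm
  correction.
- **Synthetic data** — generators that emulate the full study: 8-session
  longitudinal datasets (P3_L…P5_L every 8 h, plus P6_L) with
  class-specific tree birth/death/growth dynamics and ground-truth event
  logs, and control vs nerve-cut spontaneous-activity movies.

## Worked example

Simulate 40 barrel-edge SS neurons over the default 8-session schedule,
track every tree, and measure orientation bias and turnover:

```python
import numpy as np
from barreltree.synthetic import SimConfig, gen_longitudinal_neurons
from barreltree.registration import build_presence_matrix
from barreltree.survival import (derive_survival_records,
                                 elimination_fraction, logrank_test)
from barreltree.morphometry import compute_obi, neuron_totals, fold_change

cfg = SimConfig(n_neurons=40,
                class_mix={"eSS": 1.0, "cSS": 0.0, "iSS": 0.0, "eSP": 0.0})
sim = gen_longitudinal_neurons(cfg, seed=1)
first, last = cfg.sessions[0], cfg.sessions[-1]

obi0 = np.mean([compute_obi(n, sim.barrel_map).obi for n in sim.dataset[first]])
obi1 = np.mean([compute_obi(n, sim.barrel_map).obi for n in sim.dataset[last]])
fold = fold_change(
    [neuron_totals(n)["total_bd_length"] for n in sim.dataset[first]],
    [neuron_totals(n)["total_bd_length"] for n in sim.dataset[last]])[0]

pm = build_presence_matrix(sim.dataset, barrel_map=sim.barrel_map)
recs = derive_survival_records(pm, window=(cfg.sessions[1], cfg.sessions[-2]))
inner = [r for r in recs if r.side == "inner"]
outer = [r for r in recs if r.side == "outer"]
```

Output for this seed:

```
mean OBI P3_L: 0.691
mean OBI P6_L: 0.869
total BD length fold change: 3.17
outer one-frame elimination: 82% (88/107)
inner one-frame elimination: 26% (25/96)
log-rank inner vs outer: chi2=69.21, p=8.87e-17
```

Reading: edge neurons start with a modest orientation bias (OBI ≈ 0.69 at
P3_L, driven by more inner than outer trees), which strengthens to ≈ 0.87
by P6_L while total BD length roughly triples. Newly formed outer trees
mostly vanish within one 8-h frame (82%), inner ones mostly persist
(26% eliminated), and the survival curves differ decisively — the selection
mechanism that builds the bias.

The same pipeline runs from the shell on SWC/GeoJSON/TIFF inputs:

```bash
barreltree simulate --seed 1 --n-neurons 20 --out run/
barreltree morpho   --data run/morphology --barrel-map run/barrel_map.geojson --out run/morpho
barreltree track    --data run/morphology --barrel-map run/barrel_map.geojson --out run/track
barreltree survival --presence run/track/presence_matrix.csv --out run/survival
barreltree report   --run-dir run --out run/summary.json
```

## File formats

- Morphology: SWC (type codes 1 = soma, 2 = axon, 3 = basal dendrite,
  4 = apical dendrite; coordinates in µm) with a JSON sidecar manifest
  per file (neuron id, session id, home barrel, tree ids).
- Barrel maps: GeoJSON polygons in µm with `id` and `center` properties.
- Movies: multi-page TIFF plus JSON metadata (`um_per_px`, `hz`,
  `excluded_frames`).
- Tables and matrices: CSV; run manifests and reports: JSON.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
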