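# asymdiv

Tools for studying how a microbial population can keep dividing in a poor
environment by **segregating a limiting cellular resource asymmetrically**.
The motivating system is budding yeast shifted to low-zinc medium: instead of
diluting the vacuolar zinc pool over the whole population, mother cells
retain the vacuole at each division, daughters are born resource-poor and
arrest in G1, and the colony switches from exponential to *linear* growth —
cell number increases at a constant rate set by the fixed cohort of dividing
mothers.

The package is aimed at quantitative cell biologists and modellers who want
to (a) explore the limiting-resource model, (b) generate realistic synthetic
single-cell data — lineage trees and dual-marker time-lapse movies — and
(c) test lineage-reconstruction and growth-statistics pipelines against
ground truth.

## The model

A progenitor enters a poor environment with an amount *Z*₀ of a
non-replenishable resource. Division is impossible below a critical level
*Z*c, and each division costs Δ*Z*.

* **Symmetric segregation** halves the pool every cycle, so division stops
  after ⌊log₂(*Z*₀/*Z*c)⌋ cycles and the population grows at most by
  *N*ₛ = *Z*₀/*Z*c.
* **Asymmetric segregation** (mother keeps the pool) supports
  *N*ₐₛ = (*Z*₀ − *Z*c)/Δ*Z* daughters — unbounded as Δ*Z* → 0.

When Δ*Z* is small relative to *Z*c the asymmetric strategy wins. The
agent-based simulator embeds this bookkeeping in a Start-like size rule, a
retention fraction *f* (0.5 = symmetric, →1 = full maternal retention),
medium-dependent resource regeneration, and regime presets (rich, low-metal
direct shift or pre-adapted, *whi5*, *vac17*, *zrc1-cot1*). A renderer turns
any simulated tree into a synthetic movie carrying exactly the cues a
tracking pipeline uses (nuclear-marker onset at nuclear separation, bud-neck
marker drop at cytokinesis, bright-field size proxy), and the reconstruction
module implements end-anchored tracking: segment the final frame only, track
every cell backwards, and read divisions off the two marker channels.

## Worked example

Closed-form capacities over a parameter grid:

```bash
$ asymdiv model --z0 16 --zc 1 --dz 0.1,1
Z0,Zc,deltaZ,Ns,Nas,cycles_symmetric,cells_symmetric,preferred
16,1,0.1,16,150,4,16,asymmetric
16,1,1,16,15,4,16,symmetric
```

With *Z*₀=16, *Z*c=1 a symmetric divider manages 4 cycles (16 cells) in
either case; an asymmetric progenitor yields 150 daughters when the
per-division loss is 0.1 but only 15 when it is 1, which flips the preferred
strategy.

Simulating the direct-shift low-metal regime and reading the statistics
back:

```python
import numpy as np
from asymdiv import preset, simulate_population, count_series
from asymdiv import growth_analysis as ga

low = simulate_population(preset("low_metal"), 30, 1500, seed=1)
divs = [len(f.division_times) for f in low.founders()]
gaps = ga.mother_interdivision_times(low)
print(ga.classify_growth_mode(count_series(low, horizon=700)))
print(f"{np.mean(divs):.1f} divisions per founder, "
      f"{np.mean(gaps):.1f} min mother cycle")
```

prints

```
linear
8.0 divisions per founder, 121.3 min mother cycle
```

i.e. counts rise linearly while each founder mother completes 8 post-shift
divisions at a ~120-min cycle before arresting; at 7 h the arrested
daughters are 35% smaller than their mothers
(`ga.size_distributions(tree, 420).gap`).

The same numbers can be produced from pixels instead of the tree: render
the tree (`asymdiv render`), reconstruct it from the movie's marker
channels (`asymdiv track`), and run `asymdiv analyze` on the reconstructed
tree — on noiseless renders the reconstruction is exact. `asymdiv pipeline`
chains all four stages and writes a checksummed manifest.

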