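# celltopo

Unsupervised classification of multicellular spatial patterns formed by
two adhering, motile cell types — a topological machine-learning
pipeline wrapped around an agent-based differential-adhesion simulator.

Mixtures of cell types sort, intermix, stripe, or arrange into
hexagonal spots and labyrinths depending on the relative strengths of
homotypic adhesion (blue–blue `J_BB`, orange–orange `J_OO`) and
heterotypic adhesion (`J_BO`). Recognizing which architecture a given
point cloud of labeled cell positions realizes — automatically, without
training labels — is the problem this package addresses, for anyone
studying tissue patterning, cell sorting, or synthetic multicellular
design in simulation or segmented imaging data.

## What it does

1. **Simulate** (`celltopo.sim_core`): overdamped self-propelled
   particles, `x_i ← x_i + (Δt/η)(P_i + Σ_j F_ij)`, with run-and-tumble
   repolarization and a type-dependent Morse pair potential
   `U(r) = −J_ij[e^{−r/l_A} − ¼ e^{−r/l_R}]` cut off at `r_max = 1.5`
   in a periodic box; optional contact-inhibited proliferation
   (division clock + ≤ 4-neighbor gate).
2. **Featurize** (`celltopo.tda_features`, `celltopo.order_params`):
   Vietoris–Rips persistence diagrams per cell-type channel (H0
   components, H1 loops; built-in reduction with a brute-force oracle),
   vectorized as lifespan-weighted Gaussian persistence images (1-D for
   H0, 2-D in (start, persistence) for H1) or Betti/life/Gaussian
   persistence curves; classical g(r) and ψ6 order parameters as the
   baseline.
3. **Classify** (`celltopo.embed_classify`): embed feature vectors to
   20-d (autoencoder, PCA, or UMAP), Ward-cluster at the phase-taxonomy
   size, and score against ground truth with optimal one-to-one label
   assignment; an RBF-SVM cross-validation provides the supervised
   cross-check.
4. **Ground truth** (`celltopo.phases`): an editable rule table maps
   each adhesion triple to one of the pattern phases (i–xii constant
   population, v–vii/ix–xv with proliferation), plus a fast generator
   of idealized pattern fixtures (sorted, checkerboard, stripes,
   hex spots, core–shell, labyrinth, ...).

See `docs/methods.md` for the model, conventions, parameter defaults,
and the limitations of the desk-scale protocol.

## Worked example

```python
import numpy as np
from celltopo import (SimulationConfig, AdhesionTable, run_simulation,
                      build_feature_vector, regime_label)

# strong homotypic, zero heterotypic adhesion: cells sort by type
cfg = SimulationConfig(n_cells=100, n_steps=200_000, box_halfwidth=14.0, seed=11)
pop = run_simulation(cfg, AdhesionTable.from_pairs(0.25, 0.25, 0.0))
print(pop.n_cells, regime_label(0.25, 0.25, 0.0))

fv = build_feature_vector(pop.positions, pop.types,
                          channels=("blue", "orange"), dims=(0, 1))
print(fv.values.shape, [p[:2] for p in fv.provenance])
```

prints

```
100 iv
(1000,) [('blue', 0), ('blue', 1), ('orange', 0), ('orange', 1)]
```

`iv` is the sorted-clusters phase (both homotypic adhesions strong,
heterotypic weak); the 1000-entry feature vector concatenates a 100-pixel
H0 image and a 20×20 H1 image for each of the two channels.

The same stages are scriptable from a shell:

```sh
celltopo simulate --config cond.yaml --seed 7 --out pos.csv
celltopo featurize --positions pos.csv --channels blue,orange --dims 0,1 --out feat.csv
celltopo embed --features feat.csv --method autoencoder --dim 20 --out emb.csv
celltopo classify --embedding emb.csv --n-clusters 12 --out labels.txt
celltopo report --labels labels.txt --truth truth.txt
```

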