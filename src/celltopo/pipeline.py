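"""End-to-end orchestration: adhesion sweeps -> featurization -> embedding
-> clustering -> accuracy, shared by the CLI, the tests, and the
acceptance script.

The full study design enumerates 8 values per adhesion axis without
proliferation (512 triples) and 6 values with proliferation (216 triples).
The reduced desk-scale protocol uses 4 values per axis (64 triples each),
N = 100 initial cells and 2e5 steps, which preserves every phase regime of
the rule table at a small fraction of the compute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .embed_classify import EmbeddingConfig, accuracy_vs_truth, \
    cluster_hierarchical, reduce_dimension
from .phases import regime_label
from .sim_core import AdhesionTable, SimulationConfig, run_simulation
from .tda_features import ImageConfig, build_feature_vector

__all__ = [
    "DEFAULT_CONSTANT_GRID", "DEFAULT_PROLIFERATION_GRID",
    "REDUCED_CONSTANT_GRID", "REDUCED_PROLIFERATION_GRID",
    "sweep_triples", "sweep_manifest", "run_sweep", "featurize_clouds",
    "classification_accuracy", "accuracy_report",
]

DEFAULT_CONSTANT_GRID = (0.0, 0.001, 0.05, 0.09, 0.13, 0.17, 0.21, 0.25)
DEFAULT_PROLIFERATION_GRID = (0.05, 0.09, 0.13, 0.17, 0.21, 0.25)
# Desk-scale protocol: 4 values per axis drawn from the default grids,
# chosen to span every phase regime of the rule table.
REDUCED_CONSTANT_GRID = (0.0, 0.05, 0.13, 0.25)
REDUCED_PROLIFERATION_GRID = (0.05, 0.09, 0.17, 0.25)


def sweep_triples(grid) -> list[tuple[float, float, float]]:
    """All (J_BB, J_OO, J_BO) combinations of one axis grid."""
    return [(b, o, x) for b, o, x in itertools.product(grid, grid, grid)]


def sweep_manifest(grid, seed: int, replicates: int = 1,
                   out_pattern="runs/J{J_BB}_{J_OO}_{J_BO}/rep{rep}.csv") -> pd.DataFrame:
    """Delimited manifest of a sweep: one row per (triple, replicate)."""
    triples = sweep_triples(grid)
    seeds = derive_seeds(seed, len(triples) * replicates)
    rows = []
    k = 0
    for (j_bb, j_oo, j_bo) in triples:
        for rep in range(replicates):
            rows.append({
                "J_BB": j_bb, "J_OO": j_oo, "J_BO": j_bo, "replicate": rep,
                "seed": seeds[k],
                "output_path": out_pattern.format(J_BB=j_bb, J_OO=j_oo,
                                                  J_BO=j_bo, rep=rep),
            })
            k += 1
    return pd.DataFrame(rows)


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-condition seeds below 2^31 from one master seed."""
    return (np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)).astype(np.int64)


def reduced_config(proliferation: bool, seed: int = 0) -> SimulationConfig:
    """Desk-scale simulation conditions: 100 cells for 2e5 steps.

    The box is shrunk to halfwidth 14 so the number density (~0.13
    cells per unit area) matches the full-scale study; pattern length
    scales are set by the interaction range and density, so preserving
    density preserves the local structure each adhesion regime produces.
    """
    return SimulationConfig(
        n_cells=100, n_steps=200_000, box_halfwidth=14.0,
        proliferation_enabled=proliferation, seed=seed)


def run_sweep(triples, base_config: SimulationConfig, seed: int,
              progress=None):
    """Run one simulation per adhesion triple; returns a list of
    ``(positions, types)`` final states. Per-condition seeds derive from
    ``seed`` so the sweep is reproducible as a whole."""
    seeds = derive_seeds(seed, len(triples))
    clouds = []
    for k, (j_bb, j_oo, j_bo) in enumerate(triples):
        cfg = replace(base_config, seed=int(seeds[k]))
        pop = run_simulation(cfg, AdhesionTable.from_pairs(j_bb, j_oo, j_bo))
        clouds.append((pop.positions, pop.types))
        if progress:
            progress(k, len(triples))
    return clouds


def featurize_clouds(clouds, channels=("both",), dims=(0, 1),
                     normalize: bool = False,
                     image_config: ImageConfig | None = None,
                     featurization: str = "images") -> np.ndarray:
    """Feature matrix with one row per cloud (condition)."""
    rows = [build_feature_vector(pos, types, channels=channels, dims=dims,
                                 featurization=featurization,
                                 image_config=image_config,
                                 normalize=normalize).values
            for pos, types in clouds]
    return np.vstack(rows)


def ground_truth_labels(triples, proliferation: bool) -> list[str]:
    return [regime_label(b, o, x, proliferation) for b, o, x in triples]


def classification_accuracy(features: np.ndarray, truth_labels,
                            method: str = "autoencoder", latent_dim: int = 20,
                            seed: int = 0, n_clusters: int | None = None,
                            ae_epochs: int = 400) -> float:
    """Unsupervised accuracy of embedding + Ward clustering vs truth.

    The dendrogram is cut at the number of distinct ground-truth phases
    (or an explicit ``n_clusters``).
    """
    truth = np.asarray(truth_labels)
    if n_clusters is None:
        n_clusters = np.unique(truth).size
    cfg = EmbeddingConfig(method=method,
                          latent_dim=min(latent_dim, features.shape[1]),
                          seed=seed, ae_epochs=ae_epochs)
    z = reduce_dimension(features, cfg)
    result = cluster_hierarchical(z, n_clusters)
    return accuracy_vs_truth(result.labels, truth)


@dataclass
class FeatureSetSpec:
    name: str
    channels: tuple
    dims: tuple
    normalize: bool = False


def accuracy_report(clouds, truth_labels, feature_sets, seed: int = 0,
                    method: str = "autoencoder",
                    image_config: ImageConfig | None = None,
                    ae_epochs: int = 400) -> pd.DataFrame:
    """Accuracy table over feature sets (rows mirror the channel/dimension
    grid of the study's accuracy figures)."""
    rows = []
    for spec in feature_sets:
        feats = featurize_clouds(clouds, channels=spec.channels,
                                 dims=spec.dims, normalize=spec.normalize,
                                 image_config=image_config)
        acc = classification_accuracy(feats, truth_labels, method=method,
                                      seed=seed, ae_epochs=ae_epochs)
        rows.append({"feature_set": spec.name,
                     "channels": "+".join(spec.channels),
                     "dims": "+".join(f"H{d}" for d in spec.dims),
                     "normalized": spec.normalize,
                     "accuracy": acc})
    return pd.DataFrame(rows)
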