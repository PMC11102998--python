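"""Self-contained synthetic drug-target interaction worlds.

A world mimics the structure of the benchmark DTI datasets without any
download: each entity type carries two feature views with planted cluster
structure (per view, cluster centroids drawn from a standard normal and
entities scattered around them with Gaussian noise), and interaction labels
follow a drug-cluster x target-cluster compatibility matrix with negatives
sampled uniformly from unused pairs at a 1:1 ratio.

The default world (200 drugs x 200 targets, 4x4 clusters, noise_sd 0.1,
1,000 positives, seed 7) is deliberately sparse in its compatibility
pattern: only two of the sixteen cluster cells interact.  Because negatives
are drawn blindly from unused pairs, denser patterns would contaminate the
negatives with structurally positive pairs and cap the achievable AUC of
any model well below 1; with two compatible cells the label process itself
supports AUC ~0.95, so end-to-end checks measure the model, not label
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    DrugRecord,
    FeatureMatrix,
    FeatureSource,
    InteractionPair,
    ProteinRecord,
)
from .errors import MifamError
from .protein_featurization import AMINO_ACIDS

#: Dimensions of the four synthetic views, mirroring the real feature widths
#: (drug descriptors, drug fingerprint, protein dipeptide composition,
#: protein embedding).
DEFAULT_VIEW_DIMS = (202, 167, 800, 256)


def default_compat(n_drug_clusters: int, n_target_clusters: int) -> np.ndarray:
    """Sparse one-to-one compatibility: cluster i interacts with cluster i,
    for the first two cluster indices only (see module docstring)."""
    compat = np.zeros((n_drug_clusters, n_target_clusters))
    for i in range(min(2, n_drug_clusters, n_target_clusters)):
        compat[i, i] = 1.0
    return compat


@dataclass
class WorldConfig:
    n_drugs: int = 200
    n_targets: int = 200
    n_drug_clusters: int = 4
    n_target_clusters: int = 4
    view_dims: tuple[int, int, int, int] = DEFAULT_VIEW_DIMS
    noise_sd: float = 0.1
    compat: np.ndarray | None = None
    n_positive: int = 1000
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_drug_clusters > self.n_drugs or self.n_target_clusters > self.n_targets:
            raise MifamError("cluster counts cannot exceed entity counts")
        if self.noise_sd < 0:
            raise MifamError("noise_sd must be >= 0")
        if self.compat is None:
            self.compat = default_compat(self.n_drug_clusters, self.n_target_clusters)
        self.compat = np.asarray(self.compat, dtype=np.float64)
        if self.compat.shape != (self.n_drug_clusters, self.n_target_clusters):
            raise MifamError("compat must be n_drug_clusters x n_target_clusters")
        if self.compat.min() < 0 or self.compat.max() > 1:
            raise MifamError("compat probabilities must lie in [0, 1]")


@dataclass
class SyntheticWorld:
    drug_views: tuple[FeatureMatrix, FeatureMatrix]
    target_views: tuple[FeatureMatrix, FeatureMatrix]
    pairs: list[InteractionPair]
    drug_clusters: np.ndarray
    target_clusters: np.ndarray
    config: WorldConfig = field(repr=False, default=None)


def _balanced_clusters(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.resize(np.arange(k), n)
    return rng.permutation(labels)


def _clustered_view(
    clusters: np.ndarray, dim: int, noise_sd: float,
    rng: np.random.Generator, source: FeatureSource, ids: list[str],
) -> FeatureMatrix:
    k = clusters.max() + 1
    centroids = rng.standard_normal((k, dim))
    X = centroids[clusters] + noise_sd * rng.standard_normal((len(clusters), dim))
    return FeatureMatrix(ids, X, source)


def generate_world(cfg: WorldConfig | None = None) -> SyntheticWorld:
    """Deterministically generate a labelled synthetic DTI world."""
    cfg = cfg or WorldConfig()
    rng = np.random.default_rng(cfg.seed)
    drug_ids = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    target_ids = [f"T{i:04d}" for i in range(cfg.n_targets)]
    dc = _balanced_clusters(cfg.n_drugs, cfg.n_drug_clusters, rng)
    tc = _balanced_clusters(cfg.n_targets, cfg.n_target_clusters, rng)

    # independent centroids per view so the two graphs disagree on some edges
    drug_views = (
        _clustered_view(dc, cfg.view_dims[0], cfg.noise_sd, rng,
                        FeatureSource.PCP, drug_ids),
        _clustered_view(dc, cfg.view_dims[1], cfg.noise_sd, rng,
                        FeatureSource.MACCS, drug_ids),
    )
    target_views = (
        _clustered_view(tc, cfg.view_dims[2], cfg.noise_sd, rng,
                        FeatureSource.DC, target_ids),
        _clustered_view(tc, cfg.view_dims[3], cfg.noise_sd, rng,
                        FeatureSource.EMB, target_ids),
    )

    # positives: weighted by the compatibility of the pair's cluster cell
    weights = cfg.compat[dc[:, None], tc[None, :]].ravel()
    total = weights.sum()
    if total <= 0:
        raise MifamError("compat matrix admits no positive pairs")
    n_all = cfg.n_drugs * cfg.n_targets
    n_compatible = int(np.count_nonzero(weights))
    if cfg.n_positive > n_compatible:
        raise MifamError(
            f"requested {cfg.n_positive} positives but only {n_compatible} "
            "compatible pairs exist"
        )
    pos_flat = rng.choice(n_all, size=cfg.n_positive, replace=False,
                          p=weights / total)
    pos_set = set(pos_flat.tolist())

    # negatives: uniform over unused pairs, without replacement, 1:1 ratio
    unused = np.setdiff1d(np.arange(n_all), pos_flat, assume_unique=False)
    if cfg.n_positive > len(unused):
        raise MifamError("not enough unused pairs for 1:1 negatives")
    neg_flat = rng.choice(unused, size=cfg.n_positive, replace=False)

    pairs = [
        InteractionPair(drug_ids[i // cfg.n_targets], target_ids[i % cfg.n_targets], 1)
        for i in sorted(pos_set)
    ] + [
        InteractionPair(drug_ids[i // cfg.n_targets], target_ids[i % cfg.n_targets], 0)
        for i in sorted(neg_flat.tolist())
    ]
    return SyntheticWorld(drug_views, target_views, pairs, dc, tc, cfg)


def shuffle_labels(world: SyntheticWorld, seed: int = 0) -> SyntheticWorld:
    """A null copy of the world: same pairs, labels randomly permuted."""
    rng = np.random.default_rng(seed)
    labels = rng.permutation([p.label for p in world.pairs])
    pairs = [
        InteractionPair(p.drug_id, p.protein_id, int(l))
        for p, l in zip(world.pairs, labels)
    ]
    return SyntheticWorld(world.drug_views, world.target_views, pairs,
                          world.drug_clusters, world.target_clusters, world.config)


def generate_protein_sequences(
    n: int, min_len: int = 50, max_len: int = 300, seed: int = 0
) -> list[ProteinRecord]:
    """Uniform random sequences over the 20 standard amino acids."""
    if min_len < 1 or max_len < min_len:
        raise MifamError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        records.append(ProteinRecord(f"P{i:04d}", seq))
    return records


#: Frozen SMILES fixtures: small, valid drug-like molecules.
_FIXTURE_SMILES: tuple[tuple[str, str], ...] = (
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("acetone", "CC(=O)C"),
    ("toluene", "Cc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("urea", "NC(N)=O"),
)


def fixture_smiles() -> list[DrugRecord]:
    """A frozen list of small valid SMILES used by featurization tests."""
    return [DrugRecord(name, smi) for name, smi in _FIXTURE_SMILES]
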