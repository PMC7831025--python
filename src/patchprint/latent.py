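"""Latent-space clustering: 2-D autoencoder embedding, K-means, and pairwise
centroid distances between cell-type clusters.

The embedding is for visualization and geometry only — classification always
runs on the 200-dimensional samples.  Distances are reported in latent-space
units and are not comparable across potentials (each potential gets an
independently trained autoencoder).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .autoencoder import AutoencoderSpec, TrainHyperparams, encode, train_autoencoder
from .errors import ConfigError, StageError

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    centroids: np.ndarray  # (K, d)
    assignments: np.ndarray  # sample -> cluster index
    inertia: float
    label_map: dict[int, str] | None = None  # cluster -> majority class
    distances: dict[tuple[str, str], float] | None = None


def kmeans(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """Lloyd's algorithm from random data-point initialization, Euclidean
    metric, best of ``n_init`` restarts by inertia."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ConfigError(f"K={k} exceeds the number of distinct points ({n_distinct})")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_init,
        algorithm="lloyd",
        random_state=seed,
    ).fit(points)
    return ClusterResult(
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        inertia=float(km.inertia_),
    )


def map_clusters_to_classes(result: ClusterResult, labels: np.ndarray) -> dict[int, str]:
    """Map each cluster to its majority true class.

    When two clusters share a majority class the maximum-agreement assignment
    over all permutations is used instead (exhaustive — K is small).
    Degenerate maps (fewer classes than clusters) are logged, not fatal.
    """
    labels = np.asarray(labels)
    k = result.centroids.shape[0]
    classes = sorted(set(labels))
    majority: dict[int, str] = {}
    for c in range(k):
        members = labels[result.assignments == c]
        if members.size == 0:
            majority[c] = classes[0]
            continue
        uniq, counts = np.unique(members, return_counts=True)
        majority[c] = sorted(uniq[counts == counts.max()])[0]

    if len(set(majority.values())) == k and len(classes) == k:
        return majority

    if len(classes) < k:
        log.warning(
            "degenerate cluster map: %d clusters but %d classes", k, len(classes)
        )
        return majority

    # resolve collisions by exhaustive maximum-agreement permutation
    best_map, best_agree = None, -1
    for perm in itertools.permutations(classes[:], k):
        agree = sum(
            int(np.sum(labels[result.assignments == c] == perm[c])) for c in range(k)
        )
        if agree > best_agree:
            best_agree = agree
            best_map = {c: perm[c] for c in range(k)}
    return best_map


def centroid_distances(result: ClusterResult) -> dict[tuple[str, str], float]:
    """Euclidean distances between class-mapped centroids, keyed by the
    sorted class pair.  Requires a bijective label map."""
    if result.label_map is None:
        raise ConfigError("cluster result has no label map")
    values = list(result.label_map.values())
    if len(set(values)) != len(values):
        raise StageError("label map is not bijective; distances are ill-defined")
    inv = {v: k for k, v in result.label_map.items()}
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(inv), 2):
        d = float(np.linalg.norm(result.centroids[inv[a]] - result.centroids[inv[b]]))
        out[(a, b)] = d
    return out


def embed_and_cluster(
    samples: np.ndarray,
    labels: np.ndarray,
    spec: AutoencoderSpec | None = None,
    hyperparams: TrainHyperparams | None = None,
    seed: int = 0,
    k: int | None = None,
) -> tuple[ClusterResult, np.ndarray]:
    """Compress pooled test samples to the bottleneck space, K-means them
    (K = number of classes by default), map clusters to classes and compute
    centroid distances.  Returns (ClusterResult, latent coordinates)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ConfigError("need samples from >= 2 classes to cluster the latent space")
    spec = spec or AutoencoderSpec()
    if spec.input_dim != samples.shape[1]:
        spec = AutoencoderSpec((samples.shape[1],) + spec.layer_widths[1:], spec.linear_output)
    hp = hyperparams or TrainHyperparams(epochs=100, seed=seed)
    model = train_autoencoder(samples, spec, hp)
    latent = encode(model, samples)
    result = kmeans(latent, k or len(classes), seed=seed)
    result.label_map = map_clusters_to_classes(result, labels)
    if len(set(result.label_map.values())) == len(result.label_map):
        result.distances = centroid_distances(result)
    return result, latent
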