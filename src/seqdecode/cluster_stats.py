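"""Group-level cluster-based permutation inference on frequency x time maps.

Multiple comparisons over the (frequency, time) grid are handled by cluster
mass: a one-sample t against chance is computed per cell, cells with t above
an entry threshold are grouped into 4-connected clusters, and each observed
cluster's mass (sum of t-values) is referred to the permutation distribution
of the *maximum* cluster mass obtained by randomly sign-flipping each
subject's deviation map (the standard one-sample permutation null).  Tests
are one-sided: only above-chance clusters are of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 4-connectivity: adjacent along the frequency or the time axis, no diagonals.
ADJACENCY_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    mask: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    t_threshold: float
    n_permutations: int
    perm_max_mass: np.ndarray

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c.p_value < alpha]


def _t_one_sample(d: np.ndarray) -> np.ndarray:
    """One-sample t across the subject (first) axis; zero-variance cells -> 0."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _max_cluster_mass(t: np.ndarray, threshold: float) -> float:
    lab, n_lab = ndimage.label(t > threshold, structure=ADJACENCY_4)
    if n_lab == 0:
        return 0.0
    masses = ndimage.sum_labels(t, lab, index=np.arange(1, n_lab + 1))
    return float(masses.max())


def cluster_permutation(
    subject_maps: np.ndarray,
    chance: float,
    t_threshold: float = 2.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected one-sided test of subject maps against chance.

    ``subject_maps`` is (subjects, freqs, times); all maps must share axes.
    Cluster p-values use the +1 correction: p = (1 + #{perm max >= mass}) /
    (n_permutations + 1), so the smallest attainable p is 1/(n_permutations+1).
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("subject_maps must be (subjects, freqs, times)")
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives a coarse null", stacklevel=2)

    d = maps - chance
    t_obs = _t_one_sample(d)

    lab, n_lab = ndimage.label(t_obs > t_threshold, structure=ADJACENCY_4)
    observed = []
    for k in range(1, n_lab + 1):
        mask = lab == k
        observed.append((mask, float(t_obs[mask].sum())))
    observed.sort(key=lambda c: -c[1])

    rng = np.random.default_rng(seed)
    n_cells = d.shape[1] * d.shape[2]
    d_flat = d.reshape(n_sub, n_cells)
    sq_sum = (d_flat**2).sum(axis=0)  # invariant under sign flips
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
    perm_max = np.empty(n_permutations)
    for i in range(n_permutations):
        m = signs[i] @ d_flat / n_sub
        var = (sq_sum - n_sub * m**2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var > 0, m / np.sqrt(var / n_sub), 0.0)
        perm_max[i] = _max_cluster_mass(t_perm.reshape(d.shape[1:]), t_threshold)

    clusters = [
        Cluster(
            mask=mask,
            mass=mass,
            p_value=(1.0 + np.sum(perm_max >= mass)) / (n_permutations + 1.0),
        )
        for mask, mass in observed
    ]
    return ClusterResult(
        clusters=clusters,
        t_map=t_obs,
        t_threshold=t_threshold,
        n_permutations=n_permutations,
        perm_max_mass=perm_max,
    )


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap of two boolean masks (intersection over union)."""
    inter = np.logical_and(mask_a, mask_b).sum()
    union = np.logical_or(mask_a, mask_b).sum()
    return float(inter) / union if union else 0.0
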