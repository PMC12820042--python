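"""Nonparametric cluster-based permutation testing.

Shared by the coherence feature selection (paired within-vs-between
contrast) and the univariate (BC-XY)/BC contrast (one-sample against
zero).  Elements of a channel x frequency x time map are clustered under a
declared adjacency: channel neighbors from the montage graph plus +-1 bins
in frequency and time.  Cluster mass is the summed t statistic; the null
distribution is the permutation distribution of the maximum cluster mass
under random sign flips of the per-participant (difference) maps, with the
observed statistic included in the null (so p > 0 always).

Positive and negative clusters are formed separately; for two-sided
inference both are compared against the null of the maximum absolute
cluster mass, which keeps the familywise rate at alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    members: np.ndarray  # flat element indices into the map
    mass: float
    p_value: float
    sign: int  # +1 / -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    shape: tuple[int, ...]
    n_permutations: int
    cluster_alpha: float
    alpha: float
    tail: str
    seed: int | None
    threshold: float
    null_max_mass: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value <= a]

    def significant_mask(self, alpha: float | None = None) -> np.ndarray:
        mask = np.zeros(int(np.prod(self.shape)), bool)
        for c in self.significant(alpha):
            mask[c.members] = True
        return mask.reshape(self.shape)

    def members_tsv(self) -> str:
        """TSV of member elements (cluster, channel, freq, time indices)."""
        lines = ["cluster\tsign\tchannel_idx\tfreq_idx\ttime_idx"]
        for k, c in enumerate(self.clusters):
            for flat in c.members:
                ch, f, t = np.unravel_index(flat, self.shape)
                lines.append(f"{k}\t{c.sign}\t{ch}\t{f}\t{t}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "alpha": self.alpha,
            "tail": self.tail,
            "seed": self.seed,
            "threshold": self.threshold,
            "clusters": [
                {
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "sign": c.sign,
                    "n_members": int(len(c.members)),
                }
                for c in self.clusters
            ],
        }


def grid_channel_edges(
    shape: tuple[int, int, int],
    channel_graph: dict[str, tuple[str, ...]] | None = None,
    channel_names: list[str] | None = None,
) -> np.ndarray:
    """Adjacency edge list (2, n_edges) of flat indices for a
    (channels, freqs, times) map: orthogonal +-1 steps in frequency and
    time, plus montage-graph edges across channels at identical
    (frequency, time).  ``channel_graph=None`` leaves channels isolated."""
    n_ch, n_f, n_t = shape
    idx = np.arange(n_ch * n_f * n_t).reshape(shape)
    edges = [
        np.stack([idx[:, :-1, :].ravel(), idx[:, 1:, :].ravel()]),
        np.stack([idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel()]),
    ]
    if channel_graph is not None:
        if channel_names is None:
            channel_names = list(channel_graph)
        pos = {c: i for i, c in enumerate(channel_names)}
        pairs = sorted(
            {
                (min(pos[a], pos[b]), max(pos[a], pos[b]))
                for a, nbrs in channel_graph.items()
                if a in pos
                for b in nbrs
                if b in pos and a != b
            }
        )
        for a, b in pairs:
            edges.append(np.stack([idx[a].ravel(), idx[b].ravel()]))
    return np.concatenate(edges, axis=1).astype(np.int32)


def _label_clusters(supra: np.ndarray, edges: np.ndarray, n: int):
    """Connected components of supra-threshold elements; returns
    (labels array of length n with -1 outside, n_clusters)."""
    keep = supra[edges[0]] & supra[edges[1]]
    sub = edges[:, keep]
    nodes = np.flatnonzero(supra)
    if len(nodes) == 0:
        return None, 0, nodes
    remap = np.full(n, -1, np.int32)
    remap[nodes] = np.arange(len(nodes), dtype=np.int32)
    g = sparse.coo_matrix(
        (np.ones(sub.shape[1], np.int8), (remap[sub[0]], remap[sub[1]])),
        shape=(len(nodes), len(nodes)),
    )
    n_comp, labels = connected_components(g, directed=False)
    return labels, n_comp, nodes


def _batch_max_masses(t_perm, pos_thr, neg_thr, edges, tail):
    """Per-permutation null statistic for a batch of t maps
    (n_perm_batch, n): the maximum cluster mass (absolute value for the
    two-sided tail) over all clusters of each map.

    All maps in the batch are labeled in a single connected-components
    call on a block-diagonal graph (each permutation is its own block)."""
    n_b, n = t_perm.shape
    out = np.zeros(n_b)
    tails = []
    if tail in ("two_sided", "pos"):
        tails.append(t_perm > pos_thr)
    if tail in ("two_sided", "neg"):
        tails.append(t_perm < neg_thr)
    for supra in tails:
        flat_nodes = np.flatnonzero(supra.ravel())
        if len(flat_nodes) == 0:
            continue
        emask = supra[:, edges[0]] & supra[:, edges[1]]
        rows, cols = np.nonzero(emask)
        e0 = rows * n + edges[0][cols]
        e1 = rows * n + edges[1][cols]
        remap = np.full(n_b * n, -1, np.int32)
        remap[flat_nodes] = np.arange(len(flat_nodes), dtype=np.int32)
        g = sparse.coo_matrix(
            (np.ones(len(e0), np.int8), (remap[e0], remap[e1])),
            shape=(len(flat_nodes), len(flat_nodes)),
        )
        n_comp, labels = connected_components(g, directed=False)
        masses = np.abs(np.bincount(labels, weights=t_perm.ravel()[flat_nodes], minlength=n_comp))
        perm_of_cluster = np.zeros(n_comp, np.int64)
        perm_of_cluster[labels] = flat_nodes // n  # clusters never span blocks
        np.maximum.at(out, perm_of_cluster, masses)
    return out


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def one_sample_cluster_test(
    x: np.ndarray,
    edges: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    tail: str = "two_sided",
    seed: int | None = 0,
    include_mask: np.ndarray | None = None,
) -> ClusterResult:
    """Sign-flip cluster permutation test of ``x`` (n_participants, *shape)
    against zero.

    ``edges`` is the flat adjacency from :func:`grid_channel_edges` (an
    empty edge list degrades to element-wise max-t correction).
    ``include_mask`` excludes elements (e.g. wavelet edge-invalid ones)
    from both clustering and the null.  When 2^n_participants <= the
    requested permutation count, the sign-flip null is enumerated exactly.
    """
    x = np.asarray(x, np.float64)
    n_sub = x.shape[0]
    shape = x.shape[1:]
    n = int(np.prod(shape))
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    if tail not in ("two_sided", "pos", "neg"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_permutations < 100:
        warnings.warn(f"n_permutations={n_permutations} is low for stable p-values")

    flat = x.reshape(n_sub, n)
    if include_mask is not None:
        flat = flat * include_mask.reshape(1, n)

    df = n_sub - 1
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    pos_thr, neg_thr = thr, -thr
    if tail == "pos":
        pos_thr, neg_thr = stats.t.ppf(1.0 - cluster_alpha, df), -np.inf
    elif tail == "neg":
        pos_thr, neg_thr = np.inf, stats.t.ppf(cluster_alpha, df)

    t_obs = _one_sample_t(flat)

    # observed clusters
    clusters: list[Cluster] = []
    for sign, supra in ((1, t_obs > pos_thr), (-1, t_obs < neg_thr)):
        labels, n_comp, nodes = _label_clusters(supra, edges, n)
        if n_comp == 0:
            continue
        masses = np.bincount(labels, weights=t_obs[nodes], minlength=n_comp)
        for k in range(n_comp):
            clusters.append(
                Cluster(members=nodes[labels == k], mass=float(masses[k]), p_value=1.0, sign=sign)
            )

    # sign-flip null of the max cluster mass (vectorized t computation)
    if 2**n_sub <= n_permutations:
        signs = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(n_sub)] for i in range(2**n_sub)],
            np.float64,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
        signs[0] = 1.0  # observed labeling included in the null
    n_perm = signs.shape[0]

    ss = (flat**2).sum(axis=0)  # invariant under sign flips
    null_max = np.empty(n_perm)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n_perm, chunk):
        s = signs[start : start + chunk]
        mean = (s @ flat) / n_sub
        var = (ss[None, :] - n_sub * mean**2) / df
        np.maximum(var, 0.0, out=var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n_sub)
        t_perm[~np.isfinite(t_perm)] = 0.0
        null_max[start : start + s.shape[0]] = _batch_max_masses(
            t_perm, pos_thr, neg_thr, edges, tail
        )

    for c in clusters:
        # tolerance so the observed labeling (recomputed in the vectorized
        # permutation path) always counts as >= its own mass
        cutoff = abs(c.mass) * (1 - 1e-9) - 1e-12
        exceed = int(np.sum(null_max >= cutoff))
        c.p_value = (1 + exceed) / (1 + n_perm)

    clusters.sort(key=lambda c: -abs(c.mass))
    n_sig = sum(c.p_value <= alpha for c in clusters)
    logger.info(
        "cluster test: %d clusters (%d significant at alpha=%.3g), %d permutations",
        len(clusters), n_sig, n_perm,
    )
    return ClusterResult(
        clusters=clusters,
        shape=shape,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        alpha=alpha,
        tail=tail,
        seed=seed,
        threshold=thr if tail == "two_sided" else (pos_thr if tail == "pos" else neg_thr),
        null_max_mass=null_max,
    )


def paired_cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    edges: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    tail: str = "two_sided",
    seed: int | None = 0,
    include_mask: np.ndarray | None = None,
) -> ClusterResult:
    """Paired cluster permutation test of cond_a vs cond_b
    (n_participants, *shape each): one-sample sign-flip test on the
    participant difference maps."""
    cond_a = np.asarray(cond_a)
    cond_b = np.asarray(cond_b)
    if cond_a.shape != cond_b.shape:
        raise ValueError(f"shape mismatch: {cond_a.shape} vs {cond_b.shape}")
    return one_sample_cluster_test(
        cond_a - cond_b,
        edges,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        alpha=alpha,
        tail=tail,
        seed=seed,
        include_mask=include_mask,
    )
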