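"""Univariate BC-vs-XY power contrast and its link to pattern similarity.

Per participant, linear-scale spectra are averaged over all BC and all XY
trials (repetition zero excluded upstream) and contrasted as
``(BC - XY) / BC`` elementwise - an asymmetric index, scaled by BC power
to absorb between-participant amplitude differences.  The index is tested
against zero with the sign-flip cluster permutation machinery separately
within each movie-segment window; trial-level power averaged inside a
significant cluster can then be regressed on the matched RSA window
similarity (MVNIG regression with standardized variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import MVNIGRegressionResult, mvnig_regression
from .cluster import ClusterResult, grid_channel_edges, one_sample_cluster_test
from .design import AB_SEGMENTS, ExperimentDesign
from .tfr import edge_validity


@dataclass
class PowerContrast:
    """(BC - XY)/BC index maps per participant, channels x freqs x times."""

    index: np.ndarray  # (n_participants, ch, freq, time)
    invalid: np.ndarray  # elements where BC power was 0 (undefined)
    freqs_hz: np.ndarray
    times_s: np.ndarray


def power_contrast(
    bc_mean: np.ndarray,
    xy_mean: np.ndarray,
    freqs_hz: np.ndarray,
    times_s: np.ndarray,
) -> PowerContrast:
    """Relative power index from per-participant mean linear-scale cubes
    (n_participants, ch, freq, time each).  Elements with zero BC power
    are flagged invalid and excluded from tests, not NaN-propagated."""
    bc_mean = np.asarray(bc_mean, float)
    xy_mean = np.asarray(xy_mean, float)
    if bc_mean.shape != xy_mean.shape:
        raise ValueError(f"grid mismatch: {bc_mean.shape} vs {xy_mean.shape}")
    if np.any(bc_mean < 0) or np.any(xy_mean < 0):
        raise ValueError("cubes must be linear-scale (nonnegative) power")
    invalid = bc_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        index = (bc_mean - xy_mean) / bc_mean
    index = np.where(invalid, 0.0, index)
    return PowerContrast(index, invalid, np.asarray(freqs_hz), np.asarray(times_s))


def segmentwise_tests(
    contrast: PowerContrast,
    design: ExperimentDesign,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    n_cycles: float = 5.0,
) -> dict[str, ClusterResult]:
    """One-sample (vs 0) sign-flip cluster permutation of the index within
    each movie-content segment window, both tails.  Segment tests run on
    disjoint windows, so they can never share cluster members."""
    n_sub, n_ch, n_f, _ = contrast.index.shape
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    valid = edge_validity(contrast.times_s, contrast.freqs_hz, n_cycles)
    results: dict[str, ClusterResult] = {}
    for seg in AB_SEGMENTS:
        lo, hi = design.segment_window(seg)
        cols = np.flatnonzero(
            (contrast.times_s >= lo - 1e-9) & (contrast.times_s < hi - 1e-9)
        )
        if len(cols) == 0:
            continue
        x = contrast.index[..., cols]
        mask = np.broadcast_to(valid[None, :, cols], x.shape[1:]) & ~np.any(
            contrast.invalid[..., cols], axis=0
        )
        edges = grid_channel_edges(
            (n_ch, n_f, len(cols)), design.neighbor_graph, design.channel_names
        )
        results[seg] = one_sample_cluster_test(
            x,
            edges,
            n_permutations=n_permutations,
            cluster_alpha=cluster_alpha,
            alpha=alpha,
            tail="two_sided",
            seed=seed,
            include_mask=mask,
        )
    return results


def power_similarity_link(
    cluster_power: np.ndarray,
    window_similarity: np.ndarray,
    controls: pd.DataFrame | None = None,
    trial_ids: np.ndarray | None = None,
) -> MVNIGRegressionResult:
    """Does trial-level cluster-mean power predict the matched RSA window
    similarity?  Delegates to the MVNIG regression with standardized
    variables; the power coefficient's BF10 is the evidence for a link."""
    cluster_power = np.asarray(cluster_power, float).ravel()
    window_similarity = np.asarray(window_similarity, float).ravel()
    if len(cluster_power) != len(window_similarity):
        first = trial_ids[0] if trial_ids is not None else 0
        raise ValueError(
            f"trial alignment mismatch ({len(cluster_power)} power vs "
            f"{len(window_similarity)} similarity values; first trial {first})"
        )
    X = pd.DataFrame({"cluster_power": cluster_power})
    if controls is not None:
        if len(controls) != len(cluster_power):
            raise ValueError("controls not aligned with trials")
        X = pd.concat([X, controls.reset_index(drop=True)], axis=1)
    return mvnig_regression(window_similarity, X, standardize=True)
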