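"""Wavelet coherence and the within-vs-between movie contrast.

Magnitude-squared wavelet coherence between two epochs x and y,

    C = |S(Wx conj(Wy))|^2 / (S(|Wx|^2) S(|Wy|^2)),

where W are complex Morlet coefficients (the same 5-cycle family as the
power analysis) and S is a smoothing operator applied along time (a box
kernel variance-matched to a target sigma of a fixed number of wavelet
periods at each frequency; repeated passes approximate a Gaussian) and
across adjacent frequency bins (boxcar).  By Cauchy-Schwarz over the
shared nonnegative kernel the result lies in [0, 1] and equals 1 when
y = x.

Averaging the per-pair coherence over all within-movie repetition pairs
versus all between-movie pairs, and contrasting the two maps across
participants with a cluster permutation test inside each movie-segment
window, yields boolean channel x frequency x time templates of the
features sensitive to movie content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .cluster import ClusterResult, grid_channel_edges, paired_cluster_test
from .design import AB_SEGMENTS, ExperimentDesign, PairSet
from .tfr import edge_validity, morlet_coefficients

logger = logging.getLogger(__name__)


@dataclass
class SmoothingSpec:
    """Smoothing for the coherence estimator.  ``time_halfwidth_periods``
    is the kernel's standard deviation in wavelet periods at each
    frequency (so the kernel adapts to frequency); ``scale_halfwidth_bins``
    is the boxcar halfwidth over adjacent frequency bins.  The time kernel
    is realized as ``n_passes`` box-filter passes with the box width
    variance-matched to the requested sigma: one pass is a plain boxcar,
    three passes approximate a Gaussian to within a few percent."""

    time_halfwidth_periods: float = 3.0
    scale_halfwidth_bins: int = 1
    n_passes: int = 1

    def sigmas_samples(self, freqs: np.ndarray, time_step_s: float) -> np.ndarray:
        sig = self.time_halfwidth_periods / (np.asarray(freqs, float) * time_step_s)
        return np.maximum(sig, 1.0)


@dataclass
class CoherenceMap:
    coherence: np.ndarray  # (channels, freqs, times) in [0, 1]
    freqs_hz: np.ndarray
    times_s: np.ndarray
    pair_kind: str
    smoothing: SmoothingSpec


@dataclass
class FeatureTemplate:
    """Boolean mask of movie-content-sensitive cells for one segment."""

    segment_name: str
    mask: np.ndarray  # (channels, freqs, n_window_times)
    freqs_hz: np.ndarray
    times_s: np.ndarray  # times of the window columns
    cluster_provenance: ClusterResult | None = None

    @property
    def n_cells(self) -> int:
        return int(self.mask.any(axis=-1).sum())

    def cell_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(channel_idx, freq_idx) of active cells, channel-major with
        frequency ascending within channel ("head to tail" order)."""
        ch, fr = np.nonzero(self.mask.any(axis=-1))
        return ch, fr


def _box_smooth_time(x: np.ndarray, sigmas: np.ndarray, n_passes: int = 1) -> np.ndarray:
    """Per-frequency smoothing along the last axis via repeated box passes
    (O(n) per pass), box width variance-matched to the target sigma.
    ``x`` has shape (..., n_freqs, n_times); may be complex."""
    out = np.empty_like(x)
    for k, s in enumerate(sigmas):
        w = int(round(np.sqrt(12.0 * s * s / n_passes + 1.0)))
        w += 1 - w % 2  # odd
        y = x[..., k, :]
        if np.iscomplexobj(x):
            re, im = np.ascontiguousarray(y.real), np.ascontiguousarray(y.imag)
            for _ in range(n_passes):
                re = uniform_filter1d(re, w, axis=-1, mode="reflect")
                im = uniform_filter1d(im, w, axis=-1, mode="reflect")
            out[..., k, :] = re + 1j * im
        else:
            for _ in range(n_passes):
                y = uniform_filter1d(y, w, axis=-1, mode="reflect")
            out[..., k, :] = y
    return out


def _smooth(
    x: np.ndarray, sigmas: np.ndarray, freq_halfwidth: int, n_passes: int = 1
) -> np.ndarray:
    y = _box_smooth_time(x, sigmas, n_passes)
    if freq_halfwidth >= 1:
        size = 2 * freq_halfwidth + 1
        if np.iscomplexobj(y):
            y = uniform_filter1d(y.real, size, axis=-2, mode="nearest") + 1j * uniform_filter1d(
                y.imag, size, axis=-2, mode="nearest"
            )
        else:
            y = uniform_filter1d(y, size, axis=-2, mode="nearest")
    return y


def smoothed_autopower(
    coeffs: np.ndarray, freqs: np.ndarray, time_step_s: float, smoothing: SmoothingSpec
) -> np.ndarray:
    """S(|W|^2) for a bank of coefficient arrays (..., freqs, times)."""
    power = coeffs.real.astype(np.float32) ** 2 + coeffs.imag.astype(np.float32) ** 2
    return _smooth(
        power,
        smoothing.sigmas_samples(freqs, time_step_s),
        smoothing.scale_halfwidth_bins,
        smoothing.n_passes,
    )


def coherence_from_coefficients(
    wx: np.ndarray,
    wy: np.ndarray,
    freqs: np.ndarray,
    time_step_s: float,
    smoothing: SmoothingSpec,
    sx: np.ndarray | None = None,
    sy: np.ndarray | None = None,
) -> np.ndarray:
    """Magnitude-squared coherence from complex coefficients
    (..., channels, freqs, times); ``sx``/``sy`` are precomputed smoothed
    auto-power arrays (recomputed when omitted).  Elements with zero
    smoothed auto-power are set to 0 and reported, never NaN-propagated."""
    sig = smoothing.sigmas_samples(freqs, time_step_s)
    if sx is None:
        sx = smoothed_autopower(wx, freqs, time_step_s, smoothing)
    if sy is None:
        sy = smoothed_autopower(wy, freqs, time_step_s, smoothing)
    cross = _smooth(
        (wx * np.conj(wy)).astype(np.complex64), sig, smoothing.scale_halfwidth_bins, smoothing.n_passes
    )
    denom = sx * sy
    bad = denom <= 0
    num = cross.real**2 + cross.imag**2
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = num / denom
    if np.any(bad):
        logger.warning("coherence: %d elements with zero auto-power set to 0", int(bad.sum()))
        coh = np.where(bad, 0.0, coh)
    return np.clip(coh, 0.0, 1.0)


def wavelet_coherence(
    epoch_x: np.ndarray,
    epoch_y: np.ndarray,
    sfreq: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    decim: int = 1,
    smoothing: SmoothingSpec | None = None,
) -> CoherenceMap:
    """Wavelet coherence of two equal-shape (channels, samples) epochs."""
    smoothing = smoothing or SmoothingSpec()
    if epoch_x.shape != epoch_y.shape:
        raise ValueError(f"epoch shapes differ: {epoch_x.shape} vs {epoch_y.shape}")
    if freqs is None:
        freqs = np.arange(3.0, 31.0)
    wx = morlet_coefficients(epoch_x, sfreq, freqs, n_cycles, decim)
    wy = morlet_coefficients(epoch_y, sfreq, freqs, n_cycles, decim)
    step = decim / sfreq
    coh = coherence_from_coefficients(wx, wy, freqs, step, smoothing)
    times = np.arange(coh.shape[-1]) * step
    return CoherenceMap(coh, np.asarray(freqs), times, "custom", smoothing)


class CoefficientBank:
    """Complex Morlet coefficients for every (movie, repetition) of one
    participant, with cached smoothed auto-power for coherence averaging."""

    def __init__(
        self,
        coeffs: dict[tuple[str, int], np.ndarray],
        freqs: np.ndarray,
        times_s: np.ndarray,
        smoothing: SmoothingSpec | None = None,
    ):
        self.coeffs = coeffs
        self.freqs = np.asarray(freqs, float)
        self.times_s = times_s
        self.smoothing = smoothing or SmoothingSpec()
        self._auto: dict[tuple[str, int], np.ndarray] = {}

    @property
    def time_step_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def autopower(self, key: tuple[str, int]) -> np.ndarray:
        if key not in self._auto:
            self._auto[key] = smoothed_autopower(
                self.coeffs[key], self.freqs, self.time_step_s, self.smoothing
            )
        return self._auto[key]

    def precompute_autopower(self) -> None:
        """Smooth all epochs' auto-power in one batched pass."""
        keys = [k for k in self.coeffs if k not in self._auto]
        if not keys:
            return
        stack = np.stack([self.coeffs[k] for k in keys])
        smoothed = smoothed_autopower(stack, self.freqs, self.time_step_s, self.smoothing)
        for i, k in enumerate(keys):
            self._auto[k] = smoothed[i]


def participant_coherence_summary(
    bank: CoefficientBank,
    pairs_within: list[PairSet],
    pairs_between: list[PairSet],
    batch: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean coherence maps over all within-movie and all between-movie
    pairs of one participant; each (channels, freqs, times).

    Pairs whose repetitions are missing from the bank are skipped with a
    logged count; a movie with no usable pair at all raises."""
    bank.precompute_autopower()

    def mean_over(pairsets: list[PairSet], kind: str) -> np.ndarray:
        flat = [p for ps in pairsets for p in ps.pairs]
        usable = [(a, b) for a, b in flat if a in bank.coeffs and b in bank.coeffs]
        n_missing = len(flat) - len(usable)
        if n_missing:
            logger.warning("%s: skipped %d pairs with missing repetitions", kind, n_missing)
        if not usable:
            raise ValueError(f"no usable {kind} pairs (all repetitions missing)")
        acc = None
        step = bank.time_step_s
        for start in range(0, len(usable), batch):
            chunk = usable[start : start + batch]
            wx = np.stack([bank.coeffs[a] for a, _ in chunk])
            wy = np.stack([bank.coeffs[b] for _, b in chunk])
            sx = np.stack([bank.autopower(a) for a, _ in chunk])
            sy = np.stack([bank.autopower(b) for _, b in chunk])
            coh = coherence_from_coefficients(
                wx, wy, bank.freqs, step, bank.smoothing, sx=sx, sy=sy
            )
            s = coh.sum(axis=0, dtype=np.float64)
            acc = s if acc is None else acc + s
        return acc / len(usable)

    within = mean_over(pairs_within, "within_movie")
    between = mean_over(pairs_between, "between_movie")
    return within, between


def select_template(
    within_maps: np.ndarray,
    between_maps: np.ndarray,
    times_s: np.ndarray,
    freqs: np.ndarray,
    design: ExperimentDesign,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    collapse_channels: bool = False,
    n_cycles: float = 5.0,
) -> list[FeatureTemplate]:
    """Cluster-permutation contrast of within- vs between-movie coherence
    (n_participants, channels, freqs, times), run separately inside each of
    the four AB-movie segment windows; returns one template per segment
    from the positive (within > between) significant clusters.  Segments
    with no significant cluster yield an empty mask and a warning; all
    templates are time-disjoint by construction."""
    within_maps = np.asarray(within_maps)
    between_maps = np.asarray(between_maps)
    if within_maps.shape != between_maps.shape:
        raise ValueError("within/between map shapes differ")
    n_sub, n_ch, n_f, _ = within_maps.shape
    valid = edge_validity(times_s, freqs, n_cycles)

    templates = []
    for seg in AB_SEGMENTS:
        lo, hi = design.segment_window(seg)
        cols = np.flatnonzero((times_s >= lo - 1e-9) & (times_s < hi - 1e-9))
        a = within_maps[..., cols]
        b = between_maps[..., cols]
        vmask = np.broadcast_to(valid[None, :, cols], a.shape[1:])
        if collapse_channels:
            a = a.mean(axis=1, keepdims=True)
            b = b.mean(axis=1, keepdims=True)
            vmask = vmask[:1]
            edges = grid_channel_edges((1, n_f, len(cols)))
        else:
            edges = grid_channel_edges(
                (n_ch, n_f, len(cols)), design.neighbor_graph, design.channel_names
            )
        res = paired_cluster_test(
            a,
            b,
            edges,
            n_permutations=n_permutations,
            cluster_alpha=cluster_alpha,
            alpha=alpha,
            tail="two_sided",
            seed=seed,
            include_mask=vmask,
        )
        mask = np.zeros(a.shape[1:], bool)
        for c in res.significant():
            if c.sign > 0:
                m = np.zeros(int(np.prod(a.shape[1:])), bool)
                m[c.members] = True
                mask |= m.reshape(a.shape[1:])
        if collapse_channels:
            mask = np.broadcast_to(mask, (n_ch, n_f, len(cols))).copy()
        if not mask.any():
            logger.warning("segment %s: no significant positive cluster; empty template", seg)
        templates.append(
            FeatureTemplate(
                segment_name=seg,
                mask=mask,
                freqs_hz=np.asarray(freqs),
                times_s=times_s[cols],
                cluster_provenance=res,
            )
        )
    return templates
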