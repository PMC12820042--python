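"""Template-based feature extraction and time-resolved pattern similarity.

For each AB movie, the dB-scaled time-frequency cube is averaged over the
five repetitions, masked by a segment's feature template, and reduced to a
channel x frequency feature map by taking the median along time (a
shift-robust summary); the map is flattened channel-major ("head to
tail") into the anchor feature vector.  At every timepoint of a BC or XY
epoch the same cells are read out, Pearson-correlated with the anchor, and
Fisher z-transformed, giving one similarity value per 0.02-s step.

Two baseline families turn raw similarity into a specificity contrast:
the same anchor against XY movies (novel controls) or against
non-corresponding BC movies (general-reinstatement control); the contrast
is the anchor-vs-corresponding z minus the mean of the baseline z series,
averaged in z space.  Repetition zero of BC/XY trials is excluded
upstream (no reactivation is expected on first exposure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import FeatureTemplate
from .tfr import TimeFrequencyCube

Z_CLIP = 1.0 - 1e-7


@dataclass
class FeatureVector:
    """Anchor pattern over the template's (channel, frequency) cells."""

    values: np.ndarray
    cell_channels: np.ndarray
    cell_freqs: np.ndarray
    segment_name: str
    movie_id: str


@dataclass
class SimilaritySeries:
    """Fisher-z similarity per timepoint of the comparison epoch."""

    z: np.ndarray  # NaN where invalid
    times_s: np.ndarray
    anchor_movie: str
    anchor_segment: str
    target_movie: str
    target_role: str
    target_repetition: int
    baseline_applied: str = "none"


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 - 1e-7 before the transform."""
    return np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))


def extract_ab_features(
    mean_db_cube: TimeFrequencyCube, template: FeatureTemplate, movie_id: str
) -> FeatureVector:
    """Anchor features of one AB movie from its repetition-averaged dB cube.

    Per active (channel, frequency) cell, the median over the template's
    true timepoints for that cell; cells ordered channel-major, frequency
    ascending within channel."""
    if template.n_cells == 0:
        raise ValueError(f"empty template for segment {template.segment_name!r}")
    if mean_db_cube.scale != "db":
        raise ValueError("cube must be dB-scaled")
    step = mean_db_cube.time_step_s
    cols = mean_db_cube.time_indices((template.times_s[0], template.times_s[-1] + step / 2))
    if len(cols) != template.mask.shape[-1]:
        raise ValueError(
            f"template window ({template.mask.shape[-1]} cols) does not align with "
            f"cube time axis ({len(cols)} cols)"
        )
    sub = mean_db_cube.data[..., cols]  # (ch, freq, win)
    ch_idx, f_idx = template.cell_indices()
    values = np.empty(len(ch_idx))
    for i, (c, f) in enumerate(zip(ch_idx, f_idx)):
        values[i] = np.median(sub[c, f, template.mask[c, f]])
    return FeatureVector(values, ch_idx, f_idx, template.segment_name, movie_id)


def _masked_timecourse_matrix(
    cube: TimeFrequencyCube, cell_channels: np.ndarray, cell_freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(cells x times) readout and per-timepoint validity (a timepoint is
    invalid when more than half its cells fall in the wavelet edge)."""
    X = cube.data[cell_channels, cell_freqs, :]
    if cube.valid is not None:
        frac_bad = (~cube.valid[cell_freqs, :]).mean(axis=0)
        tvalid = frac_bad <= 0.5
    else:
        tvalid = np.ones(X.shape[-1], bool)
    return X, tvalid


def similarity_timecourse(
    anchor: FeatureVector, target_cube: TimeFrequencyCube, template: FeatureTemplate,
    target_movie: str = "", target_role: str = "", target_repetition: int = -1,
) -> SimilaritySeries:
    """Fisher-z Pearson correlation of the anchor vector with the target's
    masked (channel, frequency) pattern at each timepoint.

    Timepoints with zero pattern variance (or dominated by wavelet-edge
    cells) are marked invalid (NaN), never zero."""
    if target_cube.scale != "db":
        raise ValueError("target cube must be dB-scaled")
    ch_idx, f_idx = template.cell_indices()
    if len(ch_idx) != len(anchor.values) or not (
        np.array_equal(ch_idx, anchor.cell_channels) and np.array_equal(f_idx, anchor.cell_freqs)
    ):
        raise ValueError("anchor layout does not match template cells")
    X, tvalid = _masked_timecourse_matrix(target_cube, ch_idx, f_idx)
    a = anchor.values - anchor.values.mean()
    na = np.linalg.norm(a)
    Xc = X - X.mean(axis=0, keepdims=True)
    nx = np.linalg.norm(Xc, axis=0)
    ok = tvalid & (nx > 0) & (na > 0)
    r = np.full(X.shape[-1], np.nan)
    r[ok] = (a @ Xc[:, ok]) / (na * nx[ok])
    return SimilaritySeries(
        z=fisher_z(r),
        times_s=target_cube.times_s,
        anchor_movie=anchor.movie_id,
        anchor_segment=anchor.segment_name,
        target_movie=target_movie,
        target_role=target_role,
        target_repetition=target_repetition,
    )


def baseline_contrast(
    sim_corr: SimilaritySeries, sim_baselines: list[SimilaritySeries], mode: str
) -> SimilaritySeries:
    """z_corr(t) minus the mean over baseline series of z_b(t), averaged in
    z space.  ``mode`` labels the baseline family ("vs_xy" or
    "vs_noncorresponding_bc")."""
    if not sim_baselines:
        raise ValueError("empty baseline list")
    for b in sim_baselines:
        if len(b.z) != len(sim_corr.z):
            raise ValueError("baseline series do not share the time axis")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        base = np.nanmean(np.stack([b.z for b in sim_baselines]), axis=0)
    return SimilaritySeries(
        z=sim_corr.z - base,
        times_s=sim_corr.times_s,
        anchor_movie=sim_corr.anchor_movie,
        anchor_segment=sim_corr.anchor_segment,
        target_movie=sim_corr.target_movie,
        target_role=sim_corr.target_role,
        target_repetition=sim_corr.target_repetition,
        baseline_applied=mode,
    )


def series_to_tsv(series_list: list[SimilaritySeries], participant: int | None = None) -> str:
    """Long-format TSV (participant, anchor, target, repetition, time_s, z,
    contrast_mode) for audit and plotting."""
    lines = ["participant\tanchor\ttarget\trepetition\ttime_s\tz\tcontrast_mode"]
    for s in series_list:
        for t, z in zip(s.times_s, s.z):
            lines.append(
                f"{'' if participant is None else participant}\t{s.anchor_movie}\t"
                f"{s.target_movie}\t{s.target_repetition}\t{t:.3f}\t"
                f"{'' if not np.isfinite(z) else format(z, '.6g')}\t{s.baseline_applied}"
            )
    return "\n".join(lines) + "\n"


def window_average(series: SimilaritySeries, window: tuple[float, float]) -> float:
    """Mean z over valid timepoints in [start_s, end_s)."""
    lo, hi = window
    sel = (series.times_s >= lo - 1e-9) & (series.times_s < hi - 1e-9)
    vals = series.z[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError(
            f"no valid timepoint in window [{lo}, {hi}) for anchor "
            f"{series.anchor_movie} vs {series.target_movie}"
        )
    return float(vals.mean())


def neighborhood_topography(
    anchor: FeatureVector,
    target_cube: TimeFrequencyCube,
    template: FeatureTemplate,
    neighbor_graph: dict[str, tuple[str, ...]],
    channel_names: list[str],
) -> np.ndarray:
    """Searchlight variant: per channel, correlate using only that channel's
    and its neighbors' template cells, giving a (channels x timepoints) z
    map.  Channels whose neighborhood holds fewer than 2 template cells are
    all-NaN (marked invalid)."""
    ch_idx, f_idx = template.cell_indices()
    pos = {c: i for i, c in enumerate(channel_names)}
    n_t = target_cube.data.shape[-1]
    out = np.full((len(channel_names), n_t), np.nan)
    for c_name in channel_names:
        hood = {pos[c_name]} | {pos[n] for n in neighbor_graph.get(c_name, ()) if n in pos}
        sel = np.isin(ch_idx, sorted(hood))
        if sel.sum() < 2:
            continue
        X, tvalid = _masked_timecourse_matrix(target_cube, ch_idx[sel], f_idx[sel])
        a = anchor.values[sel]
        a = a - a.mean()
        na = np.linalg.norm(a)
        Xc = X - X.mean(axis=0, keepdims=True)
        nx = np.linalg.norm(Xc, axis=0)
        ok = tvalid & (nx > 0) & (na > 0)
        r = np.full(n_t, np.nan)
        r[ok] = (a @ Xc[:, ok]) / (na * nx[ok])
        out[pos[c_name]] = fisher_z(r)
    return out
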