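"""End-to-end orchestration: simulate -> TFR -> feature selection -> RSA ->
Bayesian statistics -> univariate contrast -> report.

A :class:`RunConfig` carries every stage parameter and every seed; its
hash is embedded in the report, and re-running the same config reproduces
the report bit-for-bit.  Two scale profiles share identical code paths:
``desk`` (12 participants, 6 triads, 8 channels, 100 Hz - the default,
sized for routine simulation studies) and ``full`` (36 participants,
24 triads, 62 channels, 500 Hz - the acquisition-scale layout).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import bayes, coherence, rsa, univariate
from .design import AB_SEGMENTS, ExperimentDesign, build_design, enumerate_between_pairs, enumerate_within_pairs
from .simulate import EpochSet, SimulationParams, generate_epochs, recode_behavior
from .tfr import TimeFrequencyCube, db_normalize, edge_validity, morlet_coefficients

logger = logging.getLogger(__name__)

INTEGRATION_WINDOW = (0.0, 5.0)  # Sim C + Sim C in Context on the BC timeline
SEPARATION_WINDOW = (6.0, 8.0)  # Sim B

#: Planted effect amplitudes for desk-profile recovery studies, calibrated
#: once by pilot parameter-recovery runs (real-data similarity magnitudes
#: give no usable amplitude anchor for a 12-participant simulation).
PLANTED_DESK_EFFECTS = {"integration_effect": 0.6, "separation_effect": -0.6}


@dataclass
class RunConfig:
    profile: str = "desk"
    seed: int = 0
    # design
    n_triads: int = 6
    n_repetitions: int = 5
    sample_rate_hz: float = 100.0
    n_channels: int = 8
    n_participants: int = 12
    # simulation
    integration_effect: float = 0.0
    separation_effect: float = 0.0
    # tfr
    freq_lo: float = 3.0
    freq_hi: float = 30.0
    n_cycles: float = 5.0
    time_step_s: float = 0.02
    # coherence
    coh_time_halfwidth_periods: float = 3.0
    coh_freq_halfwidth_bins: int = 1
    coh_decim: int = 4  # coherence grid relative to the TFR grid
    # cluster statistics
    n_permutations: int = 500
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    # rsa
    anchor_segment: str = "joint_context"
    all_segments: bool = False
    # bayes
    bf_threshold: float = 3.0
    min_window_s: float = 0.1
    trace_level: str = "trial"  # "trial" | "participant"
    prior_v: float = 30.0
    prior_alpha: float = 15.0
    prior_beta: float = 15.0
    # behavior
    rt_limit_s: float = 10.0
    apply_recode: bool = True
    ceiling_accuracy: float = 0.9
    # stages
    run_univariate: bool = True

    @classmethod
    def full_profile(cls, seed: int = 0, **overrides) -> "RunConfig":
        return cls(
            profile="full",
            seed=seed,
            n_triads=24,
            n_repetitions=5,
            sample_rate_hz=500.0,
            n_channels=62,
            n_participants=36,
            n_permutations=1000,
            coh_decim=2,
            **overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_run_design(cfg: RunConfig) -> ExperimentDesign:
    return build_design(
        cfg.n_triads, cfg.n_repetitions, cfg.sample_rate_hz, cfg.n_channels, seed=cfg.seed
    )


def simulation_params(cfg: RunConfig) -> SimulationParams:
    return SimulationParams(
        seed=cfg.seed,
        n_participants=cfg.n_participants,
        integration_effect=cfg.integration_effect,
        separation_effect=cfg.separation_effect,
    )


@dataclass
class ParticipantMaps:
    """Per-participant analysis products."""

    within_map: np.ndarray
    between_map: np.ndarray
    ab_mean_db: dict  # movie_id -> TimeFrequencyCube (db, rep-averaged)
    target_db: dict  # (movie_id, rep) -> np.ndarray (ch, f, t) for BC/XY
    bc_lin_mean: np.ndarray
    xy_lin_mean: np.ndarray
    skipped_pairs: int = 0


def analyze_participant(
    epochs: EpochSet, design: ExperimentDesign, cfg: RunConfig, participant: int
) -> ParticipantMaps:
    """TFR, dB cubes, and coherence summary maps for one participant."""
    table = epochs.trial_table
    sel = (table["participant"] == participant).to_numpy()
    data = epochs.data[sel]
    sub = table[sel].reset_index(drop=True)
    sfreq = epochs.sample_rate_hz
    freqs = np.arange(cfg.freq_lo, cfg.freq_hi + 0.5, 1.0)
    decim = int(round(cfg.time_step_s * sfreq))

    coeffs = morlet_coefficients(data, sfreq, freqs, cfg.n_cycles, decim)
    power = coeffs.real.astype(np.float32) ** 2 + coeffs.imag.astype(np.float32) ** 2
    n_t = power.shape[-1]
    times = epochs.t_start_s + np.arange(n_t) * decim / sfreq
    valid = edge_validity(times, freqs, cfg.n_cycles)

    # dB per trial relative to each trial's epoch mean over valid times
    w = valid.astype(np.float32)
    mean = (power * w).sum(axis=-1) / w.sum(axis=-1)
    if not np.all(mean > 0):
        raise ValueError("zero epoch-mean power in a trial")
    db = 10.0 * np.log10(power / mean[..., None])

    def cube(arr) -> TimeFrequencyCube:
        return TimeFrequencyCube(
            data=arr, freqs_hz=freqs, times_s=times, scale="db", valid=valid,
            channel_names=epochs.channel_names,
        )

    ab_mean_db = {}
    for m in design.movies_by_role("AB"):
        rows = np.flatnonzero((sub["movie_id"] == m.movie_id).to_numpy())
        ab_mean_db[m.movie_id] = cube(db[rows].mean(axis=0))

    target_db = {}
    keep = sub["role"].isin(["BC", "XY"]).to_numpy()
    for i in np.flatnonzero(keep):
        target_db[(sub.at[i, "movie_id"], int(sub.at[i, "repetition"]))] = db[i]

    # univariate inputs: linear-scale means over BC / XY trials, rep >= 1
    rep = sub["repetition"].to_numpy()
    bc_rows = np.flatnonzero((sub["role"] == "BC").to_numpy() & (rep >= 1))
    xy_rows = np.flatnonzero((sub["role"] == "XY").to_numpy() & (rep >= 1))
    bc_lin_mean = power[bc_rows].mean(axis=0, dtype=np.float64)
    xy_lin_mean = power[xy_rows].mean(axis=0, dtype=np.float64)

    # coherence bank on the (possibly further decimated) coherence grid
    smoothing = coherence.SmoothingSpec(
        cfg.coh_time_halfwidth_periods, cfg.coh_freq_halfwidth_bins
    )
    cd = cfg.coh_decim
    bank_coeffs = {}
    for i in range(len(sub)):
        if sub.at[i, "role"] == "AB":
            key = (sub.at[i, "movie_id"], int(sub.at[i, "repetition"]))
            bank_coeffs[key] = coeffs[i, ..., ::cd]
    bank = coherence.CoefficientBank(bank_coeffs, freqs, times[::cd], smoothing)
    ab_ids = [m.movie_id for m in design.movies_by_role("AB")]
    within_sets = [enumerate_within_pairs(design, m) for m in ab_ids]
    between_sets = [enumerate_between_pairs(design, m) for m in ab_ids]
    within_map, between_map = coherence.participant_coherence_summary(
        bank, within_sets, between_sets
    )
    return ParticipantMaps(
        within_map=within_map,
        between_map=between_map,
        ab_mean_db=ab_mean_db,
        target_db=target_db,
        bc_lin_mean=bc_lin_mean,
        xy_lin_mean=xy_lin_mean,
    )


def _trial_contrasts(
    maps: ParticipantMaps,
    design: ExperimentDesign,
    template: coherence.FeatureTemplate,
    participant: int,
) -> tuple[list[dict], np.ndarray, np.ndarray]:
    """Per-BC-trial contrast series for one participant.

    Returns (trial metadata rows, vs_xy matrix, vs_noncorresponding_bc
    matrix), one row per corresponding-BC trial with repetition >= 1."""
    anchors = {
        mid: rsa.extract_ab_features(c, template, mid) for mid, c in maps.ab_mean_db.items()
    }
    any_cube = next(iter(maps.ab_mean_db.values()))
    xy_ids = [m.movie_id for m in design.movies_by_role("XY")]
    bc_ids = [m.movie_id for m in design.movies_by_role("BC")]
    rows, vs_xy, vs_nc = [], [], []
    for ab in design.movies_by_role("AB"):
        bc = design.corresponding_bc(ab.movie_id)
        anchor = anchors[ab.movie_id]
        for r in range(1, design.n_repetitions):
            if (bc.movie_id, r) not in maps.target_db:
                continue

            def series(mid):
                return rsa.similarity_timecourse(
                    anchor,
                    TimeFrequencyCube(
                        data=maps.target_db[(mid, r)],
                        freqs_hz=any_cube.freqs_hz,
                        times_s=any_cube.times_s,
                        scale="db",
                        valid=any_cube.valid,
                    ),
                    template,
                    target_movie=mid,
                    target_repetition=r,
                )

            corr = series(bc.movie_id)
            xy_base = [series(x) for x in xy_ids if (x, r) in maps.target_db]
            nc_base = [
                series(b)
                for b in bc_ids
                if b != bc.movie_id and (b, r) in maps.target_db
            ]
            c_xy = rsa.baseline_contrast(corr, xy_base, "vs_xy")
            c_nc = rsa.baseline_contrast(corr, nc_base, "vs_noncorresponding_bc")
            rows.append(
                {
                    "participant": participant,
                    "movie_id": bc.movie_id,
                    "anchor_movie": ab.movie_id,
                    "repetition": r,
                }
            )
            vs_xy.append(c_xy.z)
            vs_nc.append(c_nc.z)
    return rows, np.asarray(vs_xy), np.asarray(vs_nc)


def _classify_windows(windows: list[dict]) -> dict:
    """Sort detected windows into the planted hypothesis slots."""
    sim_in_c = [
        w
        for w in windows
        if w["sign"] == "similarity"
        and w["start_s"] < INTEGRATION_WINDOW[1]
        and w["end_s"] > INTEGRATION_WINDOW[0]
    ]
    dis_in_b = [
        w
        for w in windows
        if w["sign"] == "dissimilarity"
        and w["start_s"] < SEPARATION_WINDOW[1]
        and w["end_s"] > SEPARATION_WINDOW[0]
    ]
    return {
        "n_windows": len(windows),
        "n_similarity_in_sim_c": len(sim_in_c),
        "n_dissimilarity_in_sim_b": len(dis_in_b),
    }


def run_pipeline(config: RunConfig, epochs: EpochSet | None = None) -> dict:
    """Execute the full analysis; returns the JSON-serializable report.

    ``epochs`` may be supplied (e.g. read from a container); otherwise the
    simulation stage generates them from the config."""
    design = build_run_design(config)
    if epochs is None:
        epochs = generate_epochs(design, simulation_params(config))
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": {"n_trials": int(epochs.n_trials)},
    }

    # behavioral recoding filter
    table = epochs.trial_table
    if config.apply_recode and "rt_s" in table.columns:
        table, counts = recode_behavior(table, config.rt_limit_s)
        epochs = replace(epochs, trial_table=table) if hasattr(epochs, "__dataclass_fields__") else epochs
        epochs.trial_table = table
        report["counts"].update(counts)

    # stage: per-participant TFR + coherence
    participants = sorted(table["participant"].unique())
    per_part = []
    for p in participants:
        per_part.append(analyze_participant(epochs, design, config, p))
    within = np.stack([m.within_map for m in per_part])
    between = np.stack([m.between_map for m in per_part])

    # stage: feature selection
    freqs = np.arange(config.freq_lo, config.freq_hi + 0.5, 1.0)
    coh_times = per_part[0].ab_mean_db[
        design.movies_by_role("AB")[0].movie_id
    ].times_s[:: config.coh_decim]
    templates = coherence.select_template(
        within,
        between,
        coh_times,
        freqs,
        design,
        n_permutations=config.n_permutations,
        cluster_alpha=config.cluster_alpha,
        alpha=config.alpha,
        seed=config.seed + 101,
        n_cycles=config.n_cycles,
    )
    report["feature_selection"] = {
        t.segment_name: {
            "n_cells": t.n_cells,
            "clusters": t.cluster_provenance.to_dict()["clusters"],
        }
        for t in templates
    }
    by_segment = {t.segment_name: t for t in templates}
    anchor_template = by_segment[config.anchor_segment]
    if anchor_template.n_cells == 0:
        report["rsa"] = {"error": f"empty template for segment {config.anchor_segment}"}
        report["report_hash"] = _report_hash(report)
        return report
    anchor_template = _template_on_tfr_grid(anchor_template, per_part[0], design, config)

    # stage: RSA trial contrasts
    all_rows, xy_mats, nc_mats = [], [], []
    for p, maps in zip(participants, per_part):
        rows, m_xy, m_nc = _trial_contrasts(maps, design, anchor_template, p)
        all_rows.extend(rows)
        xy_mats.append(m_xy)
        nc_mats.append(m_nc)
    contrast_meta = pd.DataFrame(all_rows)
    contrast_xy = np.concatenate(xy_mats)
    contrast_nc = np.concatenate(nc_mats)
    tfr_times = per_part[0].ab_mean_db[design.movies_by_role("AB")[0].movie_id].times_s

    # stage: Bayesian evidence accumulation
    prior = bayes.NIGPrior(0.0, config.prior_v, config.prior_alpha, config.prior_beta)
    report["rsa"] = {}
    traces = {}
    for mode, mat in (("vs_xy", contrast_xy), ("vs_noncorresponding_bc", contrast_nc)):
        if config.trace_level == "participant":
            obs = (
                pd.DataFrame(mat)
                .groupby(contrast_meta["participant"].to_numpy())
                .mean()
                .to_numpy()
            )
        else:
            obs = mat
        trace = bayes.evidence_trace(obs, tfr_times, prior)
        windows = bayes.detect_windows(trace, config.bf_threshold, config.min_window_s)
        traces[mode] = trace
        report["rsa"][mode] = {
            "windows": windows,
            "summary": _classify_windows(windows),
            "n_observations_per_timepoint": int(np.max(trace.n_obs)),
        }

    # supplementary parity: windows for the other anchor segments
    if config.all_segments:
        report["rsa_supplementary"] = {}
        for seg, tmpl in by_segment.items():
            if seg == config.anchor_segment or tmpl.n_cells == 0:
                continue
            tmpl_full = _template_on_tfr_grid(tmpl, per_part[0], design, config)
            rows_s, xy_s = [], []
            for p, maps in zip(participants, per_part):
                _, m_xy, _ = _trial_contrasts(maps, design, tmpl_full, p)
                xy_s.append(m_xy)
            trace_s = bayes.evidence_trace(np.concatenate(xy_s), tfr_times, prior)
            report["rsa_supplementary"][seg] = {
                "windows": bayes.detect_windows(
                    trace_s, config.bf_threshold, config.min_window_s
                )
            }

    # stage: trial-level outcome regressions within detected windows
    report["regressions"] = _outcome_regressions(
        config, contrast_meta, contrast_xy, tfr_times, table,
        report["rsa"]["vs_xy"]["windows"],
    )

    # stage: univariate BC vs XY contrast
    if config.run_univariate:
        report["univariate"] = _univariate_stage(
            config, design, per_part, freqs, tfr_times, contrast_meta, contrast_xy, table
        )

    report["report_hash"] = _report_hash(report)
    return report


def _template_on_tfr_grid(template, maps: ParticipantMaps, design, cfg: RunConfig):
    """Coherence runs on a decimated grid; expand the template's time
    support back to the TFR grid by repeating columns."""
    if cfg.coh_decim == 1:
        return template
    any_cube = next(iter(maps.ab_mean_db.values()))
    lo, hi = design.segment_window(template.segment_name)
    cols = any_cube.time_indices((lo, hi))
    mask = np.zeros((*template.mask.shape[:2], len(cols)), bool)
    src_times = template.times_s
    dst_times = any_cube.times_s[cols]
    idx = np.clip(np.searchsorted(src_times, dst_times, side="right") - 1, 0, len(src_times) - 1)
    mask[:] = template.mask[..., idx]
    return coherence.FeatureTemplate(
        segment_name=template.segment_name,
        mask=mask,
        freqs_hz=template.freqs_hz,
        times_s=dst_times,
        cluster_provenance=template.cluster_provenance,
    )


def _outcome_regressions(cfg, meta, contrast_xy, times, trial_table, windows):
    """Window-mean similarity per trial regressed on memory outcomes."""
    out = []
    bc = trial_table[trial_table["role"] == "BC"]
    merged = meta.merge(
        bc[["participant", "movie_id", "repetition", "ac_correct", "source_correct"]],
        on=["participant", "movie_id", "repetition"],
        how="left",
    )
    for w in windows:
        sel = (times >= w["start_s"] - 1e-9) & (times < w["end_s"] - 1e-9)
        win_sim = np.nanmean(contrast_xy[:, sel], axis=1)
        df = merged.assign(window_similarity=win_sim).dropna(
            subset=["ac_correct", "source_correct"]
        )
        entry = {"window": {k: w[k] for k in ("start_s", "end_s", "sign")}}
        for outcome, controls in (
            ("ac_correct", ["repetition"]),
            ("source_correct", ["repetition", "ac_correct"]),
        ):
            dff, excluded = bayes.ceiling_filter(df, outcome, cfg.ceiling_accuracy)
            rec = {"excluded_participants": excluded}
            try:
                res = bayes.mvnig_regression(
                    dff["window_similarity"].to_numpy(),
                    dff[[outcome] + controls],
                    lambda_scale=cfg.prior_v,
                    alpha=cfg.prior_alpha,
                    beta=cfg.prior_beta,
                )
                rec.update(res.to_dict())
            except ValueError as exc:
                rec["error"] = str(exc)
            entry[outcome] = rec
        out.append(entry)
    return out


def _univariate_stage(cfg, design, per_part, freqs, times, meta, contrast_xy, trial_table):
    contrast = univariate.power_contrast(
        np.stack([m.bc_lin_mean for m in per_part]),
        np.stack([m.xy_lin_mean for m in per_part]),
        freqs,
        times,
    )
    seg_results = univariate.segmentwise_tests(
        contrast,
        design,
        n_permutations=cfg.n_permutations,
        cluster_alpha=cfg.cluster_alpha,
        alpha=cfg.alpha,
        seed=cfg.seed + 202,
        n_cycles=cfg.n_cycles,
    )
    report = {seg: res.to_dict() for seg, res in seg_results.items()}
    # link the largest significant cluster (if any) to the mean similarity
    links = []
    participants = sorted(trial_table["participant"].unique())
    for seg, res in seg_results.items():
        sig = res.significant()
        if not sig:
            continue
        mask = res.significant_mask()
        lo, hi = design.segment_window(seg)
        cols = np.flatnonzero((times >= lo - 1e-9) & (times < hi - 1e-9))
        # per-trial cluster-mean dB power of corresponding BC trials
        power_vals = []
        for p, maps in zip(participants, per_part):
            rows = meta[meta["participant"] == p]
            for _, r in rows.iterrows():
                cube = maps.target_db[(r["movie_id"], int(r["repetition"]))]
                power_vals.append(cube[..., cols][mask].mean())
        sel = (times >= lo - 1e-9) & (times < hi - 1e-9)
        win_sim = np.nanmean(contrast_xy[:, sel], axis=1)
        try:
            link = univariate.power_similarity_link(np.asarray(power_vals), win_sim)
            links.append({"segment": seg, **link.to_dict()})
        except ValueError as exc:
            links.append({"segment": seg, "error": str(exc)})
    return {"segments": report, "links": links}


def _report_hash(report: dict) -> str:
    payload = json.dumps(report, sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True, default=_json_default)
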