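"""Synthetic EEG generator for the overlapping-events paradigm.

Each movie carries a repetition-stable oscillatory signature: band-limited
sinusoidal components with participant- and movie-specific per-channel
amplitudes and phases, switched on segment by segment and embedded in 1/f
("pink") background noise.  Stability of the phase pattern across
repetitions (up to a small temporal jitter) is what makes within-movie
wavelet coherence exceed between-movie coherence inside the signature
bands.

Two couplings can be planted between an AB movie and its corresponding BC
movie:

* integration - during the BC movie's first-Sim segments ([0, 2) s and
  [2, 5) s, when the novel Sim C is on screen), a component whose
  channel x frequency amplitude profile copies the AB movie's
  joint-interaction signature is added, so the BC power pattern correlates
  positively with the AB feature vector;
* separation - during the shared-Sim segment ([6, 8) s, Sim B on screen), a
  complementary profile (anti-correlated with the AB signature in
  channel x frequency space) is added, pushing the pattern correlation
  negative.

XY movies share nothing systematic with any AB movie.  Per-trial coupling
strengths are drawn around the planted effect and stored in the trial
table; behavioral outcomes are generated from them through a logistic
link, so the downstream trial-level regressions have a recoverable ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SEGMENT_TABLE, ExperimentDesign

CONTENT_SEGMENTS = ("sim_first", "sim_first_context", "sim_second", "joint_context")
INTEGRATION_SEGMENTS = ("sim_first", "sim_first_context")
SEPARATION_SEGMENT = "sim_second"


@dataclass
class BehaviorLink:
    """Logistic link from planted trial couplings to memory outcomes."""

    beta_ac_on_similarity: float = 1.2
    beta_source_on_dissimilarity: float = 1.2
    intercept_ac: float = 0.8
    intercept_source: float = 0.4
    # nuisance structure exercised by the behavioral recoding filter
    slow_rt_rate: float = 0.04  # correct responses slower than 10 s
    guess_rate: float = 0.10  # confidence = 1 ("guessing") responses


@dataclass
class SimulationParams:
    """Generator settings.  ``integration_effect``/``separation_effect``
    are amplitude scales of the planted shared / complementary components
    (calibrated so the pipeline's Fisher-z contrasts are recoverable at the
    default 12-participant desk profile); both zero yields a fully null
    dataset.  Identical seed and parameters give bit-identical output."""

    seed: int = 0
    n_participants: int = 12
    pink_exponent: float = 1.0
    noise_sd: float = 1.0
    signature_bands: tuple[tuple[float, float, float], ...] = (
        (4.0, 7.0, 0.9),
        (10.0, 14.0, 0.9),
        (18.0, 24.0, 0.7),
    )
    repetition_jitter_s: float = 0.03
    integration_effect: float = 0.0
    separation_effect: float = 0.0
    trial_strength_sd: float = 0.35
    behavior_link: BehaviorLink = field(default_factory=BehaviorLink)

    def __post_init__(self):
        if self.integration_effect < 0:
            raise ValueError("integration_effect must be >= 0")
        if self.separation_effect > 0:
            raise ValueError("separation_effect must be <= 0 (dissimilarity)")


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial metadata."""

    data: np.ndarray
    sample_rate_hz: float
    t_start_s: float
    channel_names: list[str]
    trial_table: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_axis(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.data.shape[-1]) / self.sample_rate_hz

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sample_rate_hz=self.sample_rate_hz,
            t_start_s=self.t_start_s,
            channel_names=self.channel_names,
            trial_table=self.trial_table.iloc[mask].reset_index(drop=True),
        )


def _pink_noise(rng, shape, n_samples, sfreq, exponent, sd):
    """1/f^exponent noise via spectral shaping, unit-free sd scaling."""
    n_f = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = np.zeros(n_f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((*shape, n_f)) + 1j * rng.standard_normal((*shape, n_f))) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return (sd * x).astype(np.float32)


def _segment_window(times, lo, hi, sfreq, ramp_s=0.1):
    """Smooth on/off gate for a segment (raised-cosine ramps)."""
    w = np.zeros_like(times)
    inside = (times >= lo) & (times < hi)
    w[inside] = 1.0
    n_ramp = max(1, int(round(ramp_s * sfreq)))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp)))
    i0 = np.searchsorted(times, lo)
    i1 = np.searchsorted(times, hi)
    w[i0 : i0 + n_ramp] = np.minimum(w[i0 : i0 + n_ramp], ramp[: max(0, i1 - i0)])
    w[max(i0, i1 - n_ramp) : i1] = np.minimum(
        w[max(i0, i1 - n_ramp) : i1], ramp[::-1][-(i1 - max(i0, i1 - n_ramp)) :]
    )
    return w


def _component_freqs(bands):
    """Integer component frequencies and their band amplitudes."""
    freqs, amps = [], []
    for lo, hi, amp in bands:
        fs = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
        freqs.extend(fs.tolist())
        amps.extend([amp] * len(fs))
    return np.asarray(freqs, float), np.asarray(amps, float)


def _complement_profile(a: np.ndarray) -> np.ndarray:
    """Nonnegative amplitude profile anti-correlated with ``a`` in
    (channel, frequency) space: reflect around the mean and clip, then
    rescale to the original root-mean-square."""
    c = np.clip(2.0 * a.mean() - a, 0.0, None)
    rms = np.sqrt((c**2).mean())
    if rms > 0:
        c *= np.sqrt((a**2).mean()) / rms
    return c


def generate_epochs(design: ExperimentDesign, params: SimulationParams) -> EpochSet:
    """Simulate all participants' encoding epochs for ``design``.

    Trial order: participant-major, then movie (design order), then
    repetition - deterministic, so a fixed seed reproduces the array
    bit-for-bit.
    """
    sfreq = design.sample_rate_hz
    for _, lo, hi in design.segment_table:
        for bound in (lo, hi):
            if abs(bound * sfreq - round(bound * sfreq)) > 1e-9:
                raise ValueError(
                    f"segment boundary {bound}s is not an integer sample at {sfreq} Hz"
                )
    rng = np.random.default_rng(params.seed)
    n_ch = len(design.channel_names)
    times = design.time_axis()
    n_samp = design.n_samples
    comp_f, comp_amp = _component_freqs(params.signature_bands)
    n_comp = len(comp_f)
    if n_comp == 0:
        raise ValueError("signature_bands contain no integer component frequency")

    # per-segment gates and complex carrier basis exp(i 2 pi f t)
    gates = {
        name: _segment_window(times, lo, hi, sfreq)
        for name, lo, hi in design.segment_table
        if name in CONTENT_SEGMENTS
    }
    basis = np.exp(2j * np.pi * comp_f[:, None] * times[None, :])  # (comp, t)

    ab_movies = design.movies_by_role("AB")
    triad_to_ab = {m.triad_id: m.movie_id for m in ab_movies}
    reps = design.n_repetitions

    rows = []
    chunks = []
    for p in range(params.n_participants):
        # movie- and participant-specific signature amplitudes and phases
        amp = {}
        phase = {}
        for m in design.movies:
            for seg in CONTENT_SEGMENTS:
                amp[(m.movie_id, seg)] = comp_amp * rng.rayleigh(
                    scale=1.0, size=(n_ch, n_comp)
                ) / np.sqrt(np.pi / 2.0)
                phase[(m.movie_id, seg)] = rng.uniform(0, 2 * np.pi, (n_ch, n_comp))

        n_trials_p = len(design.movies) * reps
        noise = _pink_noise(
            rng, (n_trials_p, n_ch), n_samp, sfreq, params.pink_exponent, params.noise_sd
        )
        sig = np.zeros((n_trials_p, n_ch, n_samp), np.float32)
        i = 0
        for m in design.movies:
            # deterministic per-movie waveform: sum of gated components
            wav = np.zeros((n_ch, n_samp))
            for seg in CONTENT_SEGMENTS:
                a = amp[(m.movie_id, seg)]
                ph = phase[(m.movie_id, seg)]
                wav += ((a * np.exp(1j * ph)) @ basis).real * gates[seg][None, :]
            coupled = m.role == "BC" and m.triad_id in triad_to_ab
            if coupled:
                ab_id = triad_to_ab[m.triad_id]
                prof_ab = amp[(ab_id, "joint_context")]  # (ch, comp)
                prof_sep = _complement_profile(prof_ab)
            for r in range(reps):
                shift = int(round(rng.normal(0.0, params.repetition_jitter_s) * sfreq))
                trial = np.roll(wav, shift, axis=-1)
                s_int = d_sep = 0.0
                if coupled and r >= 1:
                    s_int = params.integration_effect * max(
                        0.0, 1.0 + params.trial_strength_sd * rng.standard_normal()
                    )
                    d_sep = -params.separation_effect * max(
                        0.0, 1.0 + params.trial_strength_sd * rng.standard_normal()
                    )
                    if s_int > 0:
                        ph_t = rng.uniform(0, 2 * np.pi, (n_ch, n_comp))
                        shared = ((prof_ab * np.exp(1j * ph_t)) @ basis).real
                        for seg in INTEGRATION_SEGMENTS:
                            trial = trial + s_int * shared * gates[seg][None, :]
                    if d_sep > 0:
                        ph_t = rng.uniform(0, 2 * np.pi, (n_ch, n_comp))
                        comp = ((prof_sep * np.exp(1j * ph_t)) @ basis).real
                        trial = trial + d_sep * comp * gates[SEPARATION_SEGMENT][None, :]
                sig[i] = trial
                rows.append(
                    {
                        "participant": p,
                        "movie_id": m.movie_id,
                        "role": m.role,
                        "triad_id": m.triad_id,
                        "repetition": r,
                        "planted_similarity": s_int,
                        "planted_dissimilarity": d_sep,
                    }
                )
                i += 1
        chunks.append(noise + sig)

    table = pd.DataFrame(rows)
    epochs = EpochSet(
        data=np.concatenate(chunks, axis=0),
        sample_rate_hz=sfreq,
        t_start_s=design.epoch_window[0],
        channel_names=list(design.channel_names),
        trial_table=table,
    )
    epochs.trial_table = generate_outcomes(
        epochs.trial_table, params.behavior_link, seed=params.seed + 1
    )
    return epochs


def generate_outcomes(
    trial_table: pd.DataFrame, link: BehaviorLink, seed: int
) -> pd.DataFrame:
    """Attach behavioral outcomes generated from the planted couplings.

    ``ac_correct ~ Bernoulli(logistic(b0 + b_ac * z(similarity)))`` and
    ``source_correct ~ Bernoulli(logistic(c0 + c_src * z(dissimilarity)))``
    on BC trials (z-scoring within coupled trials); AB/XY trials get base
    rates.  Confidence (1 guessing / 2 maybe / 3 sure) and response time
    follow monotone links to correctness, with a planted fraction of slow
    (> 10 s) and guessing responses so the recoding filter has work to do.
    """
    required = {"planted_similarity", "planted_dissimilarity", "role"}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    rng = np.random.default_rng(seed)
    t = trial_table.copy()
    n = len(t)

    def zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    bc = (t["role"] == "BC").to_numpy()
    sim = t["planted_similarity"].to_numpy(float)
    dis = t["planted_dissimilarity"].to_numpy(float)
    eta_ac = np.full(n, link.intercept_ac)
    eta_src = np.full(n, link.intercept_source)
    if bc.any():
        eta_ac[bc] += link.beta_ac_on_similarity * zscore(sim[bc])
        eta_src[bc] += link.beta_source_on_dissimilarity * zscore(dis[bc])
    p_ac = 1.0 / (1.0 + np.exp(-eta_ac))
    p_src = 1.0 / (1.0 + np.exp(-eta_src))
    t["ac_correct"] = (rng.uniform(size=n) < p_ac).astype(int)
    t["source_correct"] = (rng.uniform(size=n) < p_src).astype(int)

    # confidence: correct trials tend to higher confidence; a guess_rate
    # fraction responds "guessing" regardless
    conf_latent = eta_ac + rng.normal(0, 1.0, n)
    conf = np.where(conf_latent > 1.0, 3, np.where(conf_latent > 0.0, 2, 1))
    guess = rng.uniform(size=n) < link.guess_rate
    conf = np.where(guess, 1, conf)
    t["confidence"] = conf.astype(int)

    rt = np.exp(rng.normal(0.7, 0.45, n))  # ~ 2 s median
    slow = rng.uniform(size=n) < link.slow_rt_rate
    rt = np.where(slow, 10.5 + rng.exponential(2.0, n), rt)
    t["rt_s"] = rt
    return t


def recode_behavior(
    trial_table: pd.DataFrame, rt_limit_s: float = 10.0, guessing_confidence: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Recode correct responses as incorrect when the response was slower
    than ``rt_limit_s`` or rated at the guessing confidence level, so that
    answers plausibly produced by reasoning rather than memory do not count
    as remembered.  Returns the recoded table and a count record."""
    t = trial_table.copy()
    suspect = (t["rt_s"] > rt_limit_s) | (t["confidence"] == guessing_confidence)
    counts = {}
    for col in ("ac_correct", "source_correct"):
        flip = suspect & (t[col] == 1)
        counts[f"recoded_{col}"] = int(flip.sum())
        t.loc[flip, col] = 0
    return t, counts
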