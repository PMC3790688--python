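"""Synthetic EEG with the paradigm's ERP structure.

Every display onset (S1 at 0 ms, S2 at 1200 ms within a trial) evokes
three stereotyped components — P1, N1, and a sustained late positivity —
modelled as Gaussian-windowed half-period cosines projected to the scalp
with Gaussian topographies (posterior for P1/N1, vertex-centred for the
late positivity).  The two predictive effects are injected only on
rivalry trials whose consciousness later changed: the S1 N1 is deepened
over parieto-occipital channels and the S1 late positivity is reduced
over central channels.  Fusion responses carry no outcome-dependent
modulation, which makes the fusion condition a built-in negative
control.  Setting every effect amplitude to zero yields a null dataset
for Type-I calibration.

Background noise is 1/f-shaped plus white sensor noise; blinks are
frontally dominant transients large enough to trip the EOG rejection
bound, added separately by :func:`inject_blinks` so ground truth is
known.

Component amplitudes are free parameters of the generator (the study
this emulates reports component morphology only graphically); defaults
are ordinary visual-ERP magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    BehaviorParams,
    S2_ONSET_MS,
    TRIAL_MS,
    make_design,
    simulate_behavior,
)
from .montage import Montage, default_montage
from .preprocessing import EpochSet, EpochSpec
from .recording import RawRecording, EVENT_LABELS, s1_event_label
from .design import erp_condition


@dataclass
class EffectParams:
    """ERP component amplitudes and the outcome-dependent effects (µV)."""

    # base components, evoked by every display onset
    p1_latency_ms: float = 100.0
    p1_width_ms: float = 20.0
    p1_amplitude_uV: float = 4.0
    n1_latency_ms: float = 180.0
    n1_width_ms: float = 25.0
    n1_amplitude_uV: float = -5.0
    lp_window_ms: tuple[float, float] = (300.0, 800.0)
    lp_peak_ms: float = 400.0
    lp_amplitude_uV: float = 3.0
    # predictive (outcome-dependent) effects on rivalry-change trials
    n1_extra_negativity_uV: float = 2.0
    lp_reduction_uV: float = 1.5
    # analogous second-display effects (S2 onset), rivalry-change trials
    s2_n1_extra_negativity_uV: float = 0.0
    s2_lp_reduction_uV: float = 1.0
    # scalp-distance scale (radians of arc) of the Gaussian topographies
    component_topography_width: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "p1_latency_ms",
            "n1_latency_ms",
            "lp_peak_ms",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def null(self) -> "EffectParams":
        """Copy with every outcome-dependent effect set to zero."""
        return replace(
            self,
            n1_extra_negativity_uV=0.0,
            lp_reduction_uV=0.0,
            s2_n1_extra_negativity_uV=0.0,
            s2_lp_reduction_uV=0.0,
        )


@dataclass
class NoiseParams:
    """Background and artifact noise levels."""

    background_spectrum_exponent: float = 1.0  # 1/f slope
    background_rms_uV: float = 8.0
    sensor_white_rms_uV: float = 2.0
    blink_rate_hz: float = 0.1
    blink_amplitude_uV: float = 150.0  # comfortably above the 60 µV bound
    blink_duration_ms: float = 400.0

    def __post_init__(self) -> None:
        vals = [
            self.background_spectrum_exponent,
            self.background_rms_uV,
            self.sensor_white_rms_uV,
            self.blink_rate_hz,
            self.blink_amplitude_uV,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("noise parameters must be non-negative")

    def silent(self) -> "NoiseParams":
        return replace(
            self, background_rms_uV=0.0, sensor_white_rms_uV=0.0, blink_rate_hz=0.0
        )


# ---------------------------------------------------------------------------
# component machinery


def component_wave(
    t_ms: np.ndarray,
    latency_ms: float,
    width_ms: float,
    rise_width_ms: float | None = None,
) -> np.ndarray:
    """Gaussian-windowed half-period cosine, peak 1 at the latency.

    Compact support |t - latency| <= 2 width; an asymmetric (rise/fall)
    pair of widths builds the sustained late positivity.
    """
    t = np.asarray(t_ms, dtype=float) - latency_ms
    w = np.where(t < 0, rise_width_ms if rise_width_ms is not None else width_ms,
                 width_ms).astype(float)
    u = t / np.maximum(w, 1e-12)
    wave = np.cos(np.pi * u / 4.0) * np.exp(-0.5 * u * u)
    wave[np.abs(u) > 2.0] = 0.0
    return wave


def _topography(montage: Montage, center_channels: list[str], width: float):
    """Gaussian falloff in geodesic distance from a scalp centre."""
    pts = montage.positions[montage.indices(center_channels)]
    center = pts.mean(axis=0)
    center /= np.linalg.norm(center)
    d = montage.geodesic_to_point(center)
    return np.exp(-0.5 * (d / width) ** 2)


def component_templates(
    effects: EffectParams, montage: Montage
) -> list[dict]:
    """The component set: name, waveform parameters, channel weights."""
    tw = effects.component_topography_width
    posterior = _topography(montage, ["POz", "Oz"], tw)
    vertex = _topography(montage, ["Cz"], tw)
    lp_rise = (effects.lp_peak_ms - effects.lp_window_ms[0]) / 2.0
    lp_fall = (effects.lp_window_ms[1] - effects.lp_peak_ms) / 2.0
    return [
        dict(
            name="P1",
            latency=effects.p1_latency_ms,
            width=effects.p1_width_ms,
            rise=None,
            amplitude=effects.p1_amplitude_uV,
            weights=posterior,
        ),
        dict(
            name="N1",
            latency=effects.n1_latency_ms,
            width=effects.n1_width_ms,
            rise=None,
            amplitude=effects.n1_amplitude_uV,
            weights=posterior,
        ),
        dict(
            name="LP",
            latency=effects.lp_peak_ms,
            width=lp_fall,
            rise=lp_rise,
            amplitude=effects.lp_amplitude_uV,
            weights=vertex,
        ),
    ]


def _effect_templates(effects: EffectParams, montage: Montage, display: str):
    """Outcome-dependent additions for rivalry-change trials."""
    tw = effects.component_topography_width
    posterior = _topography(montage, ["POz", "Oz"], tw)
    vertex = _topography(montage, ["Cz"], tw)
    lp_rise = (effects.lp_peak_ms - effects.lp_window_ms[0]) / 2.0
    lp_fall = (effects.lp_window_ms[1] - effects.lp_peak_ms) / 2.0
    if display == "S1":
        n1_amp, lp_amp = effects.n1_extra_negativity_uV, effects.lp_reduction_uV
    else:
        n1_amp = effects.s2_n1_extra_negativity_uV
        lp_amp = effects.s2_lp_reduction_uV
    out = []
    if n1_amp:
        out.append(
            dict(
                name=f"{display}_N1_effect",
                latency=effects.n1_latency_ms,
                width=effects.n1_width_ms,
                rise=None,
                amplitude=-abs(n1_amp),  # deepen the negativity
                weights=posterior,
            )
        )
    if lp_amp:
        out.append(
            dict(
                name=f"{display}_LP_effect",
                latency=effects.lp_peak_ms,
                width=lp_fall,
                rise=lp_rise,
                amplitude=-abs(lp_amp),  # reduce the positivity
                weights=vertex,
            )
        )
    return out


def evoked_response(
    times_ms: np.ndarray,
    effects: EffectParams,
    montage: Montage,
    erp_cond: str | None,
    display: str = "S1",
) -> np.ndarray:
    """Noise-free channels x samples response to one display onset.

    ``erp_cond`` is the averaging condition of the trial (or None for
    excluded trials); only ``rivalry_changed`` receives the predictive
    effects.
    """
    resp = np.zeros((len(montage), len(times_ms)))
    comps = component_templates(effects, montage)
    if erp_cond == "rivalry_changed":
        comps = comps + _effect_templates(effects, montage, display)
    for c in comps:
        wave = component_wave(times_ms, c["latency"], c["width"], c["rise"])
        resp += c["amplitude"] * np.outer(c["weights"], wave)
    return resp


def effect_difference_wave(
    times_ms: np.ndarray,
    effects: EffectParams,
    montage: Montage,
    display: str = "S1",
) -> np.ndarray:
    """The injected change-minus-same difference (channels x samples)."""
    resp = np.zeros((len(montage), len(times_ms)))
    for c in _effect_templates(effects, montage, display):
        wave = component_wave(times_ms, c["latency"], c["width"], c["rise"])
        resp += c["amplitude"] * np.outer(c["weights"], wave)
    return resp


# ---------------------------------------------------------------------------
# continuous recording


def _pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float,
    rms: float,
) -> np.ndarray:
    """1/f^exponent background, per-channel independent, scaled to rms."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    if exponent == 0:
        return rms * white
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    pink *= rms / np.sqrt(np.mean(pink**2))
    return pink


def simulate_recording(
    trials: pd.DataFrame,
    effects: EffectParams | None = None,
    noise: NoiseParams | None = None,
    montage: Montage | None = None,
    seed: int | np.random.Generator = 0,
    fs: float = 500.0,
    start_pad_ms: float = 4000.0,
    end_pad_ms: float = 4000.0,
) -> RawRecording:
    """Continuous synthetic EEG for a behaviorally-labelled trial table.

    Event markers are written for every S1 onset (condition/outcome
    coded), S2 onset, and mask onset.  Padding at both ends leaves room
    for the FIR filter's edge region and the pre-stimulus window.
    """
    effects = effects or EffectParams()
    noise = noise or NoiseParams()
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    if trials["outcome"].isna().any():
        raise ValueError("trials must carry behavioral outcomes")

    t_end = trials["s1_onset_ms"].max() + TRIAL_MS + end_pad_ms
    n_samples = int(round((t_end + start_pad_ms) / 1000.0 * fs)) + 1
    data = _pink_noise(
        rng,
        len(montage),
        n_samples,
        fs,
        noise.background_spectrum_exponent,
        noise.background_rms_uV,
    )
    if noise.sensor_white_rms_uV:
        data += noise.sensor_white_rms_uV * rng.standard_normal(data.shape)

    # pre-computed response templates on a local time base
    resp_len = int(round(1200.0 / 1000.0 * fs)) + 1  # covers support of S1/S2 comps
    local_t = np.arange(resp_len) / fs * 1000.0
    conds = erp_condition(trials)
    cache: dict[tuple, np.ndarray] = {}

    events = []
    for i, row in trials.iterrows():
        cond = conds.iloc[i] if conds.iloc[i] is not pd.NA else None
        s1_sample = int(round((row["s1_onset_ms"] + start_pad_ms) / 1000.0 * fs))
        s2_sample = s1_sample + int(round(S2_ONSET_MS / 1000.0 * fs))
        mask_sample = s1_sample + int(round((S2_ONSET_MS + 1000.0) / 1000.0 * fs))
        for display, sample in (("S1", s1_sample), ("S2", s2_sample)):
            key = (display, cond)
            if key not in cache:
                cache[key] = evoked_response(local_t, effects, montage, cond, display)
            resp = cache[key]
            data[:, sample : sample + resp_len] += resp
        label = s1_event_label(
            row["condition"], row["outcome"], row["response_correct"]
        )
        events.append((s1_sample, EVENT_LABELS[label], label))
        events.append((s2_sample, EVENT_LABELS["S2_onset"], "S2_onset"))
        events.append((mask_sample, EVENT_LABELS["mask_onset"], "mask_onset"))

    events.sort(key=lambda e: e[0])
    return RawRecording(data, fs, montage, events)


def inject_blinks(
    raw: RawRecording,
    noise: NoiseParams | None = None,
    seed: int | np.random.Generator = 0,
    times_s: list[float] | None = None,
) -> tuple[RawRecording, list[int]]:
    """Add frontally dominant blink transients at Poisson (or given) times.

    Returns the contaminated record and the blink peak samples, for
    ground-truth checks of artifact rejection.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    out = raw.copy()
    if times_s is None:
        if noise.blink_rate_hz == 0:
            return out, []
        n = rng.poisson(noise.blink_rate_hz * raw.duration_s)
        times_s = np.sort(rng.uniform(0, raw.duration_s, size=n)).tolist()

    half = int(round(noise.blink_duration_ms / 2000.0 * raw.fs))
    t = np.arange(-half, half + 1)
    template = 0.5 * (1 + np.cos(np.pi * t / max(half, 1)))  # raised cosine
    # spatial profile: unit at the lower-vertical EOG site, decaying back
    front_pole = np.array([0.3, 0.88, -0.36])
    d = raw.montage.geodesic_to_point(front_pole)
    weights = np.exp(-((d / 0.55) ** 2))

    peaks = []
    for ts in times_s:
        peak = int(round(ts * raw.fs))
        lo, hi = peak - half, peak + half + 1
        tlo, thi = max(lo, 0), min(hi, raw.n_samples)
        if thi <= tlo:
            continue
        seg = template[tlo - lo : thi - lo]
        out.data[:, tlo:thi] += noise.blink_amplitude_uV * np.outer(weights, seg)
        peaks.append(peak)
    return out, peaks


# ---------------------------------------------------------------------------
# fast epoch-level path for calibration and power studies


def simulate_epochs(
    trials: pd.DataFrame,
    effects: EffectParams | None = None,
    montage: Montage | None = None,
    noise_sd_uV: float = 5.0,
    seed: int | np.random.Generator = 0,
    espec: EpochSpec | None = None,
    fs: float = 500.0,
) -> EpochSet:
    """Epochs sampled directly on the epoch grid (no continuous record).

    Each trial is its condition's noise-free S1 response plus white
    noise of ``noise_sd_uV`` per sample.  This is the path used for
    repeated calibration/power simulations, where the continuous
    synthesis and FIR filtering would only add run time, not validity:
    both paths share :func:`evoked_response` for the signal content.
    """
    effects = effects or EffectParams()
    montage = montage or default_montage()
    espec = espec or EpochSpec()
    rng = np.random.default_rng(seed)

    i0 = int(round(espec.tmin_ms / 1000.0 * fs))
    i1 = int(round(espec.tmax_ms / 1000.0 * fs))
    times_ms = np.arange(i0, i1 + 1) / fs * 1000.0

    conds = erp_condition(trials)
    cache: dict = {}
    n_tr = len(trials)
    data = noise_sd_uV * rng.standard_normal((n_tr, len(montage), len(times_ms)))
    for i in range(n_tr):
        cond = conds.iloc[i] if conds.iloc[i] is not pd.NA else None
        if cond not in cache:
            resp = evoked_response(
                np.clip(times_ms, 0, None), effects, montage, cond, "S1"
            )
            resp[:, times_ms < 0] = 0.0
            cache[cond] = resp
        data[i] += cache[cond]

    metadata = trials.reset_index(drop=True).copy()
    metadata["erp_condition"] = erp_condition(metadata)
    return EpochSet(
        data,
        times_ms,
        list(montage.names),
        list(montage.roles),
        fs,
        metadata,
    )


def simulate_study_epochs(
    n_participants: int = 11,
    n_blocks: int = 4,
    trials_per_block: int = 40,
    effects: EffectParams | None = None,
    behavior: BehaviorParams | None = None,
    montage: Montage | None = None,
    noise_sd_uV: float = 5.0,
    seed: int = 0,
    espec: EpochSpec | None = None,
) -> dict[int, EpochSet]:
    """Per-participant epoch sets for a whole simulated group.

    A single master seed spawns independent per-participant streams;
    each participant's outcome probabilities are drawn from the
    behavioral hyperprior.
    """
    behavior = behavior or BehaviorParams()
    montage = montage or default_montage()
    master = np.random.SeedSequence(seed)
    out = {}
    for p, child in enumerate(master.spawn(n_participants)):
        rng = np.random.default_rng(child)
        design = make_design(
            n_blocks,
            trials_per_block,
            seed=rng,
            first_condition="rivalry" if p % 2 == 0 else "fusion",
        )
        pb = behavior.draw_participant(rng)
        tr = simulate_behavior(design, pb, seed=rng)
        out[p] = simulate_epochs(
            tr, effects, montage, noise_sd_uV, seed=rng, espec=espec
        )
    return out
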