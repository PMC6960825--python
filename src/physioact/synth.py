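"""Synthetic multi-modal biosignal cohorts with activity-dependent physiology.

Generates continuous per-subject recordings of four channels — ECG (250 Hz),
thoracic electrical bioimpedance (TEB, 100 Hz) and electrodermal activity at
two sites (EDA hand/arm, 100 Hz) — over a four-activity protocol
(neutral, emotional, mental, physical).  Each activity carries its own
cardiac, respiratory and electrodermal profile, so downstream feature
extraction and classification have genuine class structure to recover.

Ground-truth event lists (beat times, breath times, SCR onsets) are stored
alongside the waveforms so detector accuracy can be tested against the
generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ECG_FS = 250.0
AUX_FS = 100.0

#: Protocol order of the four activities within a session.
ACTIVITIES = ("neutral", "emotional", "mental", "physical")


@dataclass(frozen=True)
class ActivityProfile:
    """Physiological parameters that characterise one activity.

    hr_mean/hr_sd are in beats/min, resp_rate in breaths/min, eda_tonic in
    microsiemens, scr_rate in events/min.  motion_noise_sd is broadband
    additive noise in raw signal units.
    """

    activity: str
    hr_mean: float
    hr_sd: float
    resp_rate: float
    eda_tonic: float
    scr_rate: float
    motion_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")
        if self.resp_rate <= 0:
            raise ValueError("resp_rate must be positive")
        if self.scr_rate < 0:
            raise ValueError("scr_rate must be nonnegative")
        if self.hr_sd < 0 or self.motion_noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


#: Default per-activity profiles.  These are generator choices, not values
#: taken from any study: emotional and mental are deliberately close so a
#: classifier confuses them more than it confuses physical with neutral.
DEFAULT_PROFILES: dict[str, ActivityProfile] = {
    "neutral": ActivityProfile("neutral", hr_mean=70.0, hr_sd=3.0,
                               resp_rate=14.0, eda_tonic=2.0, scr_rate=1.0),
    "emotional": ActivityProfile("emotional", hr_mean=78.0, hr_sd=4.0,
                                 resp_rate=16.0, eda_tonic=3.0, scr_rate=4.0),
    "mental": ActivityProfile("mental", hr_mean=74.0, hr_sd=3.5,
                              resp_rate=17.0, eda_tonic=2.8, scr_rate=3.0),
    "physical": ActivityProfile("physical", hr_mean=110.0, hr_sd=5.0,
                                resp_rate=25.0, eda_tonic=5.0, scr_rate=6.0),
}


@dataclass
class SessionRecording:
    """One subject's continuous multi-channel recording plus activity timeline."""

    subject_id: str
    ecg: np.ndarray
    teb: np.ndarray
    eda_hand: np.ndarray
    eda_arm: np.ndarray
    timeline: list[tuple[str, float, float]]
    ground_truth: dict = field(default_factory=dict)
    ecg_fs: float = ECG_FS
    aux_fs: float = AUX_FS

    @property
    def duration(self) -> float:
        return self.timeline[-1][2] if self.timeline else 0.0

    def activity_at(self, t: float) -> str:
        """Activity of the slot containing time ``t`` (right edge belongs to
        the preceding slot, so a decision taken at a boundary is labelled by
        the activity just completed)."""
        for act, start, end in self.timeline:
            if start < t <= end:
                return act
        if self.timeline and t <= self.timeline[0][1]:
            return self.timeline[0][0]
        raise ValueError(f"time {t} outside session timeline")

    def validate(self) -> None:
        prev_end = None
        for act, start, end in self.timeline:
            if end <= start:
                raise ValueError("timeline segment with nonpositive length")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("timeline segments must be contiguous")
            prev_end = end
        n_expected_ecg = int(round(self.duration * self.ecg_fs))
        if abs(len(self.ecg) - n_expected_ecg) > 1:
            raise ValueError("ECG length inconsistent with timeline span")


def _jittered_intervals(rng: np.random.Generator, mean_interval: float,
                        cv: float, total_s: float) -> np.ndarray:
    """Cumulative event times from lognormal multiplicative interval jitter."""
    n_max = int(np.ceil(total_s / mean_interval * 1.6)) + 8
    sigma = np.sqrt(np.log1p(cv ** 2))
    mu = np.log(mean_interval) - 0.5 * sigma ** 2
    intervals = rng.lognormal(mu, sigma, size=n_max)
    times = np.cumsum(intervals)
    return times[times < total_s]


def _add_bumps(signal: np.ndarray, fs: float, centers_s: np.ndarray,
               kernel: np.ndarray, amplitudes: np.ndarray) -> None:
    """Add a scaled kernel to ``signal`` at each centre time (in place)."""
    n = len(signal)
    k = len(kernel)
    for c, a in zip(centers_s, amplitudes):
        i0 = int(round(c * fs))
        i1 = min(i0 + k, n)
        if i0 < n:
            signal[i0:i1] += a * kernel[: i1 - i0]


def _ecg_beat_kernel(fs: float) -> tuple[np.ndarray, int]:
    """Template of one cardiac cycle: Gaussian P, Q, R, S and T waves.

    Returns (kernel, index of the R apex within the kernel).
    """
    t = np.arange(-0.30, 0.45, 1.0 / fs)
    waves = [  # (center s, width s, amplitude)
        (-0.17, 0.025, 0.12),   # P
        (-0.025, 0.010, -0.15),  # Q
        (0.0, 0.012, 1.00),     # R
        (0.025, 0.010, -0.20),  # S
        (0.25, 0.050, 0.30),    # T
    ]
    kernel = np.zeros_like(t)
    for c, w, a in waves:
        kernel += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    r_idx = int(np.argmin(np.abs(t)))
    return kernel, r_idx


def _scr_kernel(fs: float) -> np.ndarray:
    """Canonical skin-conductance-response shape: fast rise, slow decay."""
    t = np.arange(0.0, 12.0, 1.0 / fs)
    tau_r, tau_d = 0.75, 3.0
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def generate_session(subject_id: str,
                     profiles: dict[str, ActivityProfile] | None = None,
                     segment_s: float = 280.0,
                     seed: int = 0) -> SessionRecording:
    """Generate one continuous session: four equal activity segments in
    protocol order (neutral, emotional, mental, physical).

    The recording is continuous across activity boundaries, so an analysis
    window anchored shortly after a boundary reaches back into the previous
    activity, as in a real uninterrupted protocol.
    """
    if segment_s <= 0:
        raise ValueError("segment_s must be positive")
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    missing = [a for a in ACTIVITIES if a not in profiles]
    if missing:
        raise ValueError(f"missing activity profiles: {missing}")

    rng = np.random.default_rng(seed)
    total_s = segment_s * len(ACTIVITIES)
    timeline = [(a, i * segment_s, (i + 1) * segment_s)
                for i, a in enumerate(ACTIVITIES)]

    n_ecg = int(round(total_s * ECG_FS))
    n_aux = int(round(total_s * AUX_FS))
    t_aux = np.arange(n_aux) / AUX_FS

    # --- beat times: per-segment lognormal RR jitter around 60/hr_mean ---
    beat_times = []
    for act, start, end in timeline:
        p = profiles[act]
        cv = p.hr_sd / p.hr_mean
        seg_beats = _jittered_intervals(rng, 60.0 / p.hr_mean, cv, segment_s)
        beat_times.append(seg_beats + start)
    beat_times = np.concatenate(beat_times)

    # ECG: beat template train; R amplitude modulated by respiration-phase
    # proxy plus noise so amplitude features carry information.
    ecg = np.zeros(n_ecg)
    kernel, r_idx = _ecg_beat_kernel(ECG_FS)
    amp = 1.0 + 0.10 * np.sin(2 * np.pi * 0.25 * beat_times) \
        + rng.normal(0.0, 0.05, size=len(beat_times))
    # shift centres so the R apex (not the kernel start) lands on the beat time
    _add_bumps(ecg, ECG_FS, beat_times - r_idx / ECG_FS, kernel, amp)

    # --- respiration: breath times with interval jitter; quasi-sinusoid via
    # piecewise-linear phase between breaths ---
    breath_times = []
    for act, start, end in timeline:
        p = profiles[act]
        seg = _jittered_intervals(rng, 60.0 / p.resp_rate, 0.08, segment_s)
        breath_times.append(seg + start)
    breath_times = np.concatenate(breath_times)

    if len(breath_times) >= 2:
        phase = np.interp(t_aux, breath_times,
                          np.arange(len(breath_times), dtype=float))
        resp = np.sin(2 * np.pi * phase)
    else:
        resp = np.zeros(n_aux)

    # per-sample HR (for cardiac ripple on TEB) from the beat train
    if len(beat_times) >= 2:
        hr_inst = 60.0 / np.diff(beat_times)
        hr_t = np.interp(t_aux, beat_times[1:], hr_inst)
    else:
        hr_t = np.full(n_aux, 70.0)
    ripple_phase = np.cumsum(hr_t / 60.0) / AUX_FS
    noise_sd = np.concatenate([
        np.full(int(round(segment_s * AUX_FS)), profiles[a].motion_noise_sd)
        for a in ACTIVITIES])[:n_aux]
    teb = 25.0 + 1.0 * resp + 0.08 * np.sin(2 * np.pi * ripple_phase) \
        + rng.normal(0.0, 1.0, n_aux) * noise_sd

    # --- EDA: tonic step per activity (smoothed), slow drift, Poisson SCRs ---
    def eda_channel(gain: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        tonic = np.concatenate([
            np.full(int(round(segment_s * AUX_FS)), profiles[a].eda_tonic)
            for a in ACTIVITIES])[:n_aux].astype(float)
        # exponential smoothing ~30 s time constant: tonic transitions are slow
        alpha = 1.0 / (30.0 * AUX_FS)
        from scipy.signal import lfilter
        tonic = lfilter([alpha], [1, -(1 - alpha)], tonic, zi=[tonic[0] * (1 - alpha)])[0]
        drift = 0.15 * np.sin(2 * np.pi * t_aux / 600.0 + rng.uniform(0, 2 * np.pi))
        onsets, amps = [], []
        for act, start, end in timeline:
            p = profiles[act]
            rate_s = p.scr_rate / 60.0
            n_ev = rng.poisson(rate_s * segment_s)
            ev = np.sort(rng.uniform(start, end - 1.0, size=n_ev))
            onsets.append(ev)
            amps.append(rng.uniform(0.2, 0.6, size=n_ev) * gain)
        onsets = np.concatenate(onsets)
        amps = np.concatenate(amps)
        sig = tonic + drift
        _add_bumps(sig, AUX_FS, onsets, _scr_kernel(AUX_FS), amps)
        sig += rng.normal(0.0, 0.01, n_aux)
        return sig, onsets, amps

    eda_hand, scr_on_hand, scr_amp_hand = eda_channel(1.0)
    eda_arm, scr_on_arm, scr_amp_arm = eda_channel(0.8)

    ground_truth = {
        "beat_times": beat_times,
        "breath_times": breath_times,
        "scr_onsets": {"eda_hand": scr_on_hand, "eda_arm": scr_on_arm},
        "scr_amplitudes": {"eda_hand": scr_amp_hand, "eda_arm": scr_amp_arm},
    }
    session = SessionRecording(subject_id=subject_id, ecg=ecg, teb=teb,
                               eda_hand=eda_hand, eda_arm=eda_arm,
                               timeline=timeline, ground_truth=ground_truth)
    session.validate()
    return session


def perturbed_profiles(rng: np.random.Generator,
                       base: dict[str, ActivityProfile] | None = None,
                       ) -> dict[str, ActivityProfile]:
    """Per-subject variant of the activity profiles.

    A shared subject factor scales heart rate, respiration and tonic level
    across all activities (people differ in resting physiology), with a small
    extra per-activity wobble.
    """
    base = DEFAULT_PROFILES if base is None else base
    hr_f = rng.normal(1.0, 0.05)
    resp_f = rng.normal(1.0, 0.06)
    tonic_f = rng.lognormal(0.0, 0.15)
    out = {}
    for act, p in base.items():
        out[act] = replace(
            p,
            hr_mean=p.hr_mean * hr_f * rng.normal(1.0, 0.02),
            resp_rate=p.resp_rate * resp_f * rng.normal(1.0, 0.03),
            eda_tonic=p.eda_tonic * tonic_f * rng.lognormal(0.0, 0.05),
            scr_rate=max(0.0, p.scr_rate * rng.normal(1.0, 0.15)),
        )
    return out


def generate_cohort(n_subjects: int = 40, segment_s: float = 280.0,
                    seed: int = 0,
                    profile_overrides: dict[str, ActivityProfile] | None = None,
                    ) -> list[SessionRecording]:
    """Generate a cohort with deterministic per-subject variability.

    Each subject's profiles are drawn from ``perturbed_profiles`` using a
    child seed derived from ``seed``, so cohorts are reproducible and
    subjects are mutually distinct.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2 ** 31 - 1, size=2 * n_subjects)
    sessions = []
    for i in range(n_subjects):
        prof_rng = np.random.default_rng(int(child_seeds[2 * i]))
        profiles = perturbed_profiles(prof_rng, profile_overrides)
        sessions.append(generate_session(
            subject_id=f"S{i + 1:03d}", profiles=profiles,
            segment_s=segment_s, seed=int(child_seeds[2 * i + 1])))
    return sessions
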