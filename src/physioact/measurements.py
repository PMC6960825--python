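"""Derivation of named measurement streams from raw channels.

Every downstream feature is a parameter of a *measurement stream*: a named
time series derived from one raw channel.  ECG yields the raw trace plus
beat-indexed series (RR, RA, HR, HRV) and band-power series of the RR
tachogram; TEB yields the respiration waveform (LF), respiration frequency
(RF), breath-interval differences (BRV) and band powers of the breath
intervals; each EDA site yields the raw trace, the phasic (Processed)
component, band-limited LF/HF components, SCR events and band powers.

All times are seconds from session start.  Interval-derived values are
attributed to the time of their later endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

# Spectral band edges (Hz) for beat/breath interval series.  The low end of
# the conventional HRV LF band is split into LF and MF so that ratios such as
# (LF+MF)/HF are distinct features.
INTERVAL_BANDS: dict[str, tuple[float, float]] = {
    "VLLF": (0.003, 0.02),
    "VLF": (0.02, 0.04),
    "LF": (0.04, 0.08),
    "MF": (0.08, 0.15),
    "HF": (0.15, 0.5),
}

# EDA spectral bands (Hz), applied to the skin-conductance signal itself.
EDA_BANDS: dict[str, tuple[float, float]] = {
    "LF": (0.01, 0.08),
    "HF": (0.08, 0.5),
}

RESP_LOWPASS_HZ = 0.7        # TEB -> respiration waveform
BREATH_REFRACTORY_S = 1.2
EDA_TONIC_LOWPASS_HZ = 0.05  # tonic/phasic split
SCR_THRESHOLD_US = 0.05      # minimum trough-to-peak rise of an SCR
RESAMPLE_HZ = 4.0            # uniform rate for event-series periodograms
PSD_SUBWINDOW_S = 30.0
PSD_HOP_S = 5.0


@dataclass
class MeasurementStream:
    """A named derived time series on which parameters are computed."""

    name: str
    times: np.ndarray
    values: np.ndarray
    kind: str  # "uniform" | "event_indexed"
    source_signal: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Values with times in (t0, t1]."""
        m = (self.times > t0) & (self.times <= t1)
        return self.values[m]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BeatSeries:
    """R-peak times and the interval/amplitude series derived from them."""

    beat_times: np.ndarray
    ra: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ra = np.asarray(self.ra, dtype=float)

    @property
    def rr(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def hr(self) -> np.ndarray:
        return 60.0 / self.rr

    @property
    def hrv(self) -> np.ndarray:
        return np.diff(self.rr)


@dataclass
class ScrEventList:
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))


def _zerophase_lowpass(x: np.ndarray, fs: float, cutoff: float,
                       order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(ecg: np.ndarray, fs: float = 250.0) -> BeatSeries:
    """QRS detection: band-pass, squared derivative, integration, adaptive
    threshold — the classic energy-based scheme.

    A 0.25 s refractory period is enforced.  RA is the raw signal value at
    each detected beat.  A flat or empty signal yields an empty series.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs or np.ptp(ecg) == 0:
        return BeatSeries(np.empty(0), np.empty(0))
    sos = sps.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(band) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    refractory = int(round(0.25 * fs))
    peaks, props = sps.find_peaks(integ, distance=refractory,
                                  height=1e-12)
    if len(peaks) == 0:
        return BeatSeries(np.empty(0), np.empty(0))
    heights = props["peak_heights"]
    thresh = 0.20 * np.median(heights[heights >= np.quantile(heights, 0.5)])
    peaks = peaks[heights > thresh]
    # refine each detection to the raw-signal maximum within +-60 ms
    half = int(round(0.06 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    # re-enforce refractory after refinement
    keep = []
    for idx in refined:
        if not keep or idx - keep[-1] >= refractory:
            keep.append(idx)
    beats = np.asarray(keep, dtype=int)
    return BeatSeries(beats / fs, ecg[beats])


def derive_respiration(teb: np.ndarray, fs: float = 100.0
                       ) -> dict[str, MeasurementStream]:
    """Respiration streams from thoracic bioimpedance.

    ``lf``: zero-phase low-passed TEB (the respiration waveform); ``rf``:
    instantaneous respiration frequency in breaths/min at each breath;
    ``brv``: successive differences of breath-to-breath intervals (s).
    Breath peaks carry a 1.2 s refractory period.
    """
    teb = np.asarray(teb, dtype=float)
    t = np.arange(len(teb)) / fs
    lf = _zerophase_lowpass(teb - np.mean(teb), fs, RESP_LOWPASS_HZ)
    lf_stream = MeasurementStream("LF", t, lf, "uniform", "TEB")
    empty = lambda name: MeasurementStream(  # noqa: E731
        name, np.empty(0), np.empty(0), "event_indexed", "TEB")
    if len(teb) < 2 * fs * BREATH_REFRACTORY_S or np.std(lf) == 0:
        return {"lf": lf_stream, "rf": empty("RF"), "brv": empty("BRV"),
                "breath_times": np.empty(0)}
    peaks, _ = sps.find_peaks(lf, distance=int(BREATH_REFRACTORY_S * fs),
                              prominence=0.3 * np.std(lf))
    breath_times = peaks / fs
    if len(breath_times) < 2:
        return {"lf": lf_stream, "rf": empty("RF"), "brv": empty("BRV"),
                "breath_times": breath_times}
    intervals = np.diff(breath_times)
    rf = MeasurementStream("RF", breath_times[1:], 60.0 / intervals,
                           "event_indexed", "TEB")
    brv = MeasurementStream("BRV", breath_times[2:], np.diff(intervals),
                            "event_indexed", "TEB")
    return {"lf": lf_stream, "rf": rf, "brv": brv,
            "breath_times": breath_times, "intervals": intervals}


def process_eda(eda: np.ndarray, fs: float = 100.0, source: str = "EDA",
                scr_threshold: float = SCR_THRESHOLD_US
                ) -> dict[str, object]:
    """Tonic/phasic decomposition and SCR detection for one EDA site.

    ``processed`` is the phasic component (raw minus a 0.05 Hz zero-phase
    low-pass tonic estimate).  SCR events are local maxima of the phasic
    signal whose rise from the preceding trough exceeds ``scr_threshold``;
    the event onset is placed at the preceding trough.
    """
    eda = np.asarray(eda, dtype=float)
    t = np.arange(len(eda)) / fs
    if len(eda) < 4 * fs:
        z = np.zeros_like(eda)
        return {"processed": MeasurementStream("Processed", t, z, "uniform", source),
                "lf": MeasurementStream("LF", t, z, "uniform", source),
                "hf": MeasurementStream("HF", t, z, "uniform", source),
                "scr": ScrEventList()}
    tonic = _zerophase_lowpass(eda, fs, EDA_TONIC_LOWPASS_HZ, order=2)
    phasic = eda - tonic
    lf_band = sps.butter(2, EDA_BANDS["LF"], btype="band", fs=fs, output="sos")
    hf_band = sps.butter(2, EDA_BANDS["HF"], btype="band", fs=fs, output="sos")
    lf = sps.sosfiltfilt(lf_band, eda - eda.mean())
    hf = sps.sosfiltfilt(hf_band, eda - eda.mean())

    # smooth the phasic trace slightly before peak picking (noise floor)
    smooth = _zerophase_lowpass(phasic, fs, 2.0)
    peaks, _ = sps.find_peaks(smooth, distance=int(1.0 * fs))
    onsets, amps = [], []
    for p in peaks:
        seg = smooth[max(0, p - int(10 * fs)):p + 1]
        trough_rel = int(np.argmin(seg))
        trough = max(0, p - int(10 * fs)) + trough_rel
        rise = smooth[p] - smooth[trough]
        if rise > scr_threshold:
            onsets.append(trough / fs)
            amps.append(rise)
    scr = ScrEventList(np.asarray(onsets), np.asarray(amps))
    return {"processed": MeasurementStream("Processed", t, phasic, "uniform", source),
            "lf": MeasurementStream("LF", t, lf, "uniform", source),
            "hf": MeasurementStream("HF", t, hf, "uniform", source),
            "scr": scr}


def resample_uniform(stream: MeasurementStream, fs: float = RESAMPLE_HZ
                     ) -> MeasurementStream:
    """Cubic-interpolation resampling of an event-indexed stream to ``fs``."""
    if len(stream) < 4:
        return MeasurementStream(stream.name, np.empty(0), np.empty(0),
                                 "uniform", stream.source_signal)
    t0, t1 = stream.times[0], stream.times[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    f = interp1d(stream.times, stream.values, kind="cubic")
    return MeasurementStream(stream.name, t, f(t), "uniform",
                             stream.source_signal)


def _band_masses(freqs: np.ndarray, pxx: np.ndarray,
                 bands: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Band powers from a periodogram: each frequency bin's mass
    (density x bin width) goes to the band containing it, so a partition of
    [0, Nyquist] sums to the total power.  A band narrower than the bin
    spacing receives the interpolated density at its midpoint times its
    width — the nearest-bin mass — rather than exactly zero."""
    if len(freqs) < 2:
        return {name: 0.0 for name in bands} | {"total": 0.0}
    df = float(freqs[1] - freqs[0])
    out = {}
    for name, (lo, hi) in bands.items():
        m = (freqs > lo) & (freqs <= hi)
        if np.any(m):
            out[name] = float(np.sum(pxx[m]) * df)
        else:
            mid = min((lo + hi) / 2.0, freqs[-1])
            out[name] = float(np.interp(mid, freqs, pxx) * (hi - lo))
    out["total"] = float(np.sum(pxx[freqs > 0]) * df)
    return out


def band_power_series(stream: MeasurementStream,
                      bands: dict[str, tuple[float, float]],
                      subwindow_s: float = PSD_SUBWINDOW_S,
                      hop_s: float = PSD_HOP_S,
                      resample_fs: float = RESAMPLE_HZ,
                      ) -> dict[str, MeasurementStream]:
    """Short-time band-power series of a measurement stream.

    Event-indexed streams are first cubic-resampled to a uniform rate.  For
    each hop a linearly detrended periodogram of the sub-window is integrated
    over each band (plus the total power up to Nyquist).  Each estimate is
    stamped with the sub-window's end time.  A stream shorter than one
    sub-window yields a single whole-stream estimate.
    """
    if stream.kind == "event_indexed":
        stream = resample_uniform(stream, resample_fs)
    names = list(bands) + ["total"]
    src = stream.source_signal
    if len(stream) < 8:
        return {n: MeasurementStream(f"PSD-{n}", np.empty(0), np.empty(0),
                                     "uniform", src) for n in names}
    dt = float(np.median(np.diff(stream.times)))
    fs = 1.0 / dt
    n_sub = int(round(subwindow_s / dt))
    hop = max(1, int(round(hop_s / dt)))
    x = stream.values
    if len(x) <= n_sub:
        starts = [0]
        n_sub = len(x)
    else:
        starts = list(range(0, len(x) - n_sub + 1, hop))
    times = np.empty(len(starts))
    powers = {n: np.empty(len(starts)) for n in names}
    for j, s in enumerate(starts):
        seg = x[s:s + n_sub]
        freqs, pxx = sps.periodogram(seg, fs=fs, detrend="linear")
        masses = _band_masses(freqs, pxx, bands)
        for n in names:
            powers[n][j] = masses[n]
        times[j] = stream.times[s + n_sub - 1]
    return {n: MeasurementStream(f"PSD-{n}", times, powers[n], "uniform", src)
            for n in names}
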