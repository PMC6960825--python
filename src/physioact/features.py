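"""Per-decision-window feature computation over the measurement catalog.

The decision grid is fixed by the protocol: one decision every ``shift_s``
seconds (10 s by default), labelled with the activity of the slot just
completed.  The analysis window reaches back ``W`` seconds from the decision
time, crossing activity boundaries when earlier data exists, so the number
of decisions does not depend on the window length.

Window statistics are the 13-parameter SSSP; the slow baseline is a
first-order IIR low-pass whose coefficient corresponds to a ~20 min memory,
run over the whole session up to the decision time.  Parameters that cannot
be computed in a window (empty event stream, too-short series) are NaN here
and imputed with design-set column means at training time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter, resample_poly

from .measurements import (EDA_BANDS, INTERVAL_BANDS, MeasurementStream,
                           band_power_series, derive_respiration,
                           detect_r_peaks, process_eda)
from .registry import (BASELINE_PARAM, FeatureRegistry, SIGNAL_NAMES,
                       SSSP_PARAMS, _SIGNAL_KIND)
from .synth import SessionRecording

BASELINE_MEMORY_S = 1200.0  # ~20 min effective memory of the baseline filter
DFA1_SCALES = np.arange(4, 17)
DFA2_SCALES = np.unique(np.round(np.geomspace(8, 32, 8)).astype(int))
DEFAULT_SHIFT_S = 10.0
WINDOW_LENGTHS = (10.0, 20.0, 40.0, 60.0)


# ---------------------------------------------------------------------------
# elementary parameters
# ---------------------------------------------------------------------------

def sssp(values: np.ndarray) -> np.ndarray:
    """The Standard Set of Statistical Parameters of a vector, in registry
    order: mean, median, SD, 25% trimmed mean, skewness, kurtosis, maximum,
    minimum, 25th/75th percentiles, geometric mean, harmonic mean and mean
    absolute deviation.

    Conventions: SD/skewness/kurtosis are 0 for vectors shorter than 2 or
    with zero variance (excess kurtosis is used); the trimmed mean removes
    25% of mass from each tail; percentiles interpolate linearly; when any
    value is <= 0 the geometric and harmonic means are computed on the
    vector shifted by (1 - min), so they are always finite.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return np.full(13, np.nan)
    mean = float(v.mean())
    dev = v - mean
    scale = float(np.max(np.abs(dev))) if n >= 2 else 0.0
    if scale == 0.0 or v[-1] == v[0]:
        # constant vector or single sample: moments zero by convention
        sd = skew = kurt = 0.0
    else:
        w = dev / scale  # max-normalized: moment ratios without underflow
        m2 = float(np.mean(w ** 2))
        sd = scale * float(np.sqrt(m2 * n / (n - 1)))
        skew = float(np.mean(w ** 3)) / m2 ** 1.5
        kurt = float(np.mean(w ** 4)) / m2 ** 2 - 3.0
    k = int(n * 0.25)  # samples trimmed from EACH tail
    trimmed = float(v[k:n - k].mean()) if n - 2 * k > 0 else mean
    p25, med, p75 = np.percentile(v, [25.0, 50.0, 75.0])
    vmin, vmax = float(v[0]), float(v[-1])
    pos = v if vmin > 0 else v + (1.0 - vmin)
    gmean = float(np.exp(np.mean(np.log(pos))))
    hmean = float(n / np.sum(1.0 / pos))
    return np.array([
        mean, float(med), sd, trimmed, skew, kurt, vmax, vmin,
        float(p25), float(p75), gmean, hmean,
        float(np.mean(np.abs(v - mean))),
    ])


def baseline(stream: MeasurementStream, beta: float) -> MeasurementStream:
    """First-order IIR baseline  y_i = z_i * beta + y_{i-1} * (1 - beta),
    initialised at y_0 = z_0; same timestamps as the input."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must be in (0, 1]")
    z = stream.values
    if len(z) == 0:
        return MeasurementStream(stream.name + ".baseline", stream.times,
                                 z.copy(), stream.kind, stream.source_signal)
    y, _ = lfilter([beta], [1.0, -(1.0 - beta)], z, zi=[z[0] * (1.0 - beta)])
    return MeasurementStream(stream.name + ".baseline", stream.times, y,
                             stream.kind, stream.source_signal)


def baseline_beta(stream: MeasurementStream,
                  memory_s: float = BASELINE_MEMORY_S) -> float:
    """Coefficient giving the baseline filter a ~``memory_s`` memory:
    the mean sample interval divided by the memory, clamped to (0, 1]."""
    if len(stream) < 2:
        return 1.0
    dt = float(np.mean(np.diff(stream.times)))
    return float(min(max(dt / memory_s, 1e-12), 1.0))


def dfa(series: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The mean-removed series is integrated, split into non-overlapping boxes
    of each scale, linearly detrended per box; the exponent is the slope of
    log F(n) against log n.  Scales above len(series)//4 are dropped; fewer
    than 3 usable scales yields NaN (the caller imputes).
    """
    x = np.asarray(series, dtype=float)
    scales = np.asarray(scales, dtype=int)
    scales = scales[scales <= len(x) // 4]
    if len(x) < 8 or len(scales) < 3 or np.ptp(x) == 0:
        return float("nan")
    y = np.cumsum(x - np.mean(x))
    log_n, log_f = [], []
    for n in scales:
        n_boxes = len(y) // n
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box linear detrend via least squares
        tm = t - t.mean()
        slope = seg @ tm / (tm @ tm)
        resid = seg - seg.mean(axis=1, keepdims=True) - np.outer(slope, tm)
        f = np.sqrt(np.mean(resid ** 2))
        if f > 0:
            log_n.append(np.log(n))
            log_f.append(np.log(f))
    if len(log_n) < 3:
        return float("nan")
    return float(np.polyfit(log_n, log_f, 1)[0])


# ---------------------------------------------------------------------------
# decision grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionWindow:
    subject_id: str
    decision_time: float
    window_length: float
    label: str

    @property
    def start(self) -> float:
        return max(0.0, self.decision_time - self.window_length)


def slice_decisions(session: SessionRecording, window_length: float,
                    shift_s: float = DEFAULT_SHIFT_S) -> list[DecisionWindow]:
    """One decision at each multiple of ``shift_s`` inside every activity
    segment, labelled by the activity of the slot ending at the decision
    time.  The count of decisions is independent of the window length."""
    decisions = []
    for act, start, end in session.timeline:
        n_slots = int(np.floor((end - start) / shift_s + 1e-9))
        for j in range(1, n_slots + 1):
            decisions.append(DecisionWindow(session.subject_id,
                                            start + j * shift_s,
                                            window_length, act))
    return decisions


# ---------------------------------------------------------------------------
# session-level measurement bundle
# ---------------------------------------------------------------------------

class SessionMeasurements:
    """All measurement streams of a session, with precomputed baselines and
    band-power series, ready for windowed parameter extraction."""

    def __init__(self, session: SessionRecording) -> None:
        self.session = session
        self.streams: dict[tuple[str, str], MeasurementStream] = {}
        self.scr: dict[str, object] = {}
        self.breath_times = np.empty(0)
        self._build()
        self.baselines = {
            key: baseline(s, baseline_beta(s)) if len(s) else None
            for key, s in self.streams.items()
        }

    def _put(self, signal: str, measurement: str,
             stream: MeasurementStream) -> None:
        self.streams[(signal, measurement)] = stream

    def _build(self) -> None:
        ses = self.session
        t_ecg = np.arange(len(ses.ecg)) / ses.ecg_fs
        t_aux = np.arange(len(ses.teb)) / ses.aux_fs

        # --- ECG ---
        self._put("ecg", "Original",
                  MeasurementStream("Original", t_ecg, ses.ecg, "uniform", "ECG"))
        beats = detect_r_peaks(ses.ecg, ses.ecg_fs)
        bt = beats.beat_times
        rr = MeasurementStream("RR", bt[1:], beats.rr, "event_indexed", "ECG") \
            if len(bt) >= 2 else MeasurementStream("RR", np.empty(0), np.empty(0),
                                                   "event_indexed", "ECG")
        self._put("ecg", "RR", rr)
        self._put("ecg", "RA",
                  MeasurementStream("RA", bt, beats.ra, "event_indexed", "ECG"))
        self._put("ecg", "HR",
                  MeasurementStream("HR", bt[1:], 60.0 / beats.rr,
                                    "event_indexed", "ECG")
                  if len(bt) >= 2 else
                  MeasurementStream("HR", np.empty(0), np.empty(0),
                                    "event_indexed", "ECG"))
        self._put("ecg", "HRV",
                  MeasurementStream("HRV", bt[2:], beats.hrv,
                                    "event_indexed", "ECG")
                  if len(bt) >= 3 else
                  MeasurementStream("HRV", np.empty(0), np.empty(0),
                                    "event_indexed", "ECG"))
        for band, s in band_power_series(rr, INTERVAL_BANDS).items():
            name = "PSD" if band == "total" else f"PSD-{band}"
            self._put("ecg", name, s)

        # --- TEB ---
        self._put("teb", "Original",
                  MeasurementStream("Original", t_aux, ses.teb, "uniform", "TEB"))
        resp = derive_respiration(ses.teb, ses.aux_fs)
        self._put("teb", "LF", resp["lf"])
        self._put("teb", "RF", resp["rf"])
        self._put("teb", "BRV", resp["brv"])
        self.breath_times = resp["breath_times"]
        bti = resp.get("intervals")
        intervals = MeasurementStream(
            "BreathIntervals",
            resp["breath_times"][1:] if bti is not None else np.empty(0),
            bti if bti is not None else np.empty(0), "event_indexed", "TEB")
        for band, s in band_power_series(intervals, INTERVAL_BANDS).items():
            name = "PSD" if band == "total" else f"PSD-{band}"
            self._put("teb", name, s)

        # --- EDA sites ---
        for sig, raw in (("eda_hand", ses.eda_hand), ("eda_arm", ses.eda_arm)):
            src = SIGNAL_NAMES[sig]
            self._put(sig, "Original",
                      MeasurementStream("Original", t_aux, raw, "uniform", src))
            proc = process_eda(raw, ses.aux_fs, source=src)
            self._put(sig, "Processed", proc["processed"])
            self._put(sig, "LF", proc["lf"])
            self._put(sig, "HF", proc["hf"])
            self.scr[sig] = proc["scr"]
            # decimate to 4 Hz before spectral analysis (bands end at 0.5 Hz)
            down = int(round(ses.aux_fs / 4.0))
            eda4 = resample_poly(raw - np.mean(raw), 1, down)
            s4 = MeasurementStream("Original4Hz",
                                   np.arange(len(eda4)) / 4.0, eda4,
                                   "uniform", src)
            for band, s in band_power_series(s4, EDA_BANDS).items():
                name = "PSD" if band == "total" else f"PSD-{band}"
                self._put(sig, name, s)

    def baseline_at(self, key: tuple[str, str], t: float) -> float:
        b = self.baselines.get(key)
        if b is None or len(b) == 0:
            return float("nan")
        i = np.searchsorted(b.times, t, side="right") - 1
        return float(b.values[i]) if i >= 0 else float("nan")


# band names used for ratio features, per signal kind
_RATIO_BANDS = {"ECG": ("VLF", "LF", "MF", "HF"),
                "TEB": ("VLF", "LF", "MF", "HF"),
                "EDA": ("LF", "HF")}


def _window_band_means(sm: SessionMeasurements, signal: str,
                       t0: float, t1: float) -> dict[str, float]:
    kind = _SIGNAL_KIND[signal]
    out = {}
    for band in _RATIO_BANDS[kind] + ("total",):
        meas = "PSD" if band == "total" else f"PSD-{band}"
        v = sm.streams[(signal, meas)].window(t0, t1)
        out[band] = float(np.mean(v)) if len(v) else float("nan")
    return out


def _safe_div(a: float, b: float) -> float:
    return a / b if np.isfinite(a) and np.isfinite(b) and b != 0 else float("nan")


def _extra_param(param: str, v: np.ndarray, *, signal: str,
                 sm: SessionMeasurements, t0: float, t1: float,
                 band_means: dict[str, float]) -> float:
    bm = band_means
    if param == "log_sd":
        sd = np.std(v, ddof=1) if len(v) >= 2 else 0.0
        return float(np.log(sd)) if sd > 0 else float("nan")
    if param == "rmssd":
        d = np.diff(v)
        return float(np.sqrt(np.mean(d ** 2))) if len(d) else float("nan")
    if param == "sdsd":
        d = np.diff(v)
        return float(np.std(d, ddof=1)) if len(d) >= 2 else float("nan")
    if param in ("nn50", "pnn50", "pnn20"):
        d = np.abs(np.diff(v))
        if len(d) == 0:
            return float("nan")
        thr = 0.020 if param == "pnn20" else 0.050
        n = int(np.sum(d > thr))
        return float(n) if param == "nn50" else float(n) / len(d)
    if param == "dfa1":
        return dfa(v, DFA1_SCALES)
    if param == "dfa2":
        return dfa(v, DFA2_SCALES)
    if param == "average_br":
        m = (sm.breath_times > t0) & (sm.breath_times <= t1)
        return 60.0 * float(np.sum(m)) / (t1 - t0) if t1 > t0 else float("nan")
    if param == "n_scr":
        ev = sm.scr[signal]
        return float(np.sum((ev.onsets > t0) & (ev.onsets <= t1)))
    if param == "mean_scr_amplitude":
        ev = sm.scr[signal]
        m = (ev.onsets > t0) & (ev.onsets <= t1)
        return float(np.mean(ev.amplitudes[m])) if np.any(m) else float("nan")
    if param in ("pns", "nzc", "pzc"):
        d = np.diff(v)
        if len(d) == 0:
            return float("nan")
        if param == "pns":
            return float(np.mean(d < 0))
        sign = np.sign(d)
        nz = sign != 0
        s = sign[nz]
        if len(s) < 2:
            return 0.0
        flips = np.diff(s)
        if param == "nzc":
            return float(np.sum(flips < 0))
        return float(np.sum(flips > 0))
    if param == "hf_lf_ratio":
        return _safe_div(bm.get("HF", np.nan), bm.get("LF", np.nan))
    if param == "lf_hf_ratio":
        return _safe_div(bm.get("LF", np.nan), bm.get("HF", np.nan))
    if param == "lfmf_hf_ratio":
        return _safe_div(bm.get("LF", np.nan) + bm.get("MF", np.nan),
                         bm.get("HF", np.nan))
    if param == "mf_hf_ratio":
        return _safe_div(bm.get("MF", np.nan), bm.get("HF", np.nan))
    if param.endswith("_nu"):
        return _safe_div(bm.get(param[:-3].upper(), np.nan), bm.get("total", np.nan))
    raise KeyError(f"unknown extra parameter {param!r}")


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-decision feature table: rows are decisions, columns follow the
    registry order; labels and subject ids align with rows."""

    X: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subjects: np.ndarray
    decision_times: np.ndarray
    registry_hash: str

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "subject", self.subjects)
        df.insert(1, "label", self.labels)
        df.insert(2, "decision_time", self.decision_times)
        return df

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        return cls(np.vstack([p.X for p in parts]), parts[0].columns,
                   np.concatenate([p.labels for p in parts]),
                   np.concatenate([p.subjects for p in parts]),
                   np.concatenate([p.decision_times for p in parts]),
                   parts[0].registry_hash)


def extract_features(session: SessionRecording, registry: FeatureRegistry,
                     window_length: float,
                     shift_s: float = DEFAULT_SHIFT_S) -> FeatureMatrix:
    """Compute every registry parameter for every decision window of one
    session.  Output column order equals registry order; uncomputable
    entries are NaN."""
    sm = SessionMeasurements(session)
    decisions = slice_decisions(session, window_length, shift_s)

    # group registry entries by (signal, measurement), preserving order
    groups: list[tuple[str, str, list[str]]] = []
    for e in registry.entries:
        if groups and groups[-1][0] == e.signal and groups[-1][1] == e.measurement:
            groups[-1][2].append(e.parameter)
        else:
            groups.append((e.signal, e.measurement, [e.parameter]))

    X = np.empty((len(decisions), len(registry)))
    for i, d in enumerate(decisions):
        t0, t1 = d.start, d.decision_time
        band_cache: dict[str, dict[str, float]] = {}
        col = 0
        for signal, meas, params in groups:
            stream = sm.streams[(signal, meas)]
            v = stream.window(t0, t1)
            if signal not in band_cache:
                band_cache[signal] = _window_band_means(sm, signal, t0, t1)
            for p in params:
                if p in SSSP_PARAMS:
                    if p == SSSP_PARAMS[0]:
                        stats = sssp(v)
                    X[i, col] = stats[SSSP_PARAMS.index(p)]
                elif p == BASELINE_PARAM:
                    X[i, col] = sm.baseline_at((signal, meas), t1)
                else:
                    X[i, col] = _extra_param(
                        p, v, signal=signal, sm=sm, t0=t0, t1=t1,
                        band_means=band_cache[signal])
                col += 1
    return FeatureMatrix(
        X, list(registry.names),
        np.array([d.label for d in decisions]),
        np.array([d.subject_id for d in decisions]),
        np.array([d.decision_time for d in decisions]),
        registry.hash)


def build_feature_matrix(sessions: list[SessionRecording],
                         registry: FeatureRegistry, window_length: float,
                         shift_s: float = DEFAULT_SHIFT_S) -> FeatureMatrix:
    """Extract and stack feature rows for a cohort of sessions."""
    parts = [extract_features(s, registry, window_length, shift_s)
             for s in sessions]
    return FeatureMatrix.concat(parts)
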