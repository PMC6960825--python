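"""The enumerated feature catalog.

Every feature is a (signal, measurement, parameter) triple.  All measurements
receive the 13-statistic standard set (SSSP) plus a slow-baseline value;
selected measurements carry extra, measurement-specific parameters
(interval-variability statistics, detrended-fluctuation exponents, band
ratios, SCR counts, ...).  The per-signal totals are ECG 174, TEB 151 and
104 per EDA site — 533 in all.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

#: The Standard Set of Statistical Parameters, in registry order.
SSSP_PARAMS: tuple[str, ...] = (
    "mean", "median", "sd", "trimmed_mean_25", "skewness", "kurtosis",
    "maximum", "minimum", "p25", "p75", "geometric_mean", "harmonic_mean",
    "mad",
)

BASELINE_PARAM = "mean_baseline"

#: Measurement inventories per signal (PSD = total band power series).
ECG_MEASUREMENTS = ("Original", "RR", "RA", "HR", "HRV",
                    "PSD", "PSD-VLLF", "PSD-VLF", "PSD-LF", "PSD-MF", "PSD-HF")
TEB_MEASUREMENTS = ("Original", "LF", "RF", "BRV",
                    "PSD", "PSD-VLLF", "PSD-VLF", "PSD-LF", "PSD-MF", "PSD-HF")
EDA_MEASUREMENTS = ("Original", "Processed", "LF", "HF",
                    "PSD", "PSD-LF", "PSD-HF")

#: Extra parameters beyond SSSP + baseline, keyed by (signal kind, measurement).
_INTERVAL_PSD_EXTRAS = {
    "PSD-VLF": ("vlf_nu",),
    "PSD-LF": ("lf_hf_ratio", "lfmf_hf_ratio", "lf_nu"),
    "PSD-MF": ("mf_hf_ratio", "mf_nu"),
    "PSD-HF": ("hf_lf_ratio", "hf_nu"),
}
EXTRAS: dict[tuple[str, str], tuple[str, ...]] = {
    ("ECG", "RR"): ("log_sd", "dfa1", "dfa2", "rmssd", "sdsd",
                    "nn50", "pnn50", "pnn20"),
    ("ECG", "HR"): ("dfa1", "dfa2"),
    ("ECG", "HRV"): ("log_sd", "rmssd"),
    **{("ECG", m): p for m, p in _INTERVAL_PSD_EXTRAS.items()},
    ("TEB", "RF"): ("average_br",),
    ("TEB", "BRV"): ("log_sd", "rmssd"),
    **{("TEB", m): p for m, p in _INTERVAL_PSD_EXTRAS.items()},
    ("EDA", "Processed"): ("n_scr", "pns", "nzc", "pzc", "mean_scr_amplitude"),
    ("EDA", "PSD-HF"): ("hf_lf_ratio",),
}

#: Canonical signal keys and their display names.
SIGNAL_KEYS = ("ecg", "teb", "eda_hand", "eda_arm")
SIGNAL_NAMES = {"ecg": "ECG", "teb": "TEB",
                "eda_hand": "EDA-hand", "eda_arm": "EDA-arm"}
_SIGNAL_KIND = {"ecg": "ECG", "teb": "TEB",
                "eda_hand": "EDA", "eda_arm": "EDA"}
_MEASUREMENTS = {"ECG": ECG_MEASUREMENTS, "TEB": TEB_MEASUREMENTS,
                 "EDA": EDA_MEASUREMENTS}


@dataclass(frozen=True)
class FeatureEntry:
    signal: str       # "ecg" | "teb" | "eda_hand" | "eda_arm"
    measurement: str
    parameter: str

    @property
    def name(self) -> str:
        return f"{SIGNAL_NAMES[self.signal]}.{self.measurement}.{self.parameter}"


class FeatureRegistry:
    """Ordered, unique catalog of feature entries for a set of signals."""

    def __init__(self, signals: tuple[str, ...] = SIGNAL_KEYS) -> None:
        bad = [s for s in signals if s not in SIGNAL_KEYS]
        if bad:
            raise ValueError(f"unknown signals: {bad}")
        self.signals = tuple(signals)
        entries: list[FeatureEntry] = []
        for sig in self.signals:
            kind = _SIGNAL_KIND[sig]
            for meas in _MEASUREMENTS[kind]:
                for p in SSSP_PARAMS:
                    entries.append(FeatureEntry(sig, meas, p))
                entries.append(FeatureEntry(sig, meas, BASELINE_PARAM))
                for p in EXTRAS.get((kind, meas), ()):
                    entries.append(FeatureEntry(sig, meas, p))
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise AssertionError("duplicate registry entries")
        self.entries = entries
        self.names = names

    def __len__(self) -> int:
        return len(self.entries)

    def count_for(self, signal: str) -> int:
        return sum(1 for e in self.entries if e.signal == signal)

    def subset(self, signals: tuple[str, ...]) -> "FeatureRegistry":
        return FeatureRegistry(signals)

    @property
    def hash(self) -> str:
        h = hashlib.sha256("\n".join(self.names).encode())
        return h.hexdigest()[:16]
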