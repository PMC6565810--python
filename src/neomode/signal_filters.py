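"""Zero-phase Butterworth filtering and the canonical / log-spaced banks.

Band-pass filtering follows clinical-EEG practice: a high-pass and a
low-pass Butterworth applied in series, each run forward and backward
(``sosfiltfilt``) so no phase lag is introduced.  Filter order is the
smallest meeting 20 dB stop-band attenuation for a single pass; the
forward-backward application then exceeds that figure.

Two log-spaced banks cover the carrier-by-amplitude frequency plane:
21 carrier bands from 0.5 Hz and 15 amplitude bands from 0.015 Hz, with
consecutive centre frequencies in ratio 1.2 and cutoffs at 0.85 f / 1.15 f
(stops at 0.5 f / 1.5 f).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "CanonicalBand",
    "CANONICAL_BANDS",
    "FilterBankSpec",
    "build_carrier_bank",
    "build_amplitude_bank",
    "build_filter_banks",
    "apply_bandpass",
    "preprocess",
    "hilbert_envelope",
]

#: Default pass-band ripple allowed when choosing the minimal filter order.
GPASS_DB = 1.0
#: Seconds discarded at each end of a filtered epoch before correlation.
EDGE_TRIM_S = 2.0


@dataclass(frozen=True)
class BandSpec:
    """Narrow band centred at ``f``: pass 0.85f-1.15f, stop 0.5f-1.5f."""

    f: float
    attenuation_db: float = 20.0

    def __post_init__(self):
        if self.f <= 0 or self.attenuation_db <= 0:
            raise ValueError("centre frequency and attenuation must be positive")

    @property
    def pass_lo(self) -> float:
        return 0.85 * self.f

    @property
    def pass_hi(self) -> float:
        return 1.15 * self.f

    @property
    def stop_lo(self) -> float:
        return 0.5 * self.f

    @property
    def stop_hi(self) -> float:
        return 1.5 * self.f


@dataclass(frozen=True)
class CanonicalBand:
    name: str
    lo: float
    hi: float


#: The four canonical neonatal EEG bands.
CANONICAL_BANDS = {
    "delta": CanonicalBand("delta", 0.4, 1.5),
    "theta": CanonicalBand("theta", 4.0, 8.0),
    "alpha": CanonicalBand("alpha", 8.0, 13.0),
    "beta": CanonicalBand("beta", 13.0, 22.0),
}


@dataclass
class FilterBankSpec:
    carrier: list = field(default_factory=list)
    amplitude: list = field(default_factory=list)

    def to_json(self, path: str) -> None:
        def enc(bands):
            return [{"f": b.f, "pass": [b.pass_lo, b.pass_hi],
                     "stop": [b.stop_lo, b.stop_hi],
                     "attenuation_db": b.attenuation_db} for b in bands]
        with open(path, "w") as fh:
            json.dump({"carrier": enc(self.carrier),
                       "amplitude": enc(self.amplitude)}, fh, indent=1)


def _geometric_bank(f1: float, n: int, ratio: float = 1.2) -> list:
    return [BandSpec(f1 * ratio ** k) for k in range(n)]


def build_carrier_bank() -> list:
    """21 carrier bands, f_k = 0.5 * 1.2**(k-1) Hz (f_21 ~ 19.2 Hz)."""
    return _geometric_bank(0.5, 21)


def build_amplitude_bank() -> list:
    """15 amplitude bands, f_k = 0.015 * 1.2**(k-1) Hz (f_15 ~ 0.19 Hz)."""
    return _geometric_bank(0.015, 15)


def build_filter_banks() -> FilterBankSpec:
    return FilterBankSpec(build_carrier_bank(), build_amplitude_bank())


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _butter_sos(kind: str, cutoff: float, stop: float, fs: float,
                attenuation_db: float):
    """Minimal-order Butterworth meeting ``attenuation_db`` at ``stop``."""
    nyq = fs / 2.0
    order, wn = sps.buttord(cutoff / nyq, stop / nyq, GPASS_DB,
                            attenuation_db)
    return sps.butter(max(order, 1), wn, btype=kind, output="sos")


def bandpass_sos(lo: float, hi: float, fs: float,
                 attenuation_db: float = 20.0,
                 stop_lo: float | None = None,
                 stop_hi: float | None = None):
    """High-pass + low-pass cascade as a list of SOS arrays."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={fs / 2})")
    stop_lo = 0.5 * lo if stop_lo is None else stop_lo
    stop_hi = min(1.5 * hi, 0.999 * fs / 2) if stop_hi is None else stop_hi
    return [_butter_sos("highpass", lo, stop_lo, fs, attenuation_db),
            _butter_sos("lowpass", hi, stop_hi, fs, attenuation_db)]


def apply_bandpass(ts: np.ndarray, lo: float, hi: float, fs: float,
                   attenuation_db: float = 20.0,
                   stop_lo: float | None = None,
                   stop_hi: float | None = None) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length preserved."""
    out = np.asarray(ts, dtype=float)
    for sos in bandpass_sos(lo, hi, fs, attenuation_db, stop_lo, stop_hi):
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return out


def apply_band(ts: np.ndarray, band, fs: float) -> np.ndarray:
    """Band-pass by a CanonicalBand or a BandSpec."""
    if isinstance(band, CanonicalBand):
        return apply_bandpass(ts, band.lo, band.hi, fs)
    return apply_bandpass(ts, band.pass_lo, band.pass_hi, fs,
                          band.attenuation_db, band.stop_lo, band.stop_hi)


def preprocess(ts: np.ndarray, fs_in: float, fs_out: float = 100.0,
               lo: float = 0.15, hi: float = 45.0) -> np.ndarray:
    """Broadband filter, resample to ``fs_out`` and re-reference.

    0.15-45 Hz zero-phase band-pass, polyphase anti-aliased resampling to
    100 Hz where needed, then common-average re-referencing (channel mean
    subtracted per sample).  Input is (channels, samples).
    """
    if fs_in < fs_out:
        raise ValueError("input rate below target rate")
    out = apply_bandpass(np.atleast_2d(ts), lo, min(hi, 0.98 * fs_out / 2), fs_in)
    if fs_in != fs_out:
        from fractions import Fraction
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        out = sps.resample_poly(out, frac.numerator, frac.denominator, axis=-1)
    return out - out.mean(axis=0, keepdims=True)


def hilbert_envelope(ts: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal."""
    x = np.asarray(ts, dtype=float)
    return np.abs(sps.hilbert(x, axis=-1))


def decimate_envelope(env: np.ndarray, fs: float, fs_out: float = 2.0):
    """Low-rate resampling of (slow) amplitude envelopes.

    Envelope fluctuations of interest live below ~0.3 Hz, so envelopes can
    be carried at a couple of Hz before amplitude-band filtering; this keeps
    the double-filter-bank pipeline tractable.  Returns (env, fs_out).
    """
    if fs == fs_out:
        return env, fs
    from fractions import Fraction
    frac = Fraction(fs_out / fs).limit_denominator(1000)
    out = sps.resample_poly(env, frac.numerator, frac.denominator, axis=-1)
    return out, fs_out


def save_timeseries(path: str, data: np.ndarray, fs: float,
                    channels=None, units: str = "uV") -> None:
    """Array container (.npz) with a JSON sidecar describing the signals."""
    import json
    np.savez(path if path.endswith(".npz") else path + ".npz", data=data)
    stem = path[:-4] if path.endswith(".npz") else path
    with open(stem + ".json", "w") as fh:
        json.dump({"fs_hz": fs, "units": units,
                   "channels": list(channels) if channels is not None
                   else [f"ch{i:02d}" for i in range(data.shape[0])]}, fh)


def load_timeseries(path: str):
    """Load a multichannel recording; returns ``(data, fs, channels)``.

    Supports the package's array container (.npz + JSON sidecar) and, when
    ``mne`` is installed, EDF files.
    """
    import json
    import os
    if path.endswith(".edf"):
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ImportError("reading EDF requires mne") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
    stem = path[:-4] if path.endswith(".npz") else path
    data = np.load(stem + ".npz")["data"]
    fs, channels = None, None
    if os.path.exists(stem + ".json"):
        with open(stem + ".json") as fh:
            meta = json.load(fh)
        fs = meta.get("fs_hz")
        channels = meta.get("channels")
    return data, fs, channels


def trim_edges(ts: np.ndarray, fs: float, trim_s: float = EDGE_TRIM_S):
    """Drop filter transients at both ends of an epoch."""
    n = int(round(trim_s * fs))
    if ts.shape[-1] <= 2 * n:
        warnings.warn("epoch shorter than twice the edge trim; not trimming")
        return ts
    return ts[..., n:ts.shape[-1] - n]
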