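"""Reading and writing single-lead ECG signals and R-peak annotations.

Supported containers:

* WFDB records (``.hea`` header + ``.dat`` signal), formats 16 and 212,
  single- or dual-channel -- the subset used by the MIT-BIH arrhythmia
  database.  Beat annotations in the standard MIT annotation byte format
  are read when an annotation file is present.
* Two-column (time, amplitude) or single-column amplitude CSV files.
* Plain-text annotation files: a ``# fs=<Hz>`` header line followed by one
  0-based sample index per line.

All indices are 0-based and amplitudes are kept in the physical units the
file declares (mV for the formats above); reading never rescales a signal
except through the format's own gain/baseline fields.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, InputError

__all__ = [
    "ECGRecord",
    "RAnnotation",
    "read_wfdb",
    "write_wfdb",
    "read_csv",
    "write_csv",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class ECGRecord:
    """A uniformly sampled single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz, strictly positive.
    lead : str
        Free-text lead label.
    t0 : float
        Start-time offset in seconds.
    """

    samples: np.ndarray
    fs: float
    lead: str = "ECG"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("ECG record needs a 1-D signal with >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InputError("ECG samples must all be finite")
        if not self.fs > 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Per-sample time stamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RAnnotation:
    """R-peak positions as strictly increasing 0-based sample indices."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise InputError("annotation indices must be 1-D")
        if idx.size and (np.any(idx < 0) or np.any(np.diff(idx) <= 0)):
            raise InputError("annotation indices must be non-negative and strictly increasing")
        if not self.fs > 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# WFDB records (formats 16 and 212)
# ---------------------------------------------------------------------------

_SUPPORTED_FORMATS = ("16", "212")
_DEFAULT_GAIN = 200.0  # adu/mV, the WFDB default
# MIT annotation codes that mark beats (N, L, R, a, V, F, J, A, S, E, j, n, e,
# f, /, Q, r); non-beat codes are skipped on read.
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header: {hea_path}")
    rec = lines[0].split()
    if len(rec) < 4:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    name, nsig = rec[0], int(rec[1])
    fs = float(rec[2].split("/")[0])
    nsamp = int(rec[3])
    if nsig < 1:
        raise FormatError("WFDB record declares no signal channels")
    if len(lines) < 1 + nsig:
        raise FormatError("WFDB header lists fewer signal lines than channels")
    signals = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fmt = f[1]
        if fmt not in _SUPPORTED_FORMATS:
            raise FormatError(
                f"unsupported WFDB signal format {fmt!r}; only formats "
                f"{'/'.join(_SUPPORTED_FORMATS)} are handled"
            )
        gain, baseline, units = _DEFAULT_GAIN, None, "mV"
        if len(f) > 2:
            spec = f[2]
            if "/" in spec:
                spec, units = spec.split("/", 1)
            if "(" in spec:
                g, b = spec.split("(")
                gain = float(g)
                baseline = int(b.rstrip(")"))
            elif spec:
                gain = float(spec)
        if gain == 0:
            gain = _DEFAULT_GAIN
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(f[8:]) if len(f) > 8 else "ECG"
        signals.append({"file": f[0], "fmt": fmt, "gain": gain,
                        "baseline": baseline, "units": units, "desc": desc})
    return name, nsig, fs, nsamp, signals


def _read_dat(path: str, fmt: str, nsig: int, nsamp: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if fmt == "16":
        adc = raw.view("<i2")[: nsig * nsamp].astype(np.int64)
        return adc.reshape(-1, nsig)
    # format 212: each byte-triplet packs two 12-bit two's-complement samples
    n_total = nsig * nsamp
    n_pairs = (n_total + 1) // 2
    raw = raw[: 3 * n_pairs].astype(np.int64)
    b0, b1, b2 = raw[0::3], raw[1::3], raw[2::3]
    first = ((b1 & 0x0F) << 8) | b0
    second = ((b1 & 0xF0) << 4) | b2
    samples = np.empty(2 * len(b0), dtype=np.int64)
    samples[0::2], samples[1::2] = first, second
    samples = samples[:n_total]
    samples[samples > 2047] -= 4096
    return samples.reshape(-1, nsig)


def _write_dat(path: str, adc: np.ndarray, fmt: str) -> None:
    if fmt == "16":
        adc.astype("<i2").tofile(path)
        return
    flat = adc.reshape(-1).astype(np.int64)
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    a, b = flat[0::2] & 0xFFF, flat[1::2] & 0xFFF
    out = np.empty(3 * a.size, dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((b >> 4) & 0xF0) | (a >> 8)
    out[2::3] = b & 0xFF
    out.tofile(path)


def _read_atr(path: str, fs: float) -> RAnnotation:
    data = np.fromfile(path, dtype="<u2")
    indices, t, i = [], 0, 0
    while i < len(data):
        word = int(data[i])
        code, delta = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            if i + 1 >= len(data):
                raise FormatError("truncated SKIP in annotation file")
            t += (int(data[i]) << 16) | int(data[i + 1])
            i += 2
            continue
        if code == _AUX:
            i += (delta + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += delta
        if code in _BEAT_CODES:
            indices.append(t)
    return RAnnotation(np.asarray(indices, dtype=np.int64), fs)


def _write_atr(path: str, ann: RAnnotation) -> None:
    words: list[int] = []
    prev = 0
    for idx in ann.indices:
        delta = int(idx) - prev
        if delta > 1023:
            words += [_SKIP << 10, (delta >> 16) & 0xFFFF, delta & 0xFFFF]
            delta = 0
        words.append((1 << 10) | delta)  # code 1 = normal beat
        prev = int(idx)
    words.append(0)
    with open(path, "wb") as fh:
        fh.write(struct.pack(f"<{len(words)}H", *words))


def read_wfdb(path: str, channel: int = 0, ann_ext: str = "atr"):
    """Read a WFDB record and, if present, its beat annotations.

    Parameters
    ----------
    path : str
        Record base path (with or without the ``.hea`` extension).
    channel : int
        Signal channel to return.
    ann_ext : str
        Annotation file extension to look for next to the record.

    Returns
    -------
    (ECGRecord, RAnnotation or None)
    """
    base = path[:-4] if path.endswith(".hea") else path
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    name, nsig, fs, nsamp, signals = _parse_header(hea)
    if not 0 <= channel < nsig:
        raise InputError(f"channel {channel} out of range for {nsig}-channel record")
    sig = signals[channel]
    dat = os.path.join(os.path.dirname(base) or ".", sig["file"])
    if not os.path.exists(dat):
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    adc = _read_dat(dat, sig["fmt"], nsig, nsamp)
    physical = (adc[:, channel] - sig["baseline"]) / sig["gain"]
    record = ECGRecord(physical, fs=fs, lead=sig["desc"])
    atr = base + "." + ann_ext
    ann = _read_atr(atr, fs) if os.path.exists(atr) else None
    return record, ann


def write_wfdb(record, path: str, ann: RAnnotation | None = None,
               fmt: str = "16", gain: float = _DEFAULT_GAIN, ann_ext: str = "atr") -> None:
    """Write a WFDB record (and optional beat annotations).

    ``record`` may be a single :class:`ECGRecord` or a list of records
    sharing fs and length (written as a multi-channel record).
    """
    if fmt not in _SUPPORTED_FORMATS:
        raise FormatError(f"unsupported WFDB write format {fmt!r}")
    records = [record] if isinstance(record, ECGRecord) else list(record)
    if len({r.fs for r in records}) != 1 or len({r.samples.size for r in records}) != 1:
        raise InputError("all channels must share fs and length")
    base = path[:-4] if path.endswith(".hea") else path
    name = os.path.basename(base)
    adc = np.column_stack([np.rint(r.samples * gain).astype(np.int64) for r in records])
    lim = 32767 if fmt == "16" else 2047
    if np.any(np.abs(adc) > lim):
        raise FormatError(f"signal exceeds format-{fmt} ADC range at gain {gain}")
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} {len(records)} {records[0].fs:g} {records[0].samples.size}\n")
        for ch, r in enumerate(records):
            fh.write(f"{name}.dat {fmt} {gain:g}(0)/mV 12 0 {adc[0, ch]} 0 0 {r.lead}\n")
    _write_dat(base + ".dat", adc, fmt)
    if ann is not None:
        _write_atr(base + "." + ann_ext, ann)


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------

def read_csv(path: str, time_col=None, value_col=None,
             fs_hint: float | None = None, lead: str = "ECG") -> ECGRecord:
    """Read an ECG trace from a CSV file.

    With two or more columns the first is taken as time (s) and the second
    as amplitude (mV) unless ``time_col``/``value_col`` name or index other
    columns; the sampling rate is inferred from the median time step, and
    sampling must be uniform to within 1 %.  A single-column file carries
    amplitudes only and requires ``fs_hint``.
    """
    header = _sniff_header(path)
    df = pd.read_csv(path, header=0 if header else None)
    if df.shape[0] < 2:
        raise FormatError("CSV must contain at least two rows")

    def _col(key):
        if key is None:
            return None
        if isinstance(key, str):
            if key not in df.columns:
                raise ConfigError(f"column {key!r} not in CSV header {list(df.columns)}")
            return df[key].to_numpy(dtype=float)
        return df.iloc[:, int(key)].to_numpy(dtype=float)

    if df.shape[1] >= 2 or time_col is not None:
        time = _col(time_col if time_col is not None else 0)
        values = _col(value_col if value_col is not None else 1)
        dt = np.diff(time)
        med = float(np.median(dt))
        if med <= 0:
            raise FormatError("time column must be strictly increasing")
        if np.max(np.abs(dt - med)) > 0.01 * med:
            raise FormatError("non-uniform sampling: time steps deviate by more than 1%")
        return ECGRecord(values, fs=1.0 / med, lead=lead, t0=float(time[0]))

    if fs_hint is None:
        raise ConfigError("amplitude-only CSV requires fs_hint")
    values = _col(value_col if value_col is not None else 0)
    return ECGRecord(values, fs=float(fs_hint), lead=lead)


def _sniff_header(path: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def write_csv(record: ECGRecord, path: str) -> None:
    """Write a record as a two-column ``time,amplitude`` CSV."""
    pd.DataFrame({"time": record.time, "amplitude": record.samples}).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Plain-text annotations
# ---------------------------------------------------------------------------

def write_annotations(ann: RAnnotation, path: str) -> None:
    """Write annotations as ``# fs=<Hz>`` followed by one index per line."""
    with open(path, "w") as fh:
        fh.write(f"# fs={ann.fs:g}\n")
        for idx in ann.indices:
            fh.write(f"{int(idx)}\n")


def read_annotations(path: str, fs: float | None = None) -> RAnnotation:
    """Read a plain-text annotation file written by :func:`write_annotations`."""
    indices: list[int] = []
    file_fs = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs=" in line:
                    file_fs = float(line.split("fs=")[1])
                continue
            indices.append(int(float(line)))
    fs = fs if fs is not None else file_fs
    if fs is None:
        raise FormatError(f"annotation file {path} carries no fs and none was given")
    return RAnnotation(np.asarray(indices, dtype=np.int64), fs)
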