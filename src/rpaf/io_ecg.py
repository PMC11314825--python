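"""Reading, resampling, segmenting, and splitting single-lead ECG data.

Supported containers: WFDB (.hea/.dat, formats 16 and 212, read-only),
two-column CSV (time_s, mv), and NPZ bundles {samples, fs, label}.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from rpaf.ecg import ECGSignal, HeaderError, LeadError, ParameterError

__all__ = [
    "SplitSpec",
    "read_wfdb",
    "read_csv",
    "write_csv",
    "read_npz",
    "write_npz",
    "resample",
    "segment",
    "split_dataset",
    "largest_remainder",
]


@dataclass
class SplitSpec:
    """Train/validation/test fractions and the unit they apportion."""

    train: float = 0.7
    val: float = 0.2
    test: float = 0.1
    unit: str = "record"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.val, self.test)
        if any(f <= 0 for f in fracs):
            raise ParameterError("all split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ParameterError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.unit not in ("record", "segment"):
            raise ParameterError("split unit must be 'record' or 'segment'")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train, self.val, self.test)


# ---------------------------------------------------------------- WFDB


def _parse_header(path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise HeaderError(f"empty header {path}")
    rec = lines[0].split()
    if len(rec) < 3:
        raise HeaderError(f"malformed record line in {path}: {lines[0]!r}")
    try:
        name = rec[0].split("/")[0]
        n_sig = int(rec[1])
        fs = float(rec[2].split("/")[0])
        n_samp = int(rec[3]) if len(rec) > 3 else -1
    except ValueError as exc:
        raise HeaderError(f"malformed record line in {path}: {lines[0]!r}") from exc
    if len(lines) - 1 < n_sig:
        raise HeaderError(f"header {path} declares {n_sig} signals, found {len(lines) - 1}")
    signals = []
    for ln in lines[1: 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise HeaderError(f"malformed signal line in {path}: {ln!r}")
        fmt = tok[1].split("x")[0]
        gain, baseline = 200.0, 0.0
        if len(tok) > 2:
            gspec = tok[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                gain = float(gpart)
                baseline = float(bpart.rstrip(")"))
            else:
                gain = float(gspec)
        if gain == 0:
            gain = 200.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(signals)}"
        signals.append({
            "file": tok[0], "fmt": fmt, "gain": gain,
            "baseline": baseline, "name": desc,
        })
    return name, n_sig, fs, n_samp, signals


def _read_dat(path: Path, fmt: str, n_sig: int) -> np.ndarray:
    """Decode an interleaved .dat file into an (n_samples, n_sig) int array."""
    raw = path.read_bytes()
    if fmt == "16":
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        b = b[: 3 * (b.size // 3)]
        first = b[0::3] | ((b[1::3] & 0x0F) << 8)
        second = b[2::3] | ((b[1::3] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(first.size + second.size, dtype=np.int64)
        flat[0::2] = first
        flat[1::2] = second
    else:
        raise HeaderError(f"unsupported WFDB format {fmt!r}")
    flat = flat[: n_sig * (flat.size // n_sig)]
    return flat.reshape(-1, n_sig)


def read_wfdb(record: str | Path, lead: int | str = 0) -> ECGSignal:
    """Read one channel of a WFDB record (path without extension).

    ``lead`` selects by index or by the description field of the header.
    Samples are converted to physical units via ``(adc - baseline) / gain``.
    """
    record = Path(record)
    hea = record.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    name, n_sig, fs, n_samp, signals = _parse_header(hea)
    files = {s["file"] for s in signals}
    if len(files) != 1:
        raise HeaderError("multi-file WFDB records are not supported")
    if isinstance(lead, str):
        matches = [i for i, s in enumerate(signals) if s["name"] == lead]
        if not matches:
            raise LeadError(f"lead {lead!r} not in {[s['name'] for s in signals]}")
        idx = matches[0]
    else:
        if not 0 <= lead < n_sig:
            raise LeadError(f"lead index {lead} out of range for {n_sig} signals")
        idx = lead
    sig = signals[idx]
    data = _read_dat(record.parent / sig["file"], sig["fmt"], n_sig)
    if n_samp > 0:
        data = data[:n_samp]
    mv = (data[:, idx] - sig["baseline"]) / sig["gain"]
    return ECGSignal(samples=mv, fs=fs, record_id=name, lead=sig["name"])


# ---------------------------------------------------------------- CSV / NPZ


def read_csv(path: str | Path) -> ECGSignal:
    """Read a two-column (time_s, mv) CSV; sampling rate inferred from time.

    Timestamps must be strictly increasing and uniform to within 1% of the
    median step.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ParameterError(f"{path} must have two columns (time_s, mv)")
    try:
        t = df.iloc[:, 0].to_numpy(dtype=np.float64)
        x = df.iloc[:, 1].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"non-numeric rows in {path}") from exc
    if t.size < 2:
        raise ParameterError(f"{path} has fewer than two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ParameterError(f"timestamps in {path} are not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise ParameterError(f"non-uniform sampling in {path} (>1% jitter)")
    return ECGSignal(samples=x, fs=1.0 / step, record_id=path.stem)


def write_csv(signal: ECGSignal, path: str | Path) -> None:
    t = np.arange(signal.n) / signal.fs
    pd.DataFrame({"time_s": t, "mv": signal.samples}).to_csv(Path(path), index=False)


def read_npz(path: str | Path) -> ECGSignal:
    """Read an NPZ bundle {samples, fs[, label]}."""
    with np.load(Path(path)) as z:
        label = int(z["label"]) if "label" in z else None
        return ECGSignal(samples=z["samples"], fs=float(z["fs"]),
                         record_id=Path(path).stem, label=label)


def write_npz(signal: ECGSignal, path: str | Path) -> None:
    extra = {} if signal.label is None else {"label": signal.label}
    np.savez(Path(path), samples=signal.samples, fs=signal.fs, **extra)


# ---------------------------------------------------------------- transforms


def resample(signal: ECGSignal, target_fs: float) -> ECGSignal:
    """Polyphase resampling with anti-aliasing to ``target_fs``.

    Output length is round(n * target_fs / fs); identity (bitwise) when the
    target equals the source rate.
    """
    if not target_fs > 0:
        raise ParameterError("target fs must be > 0")
    if target_fs == signal.fs:
        return signal
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(
        signal.fs).limit_denominator(10**6)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    n_out = int(round(signal.n * target_fs / signal.fs))
    if out.size > n_out:
        out = out[:n_out]
    elif out.size < n_out:
        out = np.pad(out, (0, n_out - out.size), mode="edge")
    return signal.with_samples(out, fs=target_fs)


def segment(signal: ECGSignal, window: float = 10.0,
            max_segments: int | None = None) -> list[ECGSignal]:
    """Cut into consecutive non-overlapping windows of ``window`` seconds.

    The trailing remainder shorter than one window is discarded; label and
    record id are inherited, with the segment index recorded in ``meta``.
    ``max_segments`` keeps only the first windows of a long record (useful
    to cap the per-record contribution to a dataset).
    """
    if not window > 0:
        raise ParameterError("window must be > 0")
    if max_segments is not None and max_segments < 1:
        raise ParameterError("max_segments must be >= 1")
    w = int(round(window * signal.fs))
    n_seg = signal.n // w
    if max_segments is not None:
        n_seg = min(n_seg, max_segments)
    out = []
    for k in range(n_seg):
        seg = replace(
            signal, samples=signal.samples[k * w:(k + 1) * w],
            meta={**signal.meta, "segment_index": k},
        )
        out.append(seg)
    return out


def largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion ``n`` items by largest remainder; ties favour earlier bins."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_dataset(
    segments: list[ECGSignal], spec: SplitSpec | None = None
) -> tuple[list[ECGSignal], list[ECGSignal], list[ECGSignal]]:
    """Randomly split segments into train/val/test per ``spec``.

    With ``unit='record'`` whole records are apportioned so no record id
    crosses partitions; with ``unit='segment'`` individual segments are.
    """
    spec = spec or SplitSpec()
    if not segments:
        raise ParameterError("nothing to split")
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "record":
        ids = sorted({s.record_id for s in segments})
        if len(ids) < 3:
            raise ParameterError(
                f"need at least 3 records for a record-level 3-way split, got {len(ids)}"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        counts = largest_remainder(len(ids), spec.fractions)
        assign: dict[str, int] = {}
        start = 0
        for part, c in enumerate(counts):
            for rid in perm[start:start + c]:
                assign[rid] = part
            start += c
        parts: tuple[list, list, list] = ([], [], [])
        for s in segments:
            parts[assign[s.record_id]].append(s)
        return parts
    perm = rng.permutation(len(segments))
    counts = largest_remainder(len(segments), spec.fractions)
    bounds = np.cumsum([0] + counts)
    return tuple(
        [segments[i] for i in perm[bounds[p]:bounds[p + 1]]] for p in range(3)
    )  # type: ignore[return-value]
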