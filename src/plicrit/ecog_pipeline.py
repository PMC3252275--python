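"""End-to-end sliding-window PLI analysis of a multichannel recording.

The pipeline mirrors the standard clinical-recording workflow for tracking
deviation from criticality around a seizure:

1. split the recording into overlapping windows (default 150 s, 100 s
   overlap — 30000 samples at 200 Hz, 38400 at 256 Hz);
2. per window and wavelet scale, extract phase-lock intervals pooled over
   all unordered channel pairs (intervals are cut at window boundaries);
3. fit a power law to the first window's pooled durations per scale — the
   frozen reference — and report the Delta deviation of every subsequent
   window from that reference.

A rising positive Delta flags windows with an excess of long phase-locked
intervals relative to the pre-ictal reference distribution.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import wavelet_phase as wp
from . import powerlaw_stats as pls

__all__ = [
    "MultichannelRecording",
    "WindowSpec",
    "PLIParams",
    "DeltaTimecourse",
    "load_recording",
    "make_windows",
    "window_pli",
    "delta_timecourse",
    "pli_table",
    "write_pli_tsv",
    "write_delta_tsv",
]


@dataclass
class MultichannelRecording:
    """Samples-by-channels matrix with its sampling rate and labels."""

    data: np.ndarray  # (n_samples, n_channels), float
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("recording needs a 2-D matrix with >= 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{k:02d}" for k in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowSpec:
    """Sliding-window geometry in seconds."""

    length_s: float = 150.0
    overlap_s: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.length_s:
            raise ValueError("need 0 <= overlap_s < length_s")

    @property
    def step_s(self) -> float:
        return self.length_s - self.overlap_s


@dataclass
class PLIParams:
    """Estimator configuration shared across windows and pairs."""

    scales: tuple[int, ...] = (2, 3, 4)
    lock_threshold: float = np.pi / 4
    min_coherence: float = 0.5
    avg_window: int | None = None  # None: per-scale default (2 * 2**j samples)
    min_tail: int = 10  # minimum tail points for the reference fit


@dataclass
class DeltaTimecourse:
    """Per-window, per-scale Delta against the first window's reference fit."""

    window_starts_s: np.ndarray
    scales: tuple[int, ...]
    delta: dict[int, np.ndarray]  # scale -> delta per window (NaN where unfit)
    reference: dict[int, pls.PowerLawFit]  # scale -> window-0 fit
    n_eval: dict[int, np.ndarray]  # scale -> evaluation points per window

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "window_start_s": float(t),
                "scale": j,
                "delta": float(self.delta[j][w]),
                "n_eval": int(self.n_eval[j][w]),
            }
            for j in self.scales
            for w, t in enumerate(self.window_starts_s)
        ]
        return pd.DataFrame(rows)


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def load_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    channel_labels: list[str] | None = None,
) -> MultichannelRecording:
    """Load an EDF or delimited-text recording.

    Text input is one row per sample, one column per channel, tab/comma/
    whitespace delimited; the sampling rate comes from ``fs`` or from a JSON
    sidecar ``<path>.json`` with a top-level ``"fs"`` key.  EDF input needs
    the optional ``mne`` dependency and requires a uniform sampling rate
    across channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text"
    if format == "edf":
        return _load_edf(path)
    if format != "text":
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'text')")
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    sidecar = _read_sidecar(path)
    if fs is None:
        fs = sidecar.get("fs")
    if fs is None:
        raise ValueError(
            f"sampling rate missing for text input {path}: pass fs= or provide "
            f"a JSON sidecar {path.name}.json with an 'fs' key"
        )
    with open(path) as fh:
        first = next((ln for ln in fh if ln.strip() and not ln.startswith("#")), "")
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path} as delimited text: {exc}") from exc
    data = df.to_numpy(dtype=float)
    labels = channel_labels or sidecar.get("channel_labels") or []
    return MultichannelRecording(
        data=data,
        fs=float(fs),
        channel_labels=list(labels),
        metadata=sidecar.get("metadata", {}),
    )


def _load_edf(path: Path) -> MultichannelRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne resamples mixed-rate EDF channels silently; reject such files
    orig = raw._raw_extras[0].get("n_samps") if raw._raw_extras else None
    if orig is not None:
        samps = np.asarray(orig)[: len(raw.ch_names)]
        if len(np.unique(samps)) > 1:
            bad = [raw.ch_names[i] for i in np.flatnonzero(samps != np.max(samps))]
            raise ValueError(
                f"EDF has mixed per-channel sampling rates; offending channels: {bad}"
            )
    data = raw.get_data().T  # samples x channels, volts
    meta = {"source": str(path)}
    for key in ("highpass", "lowpass"):
        if key in raw.info and raw.info[key] is not None:
            meta[key] = float(raw.info[key])  # hardware filter settings, verbatim
    return MultichannelRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        metadata=meta,
    )


def make_windows(rec: MultichannelRecording, spec: WindowSpec | None = None) -> list[tuple[int, int]]:
    """Ordered (start, stop) sample ranges of the sliding windows.

    Windows start every ``length_s - overlap_s`` seconds and hold exactly
    ``length_s * fs`` samples; a trailing partial window is discarded.
    """
    spec = spec or WindowSpec()
    win = int(round(spec.length_s * rec.fs))
    step = int(round(spec.step_s * rec.fs))
    if rec.n_samples < win:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{spec.length_s}-s window ({win} samples)"
        )
    starts = range(0, rec.n_samples - win + 1, step)
    return [(s, s + win) for s in starts]


def window_pli(
    window_data: np.ndarray,
    fs: float,
    params: PLIParams | None = None,
    window_id: int = 0,
) -> dict[int, wp.PLISet]:
    """Pooled PLI per scale over all unordered channel pairs of one window."""
    params = params or PLIParams()
    x = np.asarray(window_data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("window needs >= 2 channels")
    n_ch = x.shape[1]
    coeffs = [
        wp.hilbert_wavelet_transform(x[:, k], fs, params.scales) for k in range(n_ch)
    ]
    out: dict[int, wp.PLISet] = {}
    for j in params.scales:
        durations = []
        for a, b in itertools.combinations(range(n_ch), 2):
            pps = wp.phase_pair_series(
                coeffs[a],
                coeffs[b],
                j,
                avg_window=params.avg_window,
                min_coherence=params.min_coherence,
            )
            durations.append(wp.extract_pli(pps, params.lock_threshold).durations)
        pooled = np.concatenate(durations) if durations else np.zeros(0, np.int64)
        out[j] = wp.PLISet(
            durations=pooled,
            fs=fs,
            scale=j,
            lock_threshold=params.lock_threshold,
            min_coherence=params.min_coherence,
            pair_id="pooled",
            window_id=window_id,
        )
    return out


def delta_timecourse(
    rec: MultichannelRecording,
    spec: WindowSpec | None = None,
    params: PLIParams | None = None,
    fit_kwargs: dict | None = None,
) -> DeltaTimecourse:
    """Delta deviation per window and scale against the window-0 reference.

    The power law fitted to the first window (per scale) is frozen and
    subtracted from every window's empirical cumulative PLI distribution.
    Windows with no duration at or above the reference cutoff get NaN.
    A failed reference fit (window 0) aborts with a diagnostic.
    """
    spec = spec or WindowSpec()
    params = params or PLIParams()
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("min_tail", params.min_tail)
    fit_kwargs.setdefault("compare_alternatives", False)
    windows = make_windows(rec, spec)
    starts = np.array([s / rec.fs + rec.start_time for s, _ in windows])
    per_window = [
        window_pli(rec.data[s:e], rec.fs, params, window_id=w)
        for w, (s, e) in enumerate(windows)
    ]
    reference: dict[int, pls.PowerLawFit] = {}
    for j in params.scales:
        try:
            reference[j] = pls.fit_power_law(
                per_window[0][j].durations_seconds, **fit_kwargs
            )
        except ValueError as exc:
            raise RuntimeError(
                f"reference fit failed for window 0 at scale {j}: {exc}"
            ) from exc
    delta = {j: np.full(len(windows), np.nan) for j in params.scales}
    n_eval = {j: np.zeros(len(windows), dtype=int) for j in params.scales}
    for w, pli in enumerate(per_window):
        for j in params.scales:
            try:
                res = pls.compute_delta(pli[j].durations_seconds, reference[j])
            except ValueError:
                continue
            delta[j][w] = res.delta
            n_eval[j][w] = res.n
    return DeltaTimecourse(
        window_starts_s=starts,
        scales=tuple(params.scales),
        delta=delta,
        reference=reference,
        n_eval=n_eval,
    )


def pli_table(pli_sets: list[wp.PLISet]) -> pd.DataFrame:
    """Long-format table of PLI durations with provenance columns."""
    rows = []
    for s in pli_sets:
        for d in s.durations:
            rows.append(
                {
                    "pair_id": s.pair_id,
                    "scale": s.scale,
                    "window_id": s.window_id,
                    "duration_samples": int(d),
                    "duration_seconds": d / s.fs,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "scale", "window_id", "duration_samples", "duration_seconds"],
    )


def write_pli_tsv(pli_sets: list[wp.PLISet], path: str | Path) -> None:
    pli_table(pli_sets).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_delta_tsv(tc: DeltaTimecourse, path: str | Path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
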