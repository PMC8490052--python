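"""Preprocessing: Butterworth band-pass filtering and resampling.

Raw trials are band-pass filtered (5th-order Butterworth, 0.5-100 Hz by
default) and then brought to a 200 Hz effective sampling rate, at which
a 5-level dyadic wavelet decomposition places its detail bands exactly
on the canonical EEG rhythm boundaries (D2 25-50 gamma, D3 12.5-25
beta, D4 6.25-12.5 alpha, D5 3.125-6.25 theta).  Filtering is always
applied at the native rate, before resampling; the 100 Hz upper cutoff
doubles as the anti-aliasing guard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import TrialSet

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "apply_filter",
    "resample_to_effective",
    "read_trialset",
]

EFFECTIVE_FS = 200.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification (order, cutoffs, sampling rate)."""

    order: int = 5
    low_cut: float = 0.5
    high_cut: float = 100.0
    fs: float = 512.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= self.fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} must be below Nyquist {self.fs / 2}"
            )


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Butterworth band-pass coefficients in second-order sections.

    SOS form keeps the 5th-order band-pass numerically stable at the
    narrow normalized low cutoff (0.5 Hz at 512 Hz).
    """
    return sps.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=spec.fs,
        output="sos",
    )


def apply_filter(trials: TrialSet, spec: FilterSpec) -> TrialSet:
    """Zero-phase (forward-backward) band-pass of every channel.

    Forward-backward application squares the magnitude response and
    cancels the phase, so band timing is preserved; shape is unchanged.
    """
    if spec.fs != trials.fs:
        raise ValueError(
            f"filter designed for fs={spec.fs}, trials sampled at {trials.fs}"
        )
    sos = design_bandpass(spec)
    zi0 = sps.sosfilt_zi(sos)

    def forward_backward(x: np.ndarray) -> np.ndarray:
        # steady-state initial conditions scaled by the edge sample keep
        # the slow (0.5 Hz) modes from ringing through short trials
        y, _ = sps.sosfilt(sos, x, zi=zi0 * x[0])
        y, _ = sps.sosfilt(sos, y[::-1], zi=zi0 * y[-1])
        return y[::-1]

    flat = trials.data.reshape(-1, trials.data.shape[-1])
    filtered = np.stack([forward_backward(row) for row in flat])
    filtered = filtered.reshape(trials.data.shape)
    return TrialSet(
        data=filtered,
        labels=trials.labels.copy(),
        fs=trials.fs,
        channel_names=list(trials.channel_names),
        subject_id=trials.subject_id,
    )


def resample_to_effective(
    trials: TrialSet, target_fs: float = EFFECTIVE_FS
) -> TrialSet:
    """Polyphase resampling to the effective rate (default 200 Hz).

    Upsampling is not supported; the caller is expected to have already
    low-passed below the target Nyquist (the standard band-pass at
    100 Hz does exactly that for the 512 -> 200 Hz path).
    """
    if target_fs > trials.fs:
        raise ValueError(
            f"target_fs {target_fs} exceeds trial rate {trials.fs}; "
            "upsampling is not supported"
        )
    if target_fs == trials.fs:
        return TrialSet(
            data=trials.data.copy(),
            labels=trials.labels.copy(),
            fs=trials.fs,
            channel_names=list(trials.channel_names),
            subject_id=trials.subject_id,
        )
    ratio = Fraction(target_fs / trials.fs).limit_denominator(1000)
    data = sps.resample_poly(trials.data, ratio.numerator, ratio.denominator, axis=-1)
    return TrialSet(
        data=data,
        labels=trials.labels.copy(),
        fs=target_fs,
        channel_names=list(trials.channel_names),
        subject_id=trials.subject_id,
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_trialset(path: str | Path, format: str | None = None) -> TrialSet:
    """Read a TrialSet from a serialized directory layout.

    ``format`` is ``"csv-dir"`` or ``"edf"``; if omitted it is taken
    from the directory's metadata.json.  Both layouts hold one file per
    trial plus a metadata sidecar (see :func:`mipower.synthetic.write_trialset`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trial directory: {path}")
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    if format is None:
        format = {"csv": "csv-dir", "edf": "edf"}[meta.get("format", "csv")]
    if format not in ("csv-dir", "edf"):
        raise ValueError(f"unknown format {format!r}; use 'csv-dir' or 'edf'")

    n_trials = int(meta["n_trials"])
    channel_names = list(meta["channel_names"])
    fs = float(meta["fs"])
    ext = "csv" if format == "csv-dir" else "edf"
    trials = []
    for i in range(n_trials):
        fname = path / f"trial_{i:04d}.{ext}"
        if not fname.exists():
            raise FileNotFoundError(f"missing trial file: {fname}")
        if format == "csv-dir":
            df = pd.read_csv(fname, float_precision="round_trip")
            if list(df.columns) != channel_names:
                raise ValueError(
                    f"{fname.name}: channels {list(df.columns)} do not match "
                    f"metadata {channel_names}"
                )
            trials.append(df.to_numpy().T)
        else:
            data, file_fs, names = _read_edf(fname)
            if abs(file_fs - fs) > 1e-6:
                raise ValueError(
                    f"{fname.name}: fs {file_fs} inconsistent with metadata {fs}"
                )
            if names != channel_names:
                raise ValueError(
                    f"{fname.name}: channels {names} do not match metadata"
                )
            trials.append(data)
    shapes = {t.shape for t in trials}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent trial shapes across files: {shapes}")
    return TrialSet(
        data=np.stack(trials),
        labels=np.asarray(meta["labels"]),
        fs=fs,
        channel_names=channel_names,
        subject_id=meta.get("subject_id", ""),
    )


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    """Read one EDF file via MNE; returns (channels x samples in uV, fs, names)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an extra
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install mipower[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; trials are stored in uV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
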