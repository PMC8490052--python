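"""Wavelet sub-band decomposition and the 11-dimensional power feature set.

Each preprocessed trial is decomposed with a 5-level db4 discrete
wavelet transform.  At the 200 Hz effective rate the detail levels
cover dyadic bands that coincide with the canonical EEG rhythms:

    D1  50-100 Hz   broadband noise, discarded
    D2  25-50  Hz   gamma
    D3  12.5-25 Hz  beta
    D4  6.25-12.5   alpha
    D5  3.125-6.25  theta
    A5  0-3.125     delta, discarded

The band signals are reconstructed in the time domain (inverse DWT with
all other coefficient sets zeroed), their Welch power spectral
densities are estimated, and three families of scalar features are
formed per trial: average in-band power for alpha/beta/gamma/theta,
the relative power of alpha to each other band (the ERD/ERS-motivated
ratio features), and the variance of the PSD across in-band frequency
bins ("varied power").  Band powers are averaged across channels before
the ratios are taken, yielding exactly 11 features per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .synthetic import TrialSet

__all__ = [
    "FEATURE_NAMES",
    "RELATIVE_FEATURE_INDICES",
    "BAND_LEVELS",
    "SubbandCoeffs",
    "PSDEstimate",
    "FeatureMatrix",
    "dwt_decompose",
    "band_edges",
    "reconstruct_component",
    "reconstruct_band",
    "welch_psd",
    "average_power",
    "variance_power",
    "extract_features",
    "extract_matrix",
]

#: Canonical feature order; 1-based indices 1..11 are used throughout the
#: ranking and ablation stages.
FEATURE_NAMES: tuple[str, ...] = (
    "avg_alpha",      # 1
    "avg_beta",       # 2
    "avg_gamma",      # 3
    "avg_theta",      # 4
    "rel_alpha_beta",   # 5
    "rel_alpha_gamma",  # 6
    "rel_alpha_theta",  # 7
    "var_alpha",      # 8
    "var_beta",       # 9
    "var_gamma",      # 10
    "var_theta",      # 11
)

#: 1-based indices of the relative-power features.
RELATIVE_FEATURE_INDICES: tuple[int, ...] = (5, 6, 7)

#: Rhythm -> DWT detail level at the 200 Hz effective rate.
BAND_LEVELS: dict[str, int] = {"gamma": 2, "beta": 3, "alpha": 4, "theta": 5}

_EPS_POWER = 1e-12  # uV^2/Hz floor guarding the relative-power ratios

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 5


@dataclass
class SubbandCoeffs:
    """DWT coefficient sets of one single-channel signal.

    ``coeffs`` is in PyWavelets order [A_L, D_L, ..., D_1].
    """

    coeffs: list[np.ndarray]
    wavelet: str
    levels: int
    n_samples: int

    @property
    def approximation(self) -> np.ndarray:
        return self.coeffs[0]

    def detail(self, level: int) -> np.ndarray:
        if not 1 <= level <= self.levels:
            raise ValueError(f"detail level must be in 1..{self.levels}")
        return self.coeffs[self.levels - level + 1]


@dataclass
class PSDEstimate:
    """One-sided Welch power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    density: np.ndarray
    welch_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.density < -1e-30):
            raise ValueError("spectral density must be nonnegative")


@dataclass
class FeatureMatrix:
    """Trials x 11 feature table with aligned class labels."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        if list(self.features.columns) != list(FEATURE_NAMES):
            raise ValueError("feature columns must be the canonical 11 names")
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align with feature rows")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def values(self) -> np.ndarray:
        return self.features.to_numpy()

    def __len__(self) -> int:
        return len(self.features)

    def select(self, indices: list[int] | tuple[int, ...]) -> "FeatureMatrix":
        """Column subset by canonical 1-based indices (order preserved)."""
        names = [FEATURE_NAMES[i - 1] for i in indices]
        sub = self.features[names].copy()
        # relax the canonical-column check by constructing directly
        fm = object.__new__(FeatureMatrix)
        fm.features = sub
        fm.labels = self.labels
        return fm

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "label", self.labels)
        out.insert(0, "trial_id", np.arange(len(out)))
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df["label"].to_numpy()
        return cls(features=df[list(FEATURE_NAMES)].copy(), labels=labels)


def min_signal_length(wavelet: str = DEFAULT_WAVELET, levels: int = DEFAULT_LEVELS) -> int:
    """Shortest signal for which a ``levels``-deep decomposition is meaningful."""
    filt_len = pywt.Wavelet(wavelet).dec_len
    return (filt_len - 1) * 2**levels


def dwt_decompose(
    signal: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> SubbandCoeffs:
    """Multilevel DWT of a single-channel signal.

    Returns ``levels`` detail coefficient sets plus one approximation
    set, each roughly halving in length per level.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("dwt_decompose expects a 1-D signal")
    min_len = min_signal_length(wavelet, levels)
    if len(signal) < min_len:
        raise ValueError(
            f"signal of {len(signal)} samples is too short for a "
            f"{levels}-level {wavelet} decomposition; need >= {min_len}"
        )
    coeffs = pywt.wavedec(signal, wavelet, level=levels)
    return SubbandCoeffs(
        coeffs=coeffs, wavelet=wavelet, levels=levels, n_samples=len(signal)
    )


def band_edges(level: int | str, fs: float, levels: int = DEFAULT_LEVELS) -> tuple[float, float]:
    """Nominal dyadic frequency band of a detail level (or the approximation).

    Detail level ``j`` covers (fs/2^(j+1), fs/2^j); the approximation
    covers (0, fs/2^(levels+1)).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if isinstance(level, str):
        if level not in ("A", "approx", "approximation"):
            raise ValueError(f"unknown level {level!r}")
        return 0.0, fs / 2 ** (levels + 1)
    if not 1 <= level <= levels:
        raise ValueError(f"detail level must be in 1..{levels}, got {level}")
    return fs / 2 ** (level + 1), fs / 2**level


def reconstruct_component(coeffs: SubbandCoeffs, component: str) -> np.ndarray:
    """Time-domain reconstruction of one component ("D1".."D5" or "A5").

    Inverse transform with every other coefficient set zeroed; output
    length equals the original signal length.
    """
    L = coeffs.levels
    valid = [f"D{j}" for j in range(1, L + 1)] + [f"A{L}"]
    if component not in valid:
        raise ValueError(f"unknown component {component!r}; valid: {valid}")
    kept = [np.zeros_like(c) for c in coeffs.coeffs]
    if component == f"A{L}":
        kept[0] = coeffs.coeffs[0]
    else:
        j = int(component[1:])
        kept[L - j + 1] = coeffs.coeffs[L - j + 1]
    rec = pywt.waverec(kept, coeffs.wavelet)
    return rec[: coeffs.n_samples]


def reconstruct_band(coeffs: SubbandCoeffs, band: str) -> np.ndarray:
    """Reconstruction of one named rhythm (gamma/beta/alpha/theta)."""
    if band not in BAND_LEVELS:
        raise ValueError(
            f"unknown band {band!r}; valid bands: {sorted(BAND_LEVELS)}"
        )
    return reconstruct_component(coeffs, f"D{BAND_LEVELS[band]}")


def welch_psd(
    signal: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PSDEstimate:
    """Welch PSD with defaults emulating MATLAB's pwelch.

    pwelch splits the signal into 8 segments with 50% overlap and a
    Hamming window; with 50% overlap that means a segment length of
    floor(n / 4.5).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot estimate the PSD of an empty signal")
    if nperseg is None:
        nperseg = max(int(len(signal) / 4.5), 8)
    nperseg = min(nperseg, len(signal))
    noverlap = int(nperseg * overlap)
    freqs, density = sps.welch(
        signal,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    return PSDEstimate(
        frequencies=freqs,
        density=density,
        welch_params={
            "nperseg": nperseg,
            "overlap": overlap,
            "window": window,
        },
    )


def _band_mask(psd: PSDEstimate, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    nyq = psd.frequencies[-1]
    if not 0 <= low < high or high > nyq + 1e-9:
        raise ValueError(f"band {band} outside [0, {nyq}] or empty")
    return (psd.frequencies >= low) & (psd.frequencies < high)


def average_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Mean PSD value over in-band frequency bins (low <= f < high)."""
    mask = _band_mask(psd, band)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency grid points")
    return float(psd.density[mask].mean())


def variance_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Sample variance (ddof=1) of PSD values across in-band bins."""
    mask = _band_mask(psd, band)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band} needs >= 2 frequency grid points for a variance"
        )
    return float(psd.density[mask].var(ddof=1))


def extract_features(
    trial: np.ndarray,
    fs: float,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    nperseg: int | None = None,
) -> pd.Series:
    """The canonical 11-feature vector of one preprocessed trial.

    Per channel: decompose, reconstruct each rhythm, estimate its Welch
    PSD, and take the average and variance of the in-band density.  The
    eight avg/var quantities are averaged across channels, then the
    three alpha-relative ratios are formed from the channel-averaged
    band powers.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    avg = {b: [] for b in BAND_LEVELS}
    var = {b: [] for b in BAND_LEVELS}
    for channel in trial:
        coeffs = dwt_decompose(channel, wavelet, levels)
        for band, level in BAND_LEVELS.items():
            rec = reconstruct_band(coeffs, band)
            psd = welch_psd(rec, fs, nperseg=nperseg)
            edges = band_edges(level, fs, levels)
            avg[band].append(average_power(psd, edges))
            var[band].append(variance_power(psd, edges))
    mean_avg = {b: float(np.mean(v)) for b, v in avg.items()}
    mean_var = {b: float(np.mean(v)) for b, v in var.items()}

    def ratio(num: float, den: float, name: str) -> float:
        if den < _EPS_POWER:
            warnings.warn(
                f"near-zero denominator in {name}; using epsilon guard",
                RuntimeWarning,
                stacklevel=2,
            )
            den = max(den, _EPS_POWER)
        return num / den

    values = [
        mean_avg["alpha"],
        mean_avg["beta"],
        mean_avg["gamma"],
        mean_avg["theta"],
        ratio(mean_avg["alpha"], mean_avg["beta"], "rel_alpha_beta"),
        ratio(mean_avg["alpha"], mean_avg["gamma"], "rel_alpha_gamma"),
        ratio(mean_avg["alpha"], mean_avg["theta"], "rel_alpha_theta"),
        mean_var["alpha"],
        mean_var["beta"],
        mean_var["gamma"],
        mean_var["theta"],
    ]
    return pd.Series(values, index=list(FEATURE_NAMES))


def extract_matrix(trials: TrialSet, **kwargs) -> FeatureMatrix:
    """Feature vectors for every trial, rows aligned with the labels."""
    rows = []
    for i, (trial, _) in enumerate(trials):
        try:
            rows.append(extract_features(trial, trials.fs, **kwargs))
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed on trial {i}") from exc
    features = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureMatrix(features=features, labels=trials.labels.copy())
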