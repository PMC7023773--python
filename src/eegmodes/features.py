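"""Time-domain, spectral and nonlinear feature banks.

Features are computed per component (a selected IMF, a wavelet subband's
coefficient vector, or the raw segment) and assembled component-major into
a labelled feature table:

* time group (4): energy, mean, skewness, kurtosis (population moments);
* spectral group (5): total power, 1st–3rd spectral moments, and spectral
  entropy, all on the full two-sided periodogram grid omega_k = 2*pi*k/N,
  k = 0..N-1;
* nonlinear group (2): rescaled-range (R/S) Hurst exponent and Higuchi
  fractal dimension.

The two-sided grid means a pure real tone carries equal power in bins k0
and N-k0, so its spectral entropy is exactly 1 bit; total power equals the
time-domain energy (Parseval), which ties the two groups together and is
asserted in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

from .decompose import IMFSet, SiftConfig, SubbandSet, dwt_subbands, emd, eemd
from .synthetic import EEGEpoch

__all__ = [
    "Spectrum",
    "TimeFeatures",
    "SpectralFeatures",
    "FeatureTable",
    "time_features",
    "periodogram",
    "spectral_features",
    "hurst_exponent",
    "higuchi_fd",
    "build_feature_table",
    "FEATURE_GROUPS",
]

logger = logging.getLogger(__name__)

FEATURE_GROUPS = {
    "time": ("energy", "mean", "skewness", "kurtosis"),
    "spectral": ("total_power", "moment1", "moment2", "moment3", "entropy"),
    "nonlinear": ("hurst", "higuchi_fd"),
}


class TimeFeatures(NamedTuple):
    energy: float
    mean: float
    skewness: float
    kurtosis: float


class SpectralFeatures(NamedTuple):
    total_power: float
    moment1: float
    moment2: float
    moment3: float
    entropy: float


@dataclass
class Spectrum:
    """Two-sided periodogram on the DFT grid."""

    power: np.ndarray  # S(omega_k) = |X(omega_k)|^2 / N, k = 0..N-1
    omega: np.ndarray  # 2*pi*k/N, radians per sample

    @property
    def total(self) -> float:
        return float(np.sum(self.power))


def time_features(x: np.ndarray) -> TimeFeatures:
    """Energy, mean, skewness and kurtosis with divisor-N moments.

    Skewness is m3 / m2^(3/2) and kurtosis m4 / m2^2 (not excess), where
    m_j are central moments with divisor N.  A zero-variance series has
    undefined shape statistics; NaN sentinels are returned for them.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    energy = float(np.sum(x * x))
    mu = float(np.mean(x))
    centered = x - mu
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return TimeFeatures(energy, mu, np.nan, np.nan)
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return TimeFeatures(energy, mu, m3 / m2**1.5, m4 / m2**2)


def periodogram(x: np.ndarray) -> Spectrum:
    """Rectangular-window periodogram on the full N-point DFT grid."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    n = x.size
    transform = np.fft.fft(x)
    power = np.abs(transform) ** 2 / n
    omega = 2.0 * np.pi * np.arange(n) / n
    return Spectrum(power=power, omega=omega)


def spectral_features(x: np.ndarray) -> SpectralFeatures:
    """Total power, spectral moments M1–M3, and spectral entropy (bits).

    M_j = sum_k omega_k^j S(omega_k); entropy is Shannon entropy of the
    normalized power distribution P = S / S_T with 0*log(0) := 0.  An
    all-zero series has no spectral distribution: NaN sentinels.
    """
    spec = periodogram(x)
    total = spec.total
    if total <= 0.0:
        return SpectralFeatures(0.0, np.nan, np.nan, np.nan, np.nan)
    moments = [float(np.sum(spec.omega**j * spec.power)) for j in (1, 2, 3)]
    p = spec.power / total
    nonzero = p > 0
    entropy = float(-np.sum(p[nonzero] * np.log2(p[nonzero])))
    return SpectralFeatures(total, *moments, entropy)


def hurst_exponent(
    x: np.ndarray, min_window: int = 8, n_scales: int = 10
) -> float:
    """Rescaled-range (R/S) Hurst exponent.

    At each of ~``n_scales`` logarithmically spaced window sizes
    m in [min_window, N/2] the series is cut into non-overlapping windows;
    in each window the range R of the cumulative deviations from the
    window mean is divided by the window standard deviation S (divisor m),
    and R/S is averaged over windows.  The estimate is the least-squares
    slope of ln(mean R/S) against ln(m).

    HE = 0.5 for an uncorrelated series, above 0.5 for persistent
    (long-range correlated) series, below for anti-persistent ones.
    Zero-variance windows are skipped; with fewer than 3 usable scales the
    estimate is undefined and NaN is returned.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for R/S analysis")
    n = x.size
    sizes = np.unique(
        np.round(
            np.logspace(np.log10(min_window), np.log10(n // 2), n_scales)
        ).astype(int)
    )
    log_m: List[float] = []
    log_rs: List[float] = []
    for m in sizes:
        n_windows = n // m
        windows = x[: n_windows * m].reshape(n_windows, m)
        mu = windows.mean(axis=1, keepdims=True)
        deviations = np.cumsum(windows - mu, axis=1)
        r = deviations.max(axis=1) - deviations.min(axis=1)
        s = windows.std(axis=1)
        usable = s > 0
        if not np.any(usable):
            continue
        mean_rs = float(np.mean(r[usable] / s[usable]))
        if mean_rs <= 0:
            continue
        log_m.append(np.log(m))
        log_rs.append(np.log(mean_rs))
    if len(log_m) < 3:
        return np.nan
    slope = np.polyfit(log_m, log_rs, 1)[0]
    return float(slope)


def higuchi_fd(x: np.ndarray, k_max: int = 30) -> float:
    """Higuchi fractal dimension of a time series.

    For each delay k = 1..k_max and offset m = 1..k the curve length of
    the decimated subseries X[m], X[m+k], ... is computed with the
    standard (N-1)/(int((N-m)/k) * k^2) normalization; the lengths are
    averaged over offsets and the dimension is the least-squares slope of
    ln L[k] versus ln(1/k).

    Roughly 1 for a smooth curve, 1.5 for Brownian paths, 2 for
    uncorrelated noise.  ``k_max`` defaults to 30, the saturation point
    for minute-long 100 Hz EEG segments.
    """
    x = np.asarray(x, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = x.size
    if n <= 2 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max}")
    log_inv_k = np.empty(k_max)
    log_len = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = np.empty(k)
        for m in range(1, k + 1):
            n_steps = (n - m) // k
            idx = m - 1 + np.arange(n_steps + 1) * k
            dist = np.sum(np.abs(np.diff(x[idx])))
            lengths[m - 1] = dist * (n - 1) / (n_steps * k) / k
        log_inv_k[k - 1] = np.log(1.0 / k)
        log_len[k - 1] = np.log(np.mean(lengths))
    slope = np.polyfit(log_inv_k, log_len, 1)[0]
    return float(slope)


_GROUP_FUNCS = {
    "time": lambda x: tuple(time_features(x)),
    "spectral": lambda x: tuple(spectral_features(x)),
    "nonlinear": lambda x: (hurst_exponent(x), higuchi_fd(x)),
}


@dataclass
class FeatureTable:
    """Segments x features matrix with provenance and labels."""

    values: np.ndarray
    feature_names: List[str]
    labels: np.ndarray  # class label per row
    row_meta: pd.DataFrame  # subject, channel, epoch label per row
    dropped_rows: int = 0

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return pd.concat([self.row_meta.reset_index(drop=True), df], axis=1)


def _segment_components(
    segment: EEGEpoch,
    components: str,
    selected_imfs: Sequence[int],
    decomposer: str,
    sift_config: SiftConfig | None,
    imf_set: IMFSet | None,
) -> List[Tuple[str, np.ndarray]]:
    x = segment.data[0]
    if components == "raw":
        return [("raw", x)]
    if components == "dwt":
        return dwt_subbands(x).components()
    if components == "imf":
        if imf_set is None:
            decompose = emd if decomposer == "emd" else eemd
            imf_set = decompose(x, sift_config)
        out = []
        for i in selected_imfs:
            if i < 1 or i > len(imf_set):
                raise ValueError(
                    f"segment {segment.subject_id}/{segment.channel_names[0]} "
                    f"has {len(imf_set)} IMFs, cannot select IMF{i}"
                )
            out.append((f"IMF{i}", imf_set.imfs[i - 1]))
        return out
    raise ValueError(f"unknown component set {components!r}")


def build_feature_table(
    segments: Iterable[EEGEpoch],
    components: str = "raw",
    groups: Sequence[str] = ("time",),
    *,
    selected_imfs: Sequence[int] = (1, 3, 2),
    decomposer: str = "emd",
    sift_config: SiftConfig | None = None,
    imf_sets: Sequence[IMFSet] | None = None,
) -> FeatureTable:
    """Assemble the labelled feature table for a list of segments.

    ``components`` selects what the features are computed on: the raw
    segment, the four db4 subband coefficient vectors, or the selected
    IMFs (1-based indices, in selection-priority order).  Columns are
    ordered component-major, feature-minor within each group, groups
    concatenated in the order given.  Rows containing non-finite features
    (zero-variance components) are dropped with a logged count.

    Precomputed decompositions can be passed via ``imf_sets`` (aligned
    with ``segments``) to avoid re-sifting.
    """
    groups = tuple(groups)
    for g in groups:
        if g not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {g!r}")
    seg_list = list(segments)
    rows: List[List[float]] = []
    names: List[str] | None = None
    labels: List[str] = []
    meta: List[dict] = []
    for i, segment in enumerate(seg_list):
        if segment.n_channels != 1:
            raise ValueError("feature tables are built from single-channel segments")
        comps = _segment_components(
            segment,
            components,
            selected_imfs,
            decomposer,
            sift_config,
            imf_sets[i] if imf_sets is not None else None,
        )
        row: List[float] = []
        row_names: List[str] = []
        for group in groups:
            for comp_name, series in comps:
                vals = _GROUP_FUNCS[group](series)
                row.extend(vals)
                row_names.extend(f"{comp_name}_{f}" for f in FEATURE_GROUPS[group])
        if names is None:
            names = row_names
        rows.append(row)
        labels.append(segment.label)
        meta.append(
            {
                "subject": segment.subject_id,
                "channel": segment.channel_names[0],
                "epoch": segment.label,
            }
        )
    values = np.asarray(rows, dtype=float)
    labels_arr = np.asarray(labels)
    meta_df = pd.DataFrame(meta)
    finite = np.all(np.isfinite(values), axis=1) if values.size else np.array([], bool)
    dropped = int(np.sum(~finite))
    if dropped:
        logger.warning("dropping %d segment rows with undefined features", dropped)
        values = values[finite]
        labels_arr = labels_arr[finite]
        meta_df = meta_df.loc[finite].reset_index(drop=True)
    return FeatureTable(
        values=values,
        feature_names=names or [],
        labels=labels_arr,
        row_meta=meta_df,
        dropped_rows=dropped,
    )
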