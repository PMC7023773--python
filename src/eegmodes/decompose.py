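"""Empirical mode decomposition, its noise-assisted ensemble variant, and
the db4 discrete-wavelet baseline.

EMD adaptively splits a nonstationary signal into intrinsic mode functions
(IMFs): zero-mean oscillations whose extrema and zero-crossing counts
differ by at most one.  Each IMF is obtained by *sifting* — repeatedly
subtracting the mean of the cubic-spline envelopes through the maxima and
minima — and extraction stops when the residue is monotone or has fewer
than two extrema of either kind.  EEMD mitigates mode mixing by averaging
the IMFs of many independently noise-perturbed copies of the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftConfig",
    "IMFSet",
    "SubbandSet",
    "InsufficientExtremaError",
    "find_extrema",
    "envelope_mean",
    "num_zero_crossings",
    "emd",
    "eemd",
    "dwt_subbands",
]


class InsufficientExtremaError(ValueError):
    """Raised when a series has too few extrema to build both envelopes.

    During sifting this signals the natural stop condition, not a failure.
    """


@dataclass
class SiftConfig:
    """Sifting and ensemble parameters.

    ``sd_threshold`` is the Cauchy stopping criterion
    SD = sum((h_prev - h)^2) / sum(h_prev^2) evaluated between consecutive
    sifting iterates; sifting for one IMF stops once SD < threshold and the
    iterate satisfies the IMF oscillation condition, or after
    ``max_sift_iterations`` passes.  ``noise_fraction`` is the standard
    deviation of the EEMD perturbation noise as a fraction of the signal's
    standard deviation.
    """

    max_imfs: int = 16
    max_sift_iterations: int = 10
    sd_threshold: float = 0.2
    ensemble_size: int = 100
    noise_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_imfs < 1 or self.max_sift_iterations < 1 or self.ensemble_size < 1:
            raise ValueError("counts must be >= 1")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.noise_fraction <= 0:
            raise ValueError("noise_fraction must be positive")


@dataclass
class IMFSet:
    """Ordered IMFs plus residue from decomposing one signal.

    For plain EMD, ``sum(imfs) + residue`` reconstructs the input exactly
    up to floating-point error.  For EEMD the residue is defined as
    ``x - sum(averaged IMFs)``; ``ensemble_residue`` additionally stores the
    ensemble mean of the member residues, so that
    ``sum(imfs) + ensemble_residue`` differs from ``x`` only by the
    averaged perturbation noise (which shrinks like 1/sqrt(ensemble)).
    """

    imfs: List[np.ndarray]
    residue: np.ndarray
    source_length: int
    ensemble_residue: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        total = self.residue.copy()
        for imf in self.imfs:
            total = total + imf
        return total

    def as_matrix(self) -> np.ndarray:
        """IMFs and residue stacked as columns (residue last)."""
        return np.column_stack(self.imfs + [self.residue])


@dataclass
class SubbandSet:
    """db4 3-level wavelet subbands: detail coefficients D1–D3 and the
    level-3 approximation A3, kept as coefficient vectors."""

    details: List[np.ndarray]  # [D1, D2, D3], finest first
    approximation: np.ndarray
    wavelet_name: str = "db4"
    mode: str = "periodization"
    source_length: int = 0

    def components(self) -> List[Tuple[str, np.ndarray]]:
        """Named components in fixed order A3, D1, D2, D3."""
        out = [("A3", self.approximation)]
        out += [(f"D{i + 1}", d) for i, d in enumerate(self.details)]
        return out

    def reconstruct(self) -> np.ndarray:
        coeffs = [self.approximation] + list(self.details[::-1])
        rec = pywt.waverec(coeffs, self.wavelet_name, mode=self.mode)
        return rec[: self.source_length]


def find_extrema(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Plateaus (runs of equal consecutive samples flanked by opposite slopes)
    contribute a single extremum at the plateau midpoint.  Endpoints are
    never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("series must have at least 3 samples")
    d = np.diff(x)
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    change = np.nonzero(s[:-1] != s[1:])[0]
    if change.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    left = nz[change]       # last index before the (possibly flat) turning run
    right = nz[change + 1]  # index whose diff leaves the run
    pos = (left + 1 + right) // 2
    is_max = s[change] > 0
    return pos[is_max], pos[~is_max]


def num_zero_crossings(x: np.ndarray) -> int:
    """Count of sign changes between consecutive samples."""
    return int(np.sum(np.abs(np.diff(np.signbit(np.asarray(x))))))


def _extend_mirrored(pos: np.ndarray, val: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    # Mirror the two extrema nearest each edge across the signal boundary.
    k = min(2, pos.size)
    left_pos = 2 * 0 - pos[:k][::-1]
    right_pos = 2 * (n - 1) - pos[-k:][::-1]
    ext_pos = np.concatenate([left_pos, pos, right_pos])
    ext_val = np.concatenate([val[:k][::-1], val, val[-k:][::-1]])
    ext_pos, unique_idx = np.unique(ext_pos, return_index=True)
    return ext_pos, ext_val[unique_idx]


def envelope_mean(
    x: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> np.ndarray:
    """Pointwise mean of the upper and lower natural-cubic-spline envelopes.

    The upper envelope interpolates the maxima, the lower the minima, each
    extended beyond the edges by mirroring the two nearest extrema to tame
    end swings.
    """
    x = np.asarray(x, dtype=float)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 maxima and minima, got {maxima.size} and {minima.size}"
        )
    n = x.size
    grid = np.arange(n)

    def _envelope(pos: np.ndarray) -> np.ndarray:
        p, v = _extend_mirrored(pos, x[pos], n)
        return CubicSpline(p, v, bc_type="natural")(grid)

    return 0.5 * (_envelope(maxima) + _envelope(minima))


def _is_imf(h: np.ndarray) -> bool:
    mx, mn = find_extrema(h)
    return abs((mx.size + mn.size) - num_zero_crossings(h)) <= 1


def _sift_one(residue: np.ndarray, config: SiftConfig) -> np.ndarray | None:
    """Extract a single IMF from ``residue``; None when no IMF remains."""
    mx, mn = find_extrema(residue)
    if mx.size < 2 or mn.size < 2:
        return None
    h = residue.copy()
    for _ in range(config.max_sift_iterations):
        mx, mn = find_extrema(h)
        if mx.size < 2 or mn.size < 2:
            break
        mean_env = envelope_mean(h, mx, mn)
        h_next = h - mean_env
        denom = np.sum(h * h)
        sd = np.sum(mean_env * mean_env) / denom if denom > 0 else 0.0
        h = h_next
        if sd < config.sd_threshold and _is_imf(h):
            break
    return h


def emd(x: np.ndarray, config: SiftConfig | None = None) -> IMFSet:
    """Decompose a signal into IMFs by sifting.

    Extraction stops when the residue is monotone / has fewer than two
    extrema of either kind, or when ``config.max_imfs`` is reached.  The
    decomposition is strictly additive: the residue is whatever remains of
    the input after subtracting every IMF, so reconstruction is exact.
    """
    if config is None:
        config = SiftConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a one-dimensional series")
    if x.size < 4:
        raise ValueError("series too short to decompose")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    residue = x.copy()
    imfs: List[np.ndarray] = []
    for _ in range(config.max_imfs):
        imf = _sift_one(residue, config)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, source_length=x.size)


def eemd(x: np.ndarray, config: SiftConfig | None = None) -> IMFSet:
    """Ensemble EMD: average the IMFs of noise-perturbed copies of ``x``.

    Each ensemble member adds fresh Gaussian white noise with standard
    deviation ``noise_fraction * std(x)``, is decomposed by :func:`emd`,
    and the member IMF lists are padded with zero series to the maximum
    count before index-wise averaging.  Fully reproducible from
    ``config.seed``.
    """
    if config is None:
        config = SiftConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("eemd expects a one-dimensional series")
    noise_sd = config.noise_fraction * x.std()
    ss = np.random.SeedSequence([config.seed, x.size])
    children = ss.spawn(config.ensemble_size)
    member_imfs: List[List[np.ndarray]] = []
    residue_sum = np.zeros_like(x)
    for child in children:
        rng = np.random.default_rng(child)
        perturbed = x + noise_sd * rng.standard_normal(x.size)
        result = emd(perturbed, config)
        member_imfs.append(result.imfs)
        residue_sum += result.residue
    n_modes = max((len(m) for m in member_imfs), default=0)
    averaged: List[np.ndarray] = []
    for k in range(n_modes):
        acc = np.zeros_like(x)
        for member in member_imfs:
            if k < len(member):
                acc += member[k]
        averaged.append(acc / config.ensemble_size)
    ensemble_residue = residue_sum / config.ensemble_size
    residue = x - np.sum(averaged, axis=0) if averaged else x.copy()
    return IMFSet(
        imfs=averaged,
        residue=residue,
        source_length=x.size,
        ensemble_residue=ensemble_residue,
    )


def dwt_subbands(x: np.ndarray, wavelet: str = "db4", level: int = 3) -> SubbandSet:
    """3-level db4 discrete wavelet decomposition into A3, D3, D2, D1.

    Uses periodized boundary handling so the transform is exactly
    orthonormal: coefficient energies sum to the signal energy and the
    inverse transform is a perfect reconstruction.
    """
    x = np.asarray(x, dtype=float)
    min_len = 2**level
    if x.size < min_len:
        raise ValueError(f"series of length {x.size} too short for {level} levels")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    approximation, *details_coarse_to_fine = coeffs
    details = details_coarse_to_fine[::-1]  # [D1, D2, D3]
    return SubbandSet(
        details=details,
        approximation=approximation,
        wavelet_name=wavelet,
        mode="periodization",
        source_length=x.size,
    )
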