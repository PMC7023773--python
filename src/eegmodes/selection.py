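"""Hybrid IMF selection: four per-IMF ranking metrics, the stacked
ranking matrix, and histogram consensus over first-priority choices.

A decomposition yields more modes than are worth featurizing, and which
modes carry the class information is signal-dependent.  Four criteria are
used to rank the IMFs of every segment:

* energy (descending) — high-energy modes dominate the signal;
* Pearson correlation with the original signal (descending);
* a log power-spectral-density distance (ascending) — modes whose
  spectrum is close to the signal's are good representatives;
* one-sample t-test p-value of the zero-mean hypothesis (descending) —
  IMFs are nominally zero-mean oscillations, so a high p-value indicates
  a well-behaved mode.

The four orderings for every (subject, epoch, channel) are stacked into a
ranking matrix (rows padded with sentinel 0 to a common width); the
consensus is the histogram of the matrix's first column, and the top-k
most frequent first-priority indices are selected.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import IMFSet, SiftConfig, emd, eemd
from .features import periodogram
from .synthetic import EEGEpoch

__all__ = [
    "METRICS",
    "Ranking",
    "RankingMatrix",
    "SelectionResult",
    "imf_energy",
    "imf_correlation",
    "psd_distance",
    "imf_pvalue",
    "rank_components",
    "rank_imfs",
    "build_ranking_matrix",
    "consensus_select",
]

#: Metric row order within each segment block of the ranking matrix.
METRICS = ("energy", "correlation", "psd_distance", "p_value")

#: Sentinel for padded ranking-matrix cells (no such IMF).
SENTINEL = 0


def imf_energy(imf: np.ndarray) -> float:
    """Signal energy sum(|imf[n]|^2)."""
    imf = np.asarray(imf, dtype=float)
    return float(np.sum(imf * imf))


def imf_correlation(x: np.ndarray, imf: np.ndarray) -> float:
    """Pearson correlation between the original signal and one IMF.

    Returns NaN (ranked last) with a warning if either series has zero
    standard deviation.
    """
    x = np.asarray(x, dtype=float)
    imf = np.asarray(imf, dtype=float)
    if x.shape != imf.shape:
        raise ValueError("signal and IMF must have equal length")
    sx, si = x.std(), imf.std()
    if sx == 0.0 or si == 0.0:
        warnings.warn("zero-variance series in correlation; returning NaN sentinel")
        return np.nan
    return float(np.mean((x - x.mean()) * (imf - imf.mean())) / (sx * si))


def psd_distance(
    x: np.ndarray, imf: np.ndarray, *, symmetric_kld: bool = False
) -> float:
    """Log-ratio distance between the periodograms of signal and IMF.

    The default form is the plain sum over all DFT bins of
    ln(S_x(omega_k) / S_imf(omega_k)), with both spectra floored at
    1e-12 times the larger spectral peak before the ratio so empty bins
    cannot blow up.  Identical inputs give exactly 0; halving the signal
    scales its spectrum by 1/4 at every bin and gives N*ln(4).

    ``symmetric_kld=True`` instead computes the standard symmetrized
    Kullback-Leibler divergence between the normalized spectral
    distributions, for comparison.
    """
    x = np.asarray(x, dtype=float)
    imf = np.asarray(imf, dtype=float)
    if x.shape != imf.shape:
        raise ValueError("signal and IMF must have equal length")
    s_x = periodogram(x).power
    s_i = periodogram(imf).power
    floor = 1e-12 * max(s_x.max(), s_i.max(), np.finfo(float).tiny)
    s_x = np.maximum(s_x, floor)
    s_i = np.maximum(s_i, floor)
    if symmetric_kld:
        p = s_x / s_x.sum()
        q = s_i / s_i.sum()
        return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
    return float(np.sum(np.log(s_x / s_i)))


def imf_pvalue(imf: np.ndarray, alpha: float = 0.05) -> float:
    """Two-sided one-sample t-test p-value of the zero-mean hypothesis.

    A zero-variance series yields the sentinel p = 0 (ranked last).  The
    companion h-value (p < alpha rejection flag) is available from
    :func:`imf_ttest`.
    """
    return imf_ttest(imf, alpha)[0]


def imf_ttest(imf: np.ndarray, alpha: float = 0.05) -> Tuple[float, bool]:
    imf = np.asarray(imf, dtype=float)
    if imf.size < 2:
        raise ValueError("need at least 2 samples for a t-test")
    if imf.std() == 0.0:
        return 0.0, True
    p = float(stats.ttest_1samp(imf, popmean=0.0).pvalue)
    return p, bool(p < alpha)


@dataclass
class Ranking:
    """One metric's ordering of IMF indices, best first (1-based)."""

    order: np.ndarray
    metric_name: str
    scores: np.ndarray


def rank_components(
    scores: Sequence[float], direction: str = "descending", metric_name: str = ""
) -> Ranking:
    """Stable ordering of 1-based component indices by score.

    Ties break toward the lower IMF index; NaN sentinels always rank
    last regardless of direction.
    """
    scores_arr = np.asarray(scores, dtype=float)
    if scores_arr.size < 1:
        raise ValueError("need at least one score")
    if direction not in ("descending", "ascending"):
        raise ValueError("direction must be 'descending' or 'ascending'")
    key = scores_arr.copy()
    bad = ~np.isfinite(key)
    if direction == "descending":
        key = -key
    key[bad] = np.inf  # sentinels last
    idx = np.lexsort((np.arange(key.size), key))
    return Ranking(order=idx + 1, metric_name=metric_name, scores=scores_arr)


_METRIC_DIRECTION = {
    "energy": "descending",
    "correlation": "descending",
    "psd_distance": "ascending",
    "p_value": "descending",
}


def rank_imfs(x: np.ndarray, imf_set: IMFSet) -> Dict[str, Ranking]:
    """All four metric rankings for one decomposed segment."""
    imfs = imf_set.imfs
    if not imfs:
        raise ValueError("decomposition produced no IMFs")
    scores = {
        "energy": [imf_energy(imf) for imf in imfs],
        "correlation": [imf_correlation(x, imf) for imf in imfs],
        "psd_distance": [psd_distance(x, imf) for imf in imfs],
        "p_value": [imf_pvalue(imf) for imf in imfs],
    }
    return {
        name: rank_components(vals, _METRIC_DIRECTION[name], metric_name=name)
        for name, vals in scores.items()
    }


@dataclass
class RankingMatrix:
    """Stacked per-(subject, epoch, channel, metric) IMF orderings.

    ``rows`` is an integer matrix padded to ``max_imfs`` columns with the
    sentinel 0; each segment contributes four consecutive rows in the
    fixed metric order of :data:`METRICS`.
    """

    rows: np.ndarray
    row_meta: pd.DataFrame  # columns: subject, epoch, channel, metric

    @property
    def shape(self) -> Tuple[int, int]:
        return self.rows.shape

    def first_column(self) -> np.ndarray:
        return self.rows[:, 0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows, columns=[f"rank{i + 1}" for i in range(self.rows.shape[1])]
        )
        return pd.concat([self.row_meta.reset_index(drop=True), df], axis=1)


def build_ranking_matrix(
    segments: Iterable[EEGEpoch],
    decomposer: str = "emd",
    config: SiftConfig | None = None,
    imf_sets: Sequence[IMFSet] | None = None,
) -> RankingMatrix:
    """Decompose every segment and stack its four metric rankings.

    With the default study geometry (16 subjects x 10 channels x 2
    epochs) this yields a 1280 x 16 matrix: 4 metric rows per segment,
    padded to ``max_imfs`` columns.  Precomputed decompositions may be
    supplied via ``imf_sets`` (aligned with ``segments``).
    """
    if config is None:
        config = SiftConfig()
    if decomposer not in ("emd", "eemd"):
        raise ValueError("decomposer must be 'emd' or 'eemd'")
    decompose = emd if decomposer == "emd" else eemd
    width = config.max_imfs
    all_rows: List[np.ndarray] = []
    meta: List[dict] = []
    for i, segment in enumerate(list(segments)):
        if segment.n_channels != 1:
            raise ValueError("ranking matrix is built from single-channel segments")
        x = segment.data[0]
        try:
            imf_set = imf_sets[i] if imf_sets is not None else decompose(x, config)
            rankings = rank_imfs(x, imf_set)
        except Exception as exc:
            raise RuntimeError(
                f"decomposition/ranking failed for segment "
                f"{segment.subject_id}/{segment.channel_names[0]}/{segment.label}"
            ) from exc
        for metric in METRICS:
            order = rankings[metric].order
            padded = np.full(width, SENTINEL, dtype=int)
            padded[: min(order.size, width)] = order[:width]
            all_rows.append(padded)
            meta.append(
                {
                    "subject": segment.subject_id,
                    "epoch": segment.label,
                    "channel": segment.channel_names[0],
                    "metric": metric,
                }
            )
    return RankingMatrix(rows=np.vstack(all_rows), row_meta=pd.DataFrame(meta))


@dataclass
class SelectionResult:
    """Consensus-selected IMF indices, priority order, plus the histogram
    of first-priority occurrences it was derived from."""

    selected: Tuple[int, ...]
    histogram: Dict[int, int]


def consensus_select(matrix: RankingMatrix, k: int = 3) -> SelectionResult:
    """Histogram consensus over the first column of the ranking matrix.

    Counts how often each IMF index appears as a first-priority choice
    across all rows (sentinels ignored) and returns the ``k`` most
    frequent, ordered by descending count with ties toward the lower
    index.  If fewer than ``k`` distinct indices were observed, all of
    them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.rows.shape[1]:
        raise ValueError("k cannot exceed the matrix width")
    first = matrix.first_column()
    counts = Counter(int(v) for v in first if v != SENTINEL)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} distinct first-priority IMFs observed, "
            f"requested {k}"
        )
    selected = tuple(idx for idx, _ in ordered[:k])
    return SelectionResult(selected=selected, histogram=dict(counts))
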