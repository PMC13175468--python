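"""Model-assessment statistics.

Per-track Pearson correlation on flattened held-out predictions, track-track
concordance (per-sequence correlation averaged over sequences), stratification
of tracks into low / moderate / high performance groups, Kolmogorov-Smirnov
comparison of quality metrics between those groups, and per-TF concordance
between two models evaluated on identical inputs.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: stratification brackets: low r < 0.3; moderate 0.3 <= r <= 0.6; high r > 0.6
LOW_MAX = 0.3
HIGH_MIN = 0.6

KS_SIGNIFICANCE = 1e-5


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def per_track_pearson(preds: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-track r over (n_sequences x n_bins x k) tensors.

    Each track's predictions and targets are flattened across sequences and
    bins into one vector pair before correlating (a length n*b comparison per
    track). Zero-variance tracks yield NaN with a warning and should be
    excluded from downstream means.
    """
    preds = np.asarray(preds)
    targets = np.asarray(targets)
    if preds.shape != targets.shape or preds.ndim != 3:
        raise ValueError(f"expected matching (n, bins, k) tensors, got {preds.shape} vs {targets.shape}")
    k = preds.shape[2]
    out = np.empty(k)
    for j in range(k):
        out[j] = _pearson(preds[:, :, j].ravel(), targets[:, :, j].ravel())
    if np.isnan(out).any():
        warnings.warn(f"{int(np.isnan(out).sum())} track(s) had zero variance; r undefined")
    return out


def per_tf_mean_r(r: np.ndarray, tf_of_track: Sequence[str]) -> pd.Series:
    """Average per-track r within each TF (NaN tracks excluded)."""
    s = pd.Series(r, index=list(tf_of_track))
    return s.groupby(level=0).mean()


def track_pairwise_concordance(signals: np.ndarray) -> np.ndarray:
    """(k x k) matrix of mean per-sequence Pearson r between track pairs.

    For each pair of tracks, r is computed over each sequence's bins and then
    averaged across sequences (undefined per-sequence values are skipped).
    """
    signals = np.asarray(signals)
    if signals.ndim != 3 or signals.shape[2] < 2:
        raise ValueError("need (n_sequences, n_bins, k>=2) signal tensor")
    n, _, k = signals.shape
    out = np.eye(k)
    for a, b in itertools.combinations(range(k), 2):
        rs = [_pearson(signals[s, :, a], signals[s, :, b]) for s in range(n)]
        rs = [r for r in rs if not np.isnan(r)]
        out[a, b] = out[b, a] = np.mean(rs) if rs else np.nan
    return out


def stratify_tracks(r: np.ndarray) -> tuple[np.ndarray, dict[str, int]]:
    """Label tracks low / moderate / high by their r.

    Boundary handling is exact: r = 0.3 and r = 0.6 are both *moderate*.
    Undefined (NaN) r values are labelled ``undefined`` and excluded from the
    counts, which therefore partition the defined-r tracks.
    """
    r = np.asarray(r, dtype=np.float64)
    labels = np.full(r.shape, "undefined", dtype=object)
    labels[r < LOW_MAX] = "low"
    labels[(r >= LOW_MAX) & (r <= HIGH_MIN)] = "moderate"
    labels[r > HIGH_MIN] = "high"
    counts = {g: int((labels == g).sum()) for g in ("low", "moderate", "high")}
    if (labels == "undefined").any():
        warnings.warn(f"{int((labels == 'undefined').sum())} track(s) with undefined r excluded")
    return labels, counts


def compare_quality_metrics(
    group_labels: Sequence[str],
    metrics: pd.DataFrame,
    exact: bool = False,
) -> pd.DataFrame:
    """Two-sample KS tests of each quality metric between performance groups.

    Pairs tested: (low, moderate), (low, high), (moderate, high). Rows:
    (metric, group_a, group_b, ks_stat, p, significant) with significance at
    P < 1e-5. Pairs where a group has fewer than 2 tracks are skipped with a
    warning. The asymptotic two-sided P value is the default; ``exact=True``
    switches to the exact small-sample computation.
    """
    labels = np.asarray(group_labels, dtype=object)
    if len(labels) != len(metrics):
        raise ValueError("one group label per metrics row required")
    rows = []
    for ga, gb in (("low", "moderate"), ("low", "high"), ("moderate", "high")):
        a_idx, b_idx = labels == ga, labels == gb
        if a_idx.sum() < 2 or b_idx.sum() < 2:
            warnings.warn(f"pair ({ga}, {gb}) skipped: a group has fewer than 2 tracks")
            continue
        for metric in metrics.columns:
            a = metrics.loc[a_idx, metric].to_numpy(dtype=float)
            b = metrics.loc[b_idx, metric].to_numpy(dtype=float)
            res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
            rows.append((metric, ga, gb, float(res.statistic), float(res.pvalue),
                         res.pvalue < KS_SIGNIFICANCE))
    return pd.DataFrame(rows, columns=["metric", "group_a", "group_b", "ks_stat", "p", "significant"])


def cross_model_concordance(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    tf_of_track_a: Sequence[str],
    tf_of_track_b: Sequence[str],
    per_sequence: bool = False,
) -> dict[str, float]:
    """Per-TF concordance between two models on identical input windows.

    Within each model, tracks of a shared TF are averaged into one
    (n_sequences x n_bins) profile. By default the two profiles are
    concatenated across sequences and correlated once; ``per_sequence=True``
    instead correlates each sequence and averages.
    """
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    if preds_a.shape[:2] != preds_b.shape[:2]:
        raise ValueError("models must be evaluated on identical windows")
    shared = sorted(set(tf_of_track_a) & set(tf_of_track_b))
    if not shared:
        raise ValueError("no shared TF between the two models")
    tfa = np.asarray(tf_of_track_a, dtype=object)
    tfb = np.asarray(tf_of_track_b, dtype=object)
    out = {}
    for tf in shared:
        pa = preds_a[:, :, tfa == tf].mean(axis=2)
        pb = preds_b[:, :, tfb == tf].mean(axis=2)
        if per_sequence:
            rs = [_pearson(pa[s], pb[s]) for s in range(pa.shape[0])]
            rs = [r for r in rs if not np.isnan(r)]
            out[tf] = float(np.mean(rs)) if rs else np.nan
        else:
            out[tf] = _pearson(pa.ravel(), pb.ravel())
    return out


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based separation (Mann-Whitney AUC) of positive vs negative scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative labels")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluation_table(
    r: np.ndarray, tf_of_track: Sequence[str], track_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """TSV-ready (track, TF, r, group) table."""
    labels, _ = stratify_tracks(r)
    return pd.DataFrame(
        {
            "track": list(track_ids) if track_ids is not None else list(range(len(r))),
            "TF": list(tf_of_track),
            "r": r,
            "group": labels,
        }
    )
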