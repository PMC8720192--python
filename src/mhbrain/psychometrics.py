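"""Between-measure comparisons and observed-score equipercentile linking.

Integer questionnaire scores are compared with Spearman rank correlations
and two-sample Kolmogorov-Smirnov tests; scores on one measure are mapped to
another with equipercentile linking under the mid-percentile-rank convention
for discrete scores (each integer score occupies the interval
``[s - 0.5, s + 0.5)`` of the continuized distribution), inverted on the
target measure by linear interpolation of its score-to-percentile step
function. Latency-binned correlations quantify how the agreement between a
scan-day and an online measure decays with the acquisition gap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "spearman", "ks_two_sample", "percentile_rank", "equipercentile_link",
    "latency_binned_correlation", "filter_survey_records",
    "MIN_SURVEY_DURATION_S",
]

#: minimum plausible questionnaire completion time (2.5 s per question)
MIN_SURVEY_DURATION_S = 172.5


def _paired_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties) with two-sided p
    from the t approximation."""
    x, y = _paired_complete(x, y)
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov test: sup-distance of the empirical
    CDFs with the classic asymptotic two-sided p (Kolmogorov distribution of
    ``sqrt(nm/(n+m)) * D``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    d = float(stats.ks_2samp(a, b, alternative="two-sided",
                             method="asymp").statistic)
    en = np.sqrt(len(a) * len(b) / (len(a) + len(b)))
    return d, float(special.kolmogorov(en * d))


def percentile_rank(scores, s) -> float:
    """Mid-percentile rank of score ``s``: ``100 * (P(X < s) + P(X = s)/2)``."""
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("empty sample")
    return float(100.0 * (np.mean(x < s) + 0.5 * np.mean(x == s)))


def _continuized_cdf_knots(sample):
    """Knots (score + 0.5, F(score)) of the continuized discrete CDF,
    prepended with (min - 0.5, 0)."""
    sample = np.asarray(sample)
    grid = np.arange(int(sample.min()), int(sample.max()) + 1, dtype=float)
    counts = np.array([(sample == v).sum() for v in grid], dtype=float)
    F = np.cumsum(counts) / counts.sum()
    xs = np.concatenate([[grid[0] - 0.5], grid + 0.5])
    Fs = np.concatenate([[0.0], F])
    return xs, Fs


def equipercentile_link(source_sample, target_sample) -> pd.DataFrame:
    """Equipercentile mapping from source scores to the target measure.

    For every attainable source score the mid-percentile rank is computed
    and inverted on the target's continuized score-to-percentile function by
    linear interpolation; results are clamped to the attained target range.

    Returns a frame with columns source_score, source_percentile,
    mapped_target_score, and the percentile of the rounded mapped score on
    the target measure.
    """
    src = np.asarray(source_sample, dtype=float)
    src = src[np.isfinite(src)]
    tgt = np.asarray(target_sample, dtype=float)
    tgt = tgt[np.isfinite(tgt)]
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(tgt) == 0:
        raise ValueError("degenerate single-valued target sample")
    xs_t, Fs_t = _continuized_cdf_knots(tgt)
    grid = np.unique(src)
    rows = []
    for s in grid:
        p = percentile_rank(src, s)
        mapped = float(np.interp(p / 100.0, Fs_t, xs_t))
        mapped = float(np.clip(mapped, tgt.min(), tgt.max()))
        rows.append((s, p, mapped, percentile_rank(tgt, np.round(mapped))))
    return pd.DataFrame(rows, columns=[
        "source_score", "source_percentile", "mapped_target_score",
        "target_percentile"])


def latency_binned_correlation(x, y, latency, bin_width: float = 200.0,
                               min_n: int = 20,
                               absolute: bool = True) -> pd.DataFrame:
    """Spearman correlation of two measures within latency bins.

    Subjects are grouped by (absolute) acquisition latency in bins of
    ``bin_width`` days; bins with fewer than ``min_n`` complete pairs are
    dropped. Returns a frame (bin_low, bin_high, n, rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat = np.asarray(latency, dtype=float)
    if absolute:
        lat = np.abs(lat)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(lat)
    x, y, lat = x[ok], y[ok], lat[ok]
    if bin_width <= 0 or np.ptp(lat) == 0:
        bins = np.array([lat.min(), lat.min() + max(bin_width, 1.0)])
    else:
        bins = np.arange(lat.min(), lat.max() + bin_width, bin_width)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        inb = (lat >= lo) & (lat < hi if hi < bins[-1] else lat <= hi)
        if inb.sum() < min_n:
            continue
        rho, p = spearman(x[inb], y[inb])
        rows.append((lo, hi, int(inb.sum()), rho, p))
    if not rows:
        warnings.warn("all latency bins underpopulated; empty result")
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n", "rho", "p"])


def filter_survey_records(records: pd.DataFrame,
                          min_duration_s: float = MIN_SURVEY_DURATION_S
                          ) -> pd.DataFrame:
    """Apply the survey quality filters: drop participants who failed an
    attention check, then those who completed faster than ``min_duration_s``
    seconds (2.5 s per question by default). A participant failing at either
    timepoint is removed entirely.
    """
    df = records
    failed = set(df.loc[df["attention_pass"] == 0, "subject_id"])
    fast = set(df.loc[df["completion_seconds"] < min_duration_s,
                      "subject_id"])
    drop = failed | fast
    return df[~df["subject_id"].isin(drop)].reset_index(drop=True)
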