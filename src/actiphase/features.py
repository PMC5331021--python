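"""The six activity parameters of a 64-min active period.

For a segment of per-minute counts x_1…x_n (n = 64) the parameters are:

- ``mean_cpm``    — arithmetic mean activity count per minute;
- ``sd_pct``      — sample SD as a percentage of the mean
  (intra-individual fluctuation);
- ``rmssd_pct``   — root mean square of successive differences, as a
  percentage of the mean (minute-to-minute variability);
- ``autocorr_lag1`` — lag-1 autocorrelation (persistence / regularity);
- ``sampen``      — sample entropy, m = 2, r = 0.2, of the standardized
  series (complexity: −ln of the conditional probability that
  templates matching for m points also match at point m+1);
- ``fourier_ratio`` — spectral variance in the 2–8 min period band
  divided by that in the 8–64 min band (high- vs low-frequency balance).

Scale conventions: sample statistics use the n−1 denominator throughout
(SD, normalization to "sample mean 0, sample variance 1"). All parameters
except ``mean_cpm`` are invariant under positive rescaling of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .active_period import ActiveSegment
from .errors import UndefinedFeatureError

__all__ = [
    "FeatureSet",
    "FEATURE_NAMES",
    "mean_and_sd_pct",
    "rmssd_pct",
    "autocorr_lag1",
    "sample_entropy",
    "fourier_ratio",
    "compute_features",
    "build_feature_table",
]

FEATURE_NAMES = (
    "mean_cpm",
    "sd_pct",
    "rmssd_pct",
    "autocorr_lag1",
    "sampen",
    "fourier_ratio",
)

#: Period band edges in minutes: high frequency 2–8 min, low 8–64 min.
#: The shared 8-min edge (0.00208 Hz) is assigned to the low band so the
#: two bands exactly partition the non-DC spectrum of a 64-point series.
HF_BAND_MIN = (2.0, 8.0)
LF_BAND_MIN = (8.0, 64.0)


@dataclass(frozen=True)
class FeatureSet:
    mean_cpm: float
    sd_pct: float
    rmssd_pct: float
    autocorr_lag1: float
    sampen: float
    fourier_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def mean_and_sd_pct(counts) -> tuple[float, float]:
    """Mean counts/min and sample SD expressed as percent of the mean."""
    x = np.asarray(counts, dtype=float)
    mean = float(x.mean())
    if mean == 0.0:
        raise UndefinedFeatureError("sd_pct undefined: segment mean is 0")
    sd = float(x.std(ddof=1))
    return mean, 100.0 * sd / mean


def rmssd_pct(counts) -> float:
    """Root mean square of successive differences, percent of mean."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise UndefinedFeatureError("rmssd needs at least 2 points")
    mean = float(x.mean())
    if mean == 0.0:
        raise UndefinedFeatureError("rmssd_pct undefined: segment mean is 0")
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return 100.0 * rmssd / mean


def autocorr_lag1(counts, method: Literal["correlogram", "pairs"] = "correlogram") -> float:
    """Lag-1 autocorrelation of the segment.

    ``correlogram`` (default) is the standard autocovariance estimator
    normalized by the overall variance, as produced by mainstream
    statistics packages; ``pairs`` is the Pearson correlation of
    (x_t, x_{t+1}) pairs.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise UndefinedFeatureError("autocorrelation needs at least 3 points")
    centred = x - x.mean()
    denom = float(centred @ centred)
    if denom == 0.0:
        raise UndefinedFeatureError("autocorrelation undefined: zero variance")
    if method == "correlogram":
        return float(centred[:-1] @ centred[1:]) / denom
    if method == "pairs":
        r = np.corrcoef(x[:-1], x[1:])
        return float(r[0, 1])
    raise ValueError(f"unknown autocorrelation method {method!r}")


def sample_entropy(counts, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy of the standardized segment (Richman–Moorman).

    The series is transformed to sample mean 0, sample variance 1, so the
    tolerance ``r`` is in SD units. Templates of length m and m+1 are the
    N−m overlapping subsequences starting at 1…N−m; B (resp. A) counts
    ordered pairs of distinct templates of length m (resp. m+1) whose
    Chebyshev distance is ≤ r; the result is −ln(A/B). Self-matches are
    excluded.

    Raises :class:`UndefinedFeatureError` on zero variance or when A or B
    is zero (no substitution rule is applied; the row is excluded
    upstream).
    """
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n <= m + 1:
        raise UndefinedFeatureError("series too short for sample entropy")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise UndefinedFeatureError("sample entropy undefined: zero variance")
    z = (x - x.mean()) / sd

    n_templates = n - m
    # Chebyshev distance between all template pairs, built lag by lag.
    dist_m = np.zeros((n_templates, n_templates))
    for offset in range(m):
        seg = z[offset : offset + n_templates]
        np.maximum(dist_m, np.abs(seg[:, None] - seg[None, :]), out=dist_m)
    match_m = dist_m <= r
    seg = z[m : m + n_templates]
    match_m1 = match_m & (np.abs(seg[:, None] - seg[None, :]) <= r)

    b = int(match_m.sum()) - n_templates  # drop self-matches on the diagonal
    a = int(match_m1.sum()) - n_templates
    if b == 0 or a == 0:
        raise UndefinedFeatureError("sample entropy undefined: no template matches")
    return float(-np.log(a / b))


def fourier_ratio(counts) -> float:
    """High/low-frequency variance ratio of the standardized segment.

    The segment (length n, 1 sample/min) is standardized and its
    periodogram computed; the variance carried by bin k (period n/k min)
    is 2|X_k|²/n² for 0 < k < n/2 and |X_k|²/n² at the Nyquist bin. The
    high band collects periods in [2, 8) min, the low band periods in
    [8, n] min; returned is HF/LF. Higher values mean relatively more
    fast, jittery variation.
    """
    x = np.asarray(counts, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise UndefinedFeatureError("fourier ratio undefined: zero variance")
    z = (x - x.mean()) / sd
    spectrum = np.fft.rfft(z)
    power = np.abs(spectrum) ** 2 / n**2
    k = np.arange(power.size)
    weights = np.full(power.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is not doubled
    bin_var = weights * power
    period = np.empty(power.size)
    period[0] = np.inf
    period[1:] = n / k[1:]
    hf = float(bin_var[(period >= HF_BAND_MIN[0]) & (period < HF_BAND_MIN[1])].sum())
    lf = float(bin_var[(period >= LF_BAND_MIN[0]) & (period <= LF_BAND_MIN[1])].sum())
    # guard against pure FFT round-off masquerading as low-frequency power
    if lf <= 1e-12 * (hf + lf):
        raise UndefinedFeatureError("fourier ratio undefined: no low-frequency variance")
    return hf / lf


def compute_features(counts, m: int = 2, r: float = 0.2) -> FeatureSet:
    """All six parameters for one segment."""
    mean, sd = mean_and_sd_pct(counts)
    return FeatureSet(
        mean_cpm=mean,
        sd_pct=sd,
        rmssd_pct=rmssd_pct(counts),
        autocorr_lag1=autocorr_lag1(counts),
        sampen=sample_entropy(counts, m=m, r=r),
        fourier_ratio=fourier_ratio(counts),
    )


def build_feature_table(
    segments: Iterable[ActiveSegment],
    subjects: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-segment features into the subjects × 12-predictor table.

    ``subjects`` must have columns subject_id, phase, age, gender. Each
    subject needs exactly one morning and one evening segment; subjects
    with a missing segment or any undefined feature are excluded and
    listed in the returned exclusion report rather than silently dropped.

    Returns
    -------
    (features, exclusions)
        ``features`` has columns subject_id, phase, age, gender, then the
        morning block and the evening block (six parameters each, e.g.
        ``morning_sampen``). ``exclusions`` has columns subject_id,
        reason.
    """
    per_subject: dict[str, dict[str, float]] = {}
    problems: list[tuple[str, str]] = []
    seen: dict[str, set[str]] = {}
    for segment in segments:
        sid = segment.subject_id
        seen.setdefault(sid, set())
        if segment.window_label in seen[sid]:
            problems.append((sid, f"duplicate {segment.window_label} segment"))
            continue
        seen[sid].add(segment.window_label)
        try:
            values = compute_features(segment.counts)
        except UndefinedFeatureError as err:
            problems.append((sid, f"{segment.window_label}: {err}"))
            continue
        row = per_subject.setdefault(sid, {})
        for name, value in values.as_dict().items():
            row[f"{segment.window_label}_{name}"] = value

    expected = [f"{w}_{f}" for w in ("morning", "evening") for f in FEATURE_NAMES]
    rows = []
    excluded_ids = {sid for sid, _ in problems}
    for record in subjects.to_dict("records"):
        sid = str(record["subject_id"])
        feats = per_subject.get(sid, {})
        missing = [c for c in expected if c not in feats]
        if missing:
            if sid not in excluded_ids:
                windows = sorted({c.split("_", 1)[0] for c in missing})
                problems.append((sid, f"missing segment(s): {', '.join(windows)}"))
            continue
        rows.append(
            {
                "subject_id": sid,
                "phase": record["phase"],
                "age": record["age"],
                "gender": record["gender"],
                **{c: feats[c] for c in expected},
            }
        )
    features = pd.DataFrame(rows, columns=["subject_id", "phase", "age", "gender", *expected])
    exclusions = pd.DataFrame(problems, columns=["subject_id", "reason"])
    return features, exclusions
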