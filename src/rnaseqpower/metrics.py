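"""Evaluation statistics: FPR/TPR, call rates, strata, histograms, overlap.

Rates are quoted in percent at a significance level ``alpha`` (also in
percent): a transcript is called DE when ``100 * p < alpha``.  Under the
null the false positive rate over all transcripts should match ``alpha``
for a well-calibrated test.  When DE is induced, rates are computed against
the "effectively DE" labels (regulating factor at least a minimal fold
change away from 1): FPR is the fraction of effectively-non-DE transcripts
called, TPR the fraction of effectively-DE transcripts called; 100-FPR and
TPR are the usual specificity and sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import CountMatrix, LABEL_DE

__all__ = [
    "SignificanceLevel",
    "MetricsSummary",
    "fpr_null",
    "fpr",
    "tpr",
    "call_rate",
    "stratify_by_count",
    "pvalue_histogram",
    "call_overlap",
]


@dataclass(frozen=True)
class SignificanceLevel:
    """Significance level alpha quoted in percent; calls are 100*p < alpha."""

    alpha_percent: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha_percent < 100:
            raise ValueError("alpha_percent must lie in (0, 100)")

    @property
    def threshold(self) -> float:
        return self.alpha_percent / 100.0


@dataclass(frozen=True)
class MetricsSummary:
    """Call rate and error rates for one scenario cell and stratum."""

    call_rate_percent: float
    fpr_percent: float
    tpr_percent: float
    stratum: str
    n_transcripts: int
    n_effective_de: int
    n_effective_nonde: int


def _alpha(alpha) -> float:
    if isinstance(alpha, SignificanceLevel):
        return alpha.threshold
    alpha = float(alpha)
    if not 0 < alpha < 100:
        raise ValueError("alpha must lie in (0, 100) percent")
    return alpha / 100.0


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == LABEL_DE


def fpr_null(p_values, alpha) -> float:
    """Percent of all transcripts with 100*p < alpha (null-data FPR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return 100.0 * float(np.mean(p < _alpha(alpha)))


def fpr(p_adj, labels, alpha) -> float:
    """Percent of effectively-non-DE transcripts called at 100*p_adj < alpha.

    Returns ``nan`` (flagged) when the denominator class is empty.
    """
    p = np.asarray(p_adj, dtype=float)
    de = _as_bool_labels(labels)
    non_de = ~de
    if non_de.sum() == 0:
        return float("nan")
    return 100.0 * float(np.mean(p[non_de] < _alpha(alpha)))


def tpr(p_adj, labels, alpha) -> float:
    """Percent of effectively-DE transcripts called at 100*p_adj < alpha."""
    p = np.asarray(p_adj, dtype=float)
    de = _as_bool_labels(labels)
    if de.sum() == 0:
        return float("nan")
    return 100.0 * float(np.mean(p[de] < _alpha(alpha)))


def call_rate(p_adj, alpha) -> float:
    """Percent of all transcripts called DE at 100*p_adj < alpha."""
    p = np.asarray(p_adj, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return 100.0 * float(np.mean(p < _alpha(alpha)))


def stratify_by_count(counts, condition=None, threshold: float = 100.0, use: str = "control"):
    """High/low-count masks: mean count over replicates > threshold is high.

    Means are taken across the biological replicates of one condition
    (default: control) at the depth under evaluation; the boundary value
    itself is low.  Returns ``{"high": mask, "low": mask}``.
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        cond = counts.condition if condition is None else np.asarray(condition)
    else:
        mat = np.asarray(counts)
        cond = None if condition is None else np.asarray(condition)
    if cond is not None and use in set(cond):
        mat = mat[:, cond == use]
    means = mat.mean(axis=1)
    high = means > threshold
    return {"high": high, "low": ~high}


def pvalue_histogram(p_values, bins: int = 100) -> np.ndarray:
    """Percent of p-values per bin over [0, 1], right-closed bins.

    The first bin is [0, 1/bins]; subsequent bins are half-open on the left,
    so a point mass at 1 lands entirely in the last bin (the discreteness
    spike of the exact test).  Percentages sum to exactly 100.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.searchsorted(edges, p, side="left") - 1
    idx = np.clip(idx, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return 100.0 * counts / p.size


def call_overlap(results_a, results_b, labels, alpha) -> pd.DataFrame:
    """Two-method call overlap (a only / b only / both), split by true label.

    ``results_a``/``results_b`` are DE-result DataFrames sharing the same
    transcript set; calls use adjusted p-values at ``alpha`` percent.
    """
    a = results_a.set_index("transcript_id") if "transcript_id" in results_a else results_a
    b = results_b.set_index("transcript_id") if "transcript_id" in results_b else results_b
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("mismatched transcript sets")
        b = b.reindex(a.index)
    thr = _alpha(alpha)
    call_a = a["p_adj"].to_numpy() < thr
    call_b = b["p_adj"].to_numpy() < thr
    de = _as_bool_labels(labels)
    rows = []
    for label_name, mask in (("effectively-DE", de), ("effectively-non-DE", ~de)):
        rows.append(
            {
                "label": label_name,
                "a_only": int((call_a & ~call_b & mask).sum()),
                "b_only": int((call_b & ~call_a & mask).sum()),
                "both": int((call_a & call_b & mask).sum()),
                "union": int(((call_a | call_b) & mask).sum()),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
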