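"""Classical-test-theory analysis arm: sum scores, the score-scale effect
size, and the pooled two-sample t-test.

The observed score is the (optionally weighted) sum of a patient's item
responses.  Because the score is a bounded, discrete surrogate for the latent
trait, its standardized group difference (ES_CTT) is systematically smaller
than the latent effect size — the attenuation this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .generative import ResponseData
from .model import TestResult

__all__ = ["ScoreSet", "DegenerateDataError", "compute_scores", "ctt_effect_size", "two_sample_t_test"]


class DegenerateDataError(ValueError):
    """Raised when scores carry no variance and a scale-based quantity is undefined."""


@dataclass
class ScoreSet:
    """Per-patient scores with group labels."""

    scores: np.ndarray
    groups: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.scores.shape != self.groups.shape:
            raise ValueError("scores and groups must have the same length")

    def by_group(self) -> tuple[np.ndarray, np.ndarray]:
        return self.scores[self.groups == 0], self.scores[self.groups == 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient": np.arange(self.scores.size), "group": self.groups, "score": self.scores}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_scores(data: ResponseData, weights: np.ndarray | None = None) -> ScoreSet:
    """Sum (or weighted-sum) score per patient."""
    if weights is None:
        scores = data.responses.sum(axis=1).astype(float)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (data.n_items,):
            raise ValueError("weights must have one entry per item")
        scores = data.responses @ weights
    return ScoreSet(scores=scores, groups=data.groups, weights=weights)


def _pooled_sd(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = x1.size, x2.size
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(s2))


def ctt_effect_size(scores: ScoreSet, sd: str = "total") -> float:
    """Effect size on the score scale: (mean2 - mean1) / global SD.

    ``sd='total'`` (default) standardizes by the global standard deviation of
    the combined sample, the scale a planner observes without a group split;
    ``sd='pooled'`` uses the pooled within-group SD of the t-test instead.
    The two differ by the between-group variance the group effect itself adds,
    so the pooled variant is slightly larger under a true effect.
    """
    x1, x2 = scores.by_group()
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need at least 2 patients")
    if sd == "pooled":
        scale = _pooled_sd(x1, x2)
    elif sd == "total":
        scale = float(scores.scores.std(ddof=1))
    else:
        raise ValueError("sd must be 'pooled' or 'total'")
    if scale == 0.0:
        raise DegenerateDataError("zero score standard deviation")
    return float((x2.mean() - x1.mean()) / scale)


def two_sample_t_test(scores: ScoreSet, alpha: float = 0.05) -> TestResult:
    """Pooled-variance two-sided t-test of equal group mean scores."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    x1, x2 = scores.by_group()
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need at least 2 patients")
    if _pooled_sd(x1, x2) == 0.0:
        raise DegenerateDataError("zero pooled variance")
    stat, p = stats.ttest_ind(x2, x1, equal_var=True)
    return TestResult(
        statistic=float(stat), p_value=float(p), alpha=alpha,
        significant=bool(p < alpha), method="t",
    )
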