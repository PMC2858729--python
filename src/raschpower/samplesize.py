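"""Sample-size and power calculators for two-group comparisons, and the
pilot-study simulation-validation workflow.

Two analytic routes are provided for a normally distributed endpoint with
common variance and equal group sizes n:

* the conventional normal-approximation formula
  ``n = 2 (z_{1-alpha/2} + z_{1-beta})^2 / ES^2`` and its inversion to power;
* the exact two-sided pooled two-sample t-test power via the noncentral t,
  inverted by integer search.

The pilot workflow emulates planning from a small calibration study: each
Rasch parameter is drawn uniformly from its pilot 95% confidence interval,
a two-group study of the candidate size is simulated, and both analysis arms
(Rasch MML + Wald; sum-score t-test) are applied; power is the proportion of
significant replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ctt import compute_scores, two_sample_t_test
from .generative import (
    ItemBank,
    LatentTraitSpec,
    make_item_difficulties,
    simulate_latent_traits,
    simulate_responses,
)
from .model import FitSpecification, RaschModel

__all__ = [
    "expected_power_normal",
    "sample_size_normal",
    "power_ttest",
    "sample_size_ttest",
    "PilotSummary",
    "PilotValidationResult",
    "make_synthetic_pilot",
    "pilot_validation",
]


def expected_power_normal(es: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Normal-approximation power of the two-sided two-sample test.

    Phi(|ES| * sqrt(n/2) - z_{1-alpha/2}); the negligible opposite-tail term
    is omitted, as in the conventional formula.
    """
    if not np.isfinite(es):
        raise ValueError("es must be finite")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(es) * math.sqrt(n_per_group / 2.0) - z_crit))


def sample_size_normal(es: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Per-group n from the conventional formula, rounded up."""
    if es == 0:
        raise ValueError("es must be nonzero")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(2.0 * (z_a + z_b) ** 2 / es**2))


def power_ttest(es: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled two-sample t-test.

    With equal group sizes n the test statistic follows a noncentral t with
    2n - 2 degrees of freedom and noncentrality ES * sqrt(n/2).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for a t-test")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = abs(es) * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)  # can underflow to nan at large ncp
    if not math.isfinite(lower):
        lower = 0.0
    return float(upper + lower)


def sample_size_ttest(es: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Smallest per-group n whose exact t-test power reaches the target."""
    if es == 0:
        raise ValueError("es must be nonzero")
    n = max(2, sample_size_normal(es, alpha, power) - 2)
    while power_ttest(es, n, alpha) < power:
        n += 1
    while n > 2 and power_ttest(es, n - 1, alpha) >= power:
        n -= 1
    return n


@dataclass(frozen=True)
class PilotSummary:
    """Point estimates and 95% CIs from a pilot Rasch fit.

    ``sigma_estimate`` is the latent-trait standard deviation (not variance).
    ``difficulties_ci`` is a (J, 2) array of per-item (low, high) bounds.
    """

    d_estimate: float
    d_ci: tuple[float, float]
    sigma_estimate: float
    sigma_ci: tuple[float, float]
    difficulties: np.ndarray
    difficulties_ci: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "difficulties", np.asarray(self.difficulties, float))
        ci = np.asarray(self.difficulties_ci, float)
        object.__setattr__(self, "difficulties_ci", ci)
        if ci.shape != (self.difficulties.size, 2):
            raise ValueError("difficulties_ci must be a (J, 2) array")
        if not (self.d_ci[0] <= self.d_estimate <= self.d_ci[1]):
            raise ValueError("d CI must contain its point estimate")
        if not (0.0 < self.sigma_ci[0] <= self.sigma_estimate <= self.sigma_ci[1]):
            raise ValueError("sigma CI must be positive and contain its estimate")
        if not ((ci[:, 0] <= self.difficulties) & (self.difficulties <= ci[:, 1])).all():
            raise ValueError("each difficulty CI must contain its estimate")

    @property
    def n_items(self) -> int:
        return int(self.difficulties.size)

    @property
    def effect_size(self) -> float:
        return self.d_estimate / self.sigma_estimate


def make_synthetic_pilot(
    d: float = 0.649,
    sigma: float = 1.983,
    n_items: int = 8,
    d_halfwidth: float = 0.0,
    sigma_halfwidth: float = 0.0,
    delta_halfwidth: float = 0.0,
) -> PilotSummary:
    """A synthetic pilot summary for testing the validation workflow.

    Item difficulties are centred standard-normal quantiles scaled by the
    latent SD, so the instrument spans the trait range.  Defaults mimic a
    small pain-questionnaire pilot (8 binary items, latent group difference
    0.649, latent SD 1.983); halfwidths of 0 collapse the CIs to points.
    """
    delta = make_item_difficulties(n_items).difficulties * sigma
    ci = np.column_stack([delta - delta_halfwidth, delta + delta_halfwidth])
    return PilotSummary(
        d_estimate=d,
        d_ci=(d - d_halfwidth, d + d_halfwidth),
        sigma_estimate=sigma,
        sigma_ci=(max(sigma - sigma_halfwidth, 1e-9), sigma + sigma_halfwidth),
        difficulties=delta,
        difficulties_ci=ci,
    )


@dataclass(frozen=True)
class PilotValidationResult:
    power_irt: float
    power_ctt: float
    power_irt_ci: tuple[float, float]
    power_ctt_ci: tuple[float, float]
    n_converged: int
    n_replicates: int


def _prop_ci(p: float, n: int) -> tuple[float, float]:
    half = 1.96 * math.sqrt(max(p * (1.0 - p), 0.0) / n) if n > 0 else float("nan")
    return (max(p - half, 0.0), min(p + half, 1.0))


def pilot_validation(
    pilot: PilotSummary,
    n_per_group: int,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> PilotValidationResult:
    """Simulation check that a candidate sample size delivers its power.

    Per replicate, d, sigma and every difficulty are drawn independently and
    uniformly from their pilot CIs; a two-group dataset of ``n_per_group``
    per arm is simulated and analysed with a Situation-3 Rasch fit (Wald test
    of d) and a score t-test.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sig_irt = 0
    sig_ctt = 0
    n_conv = 0
    n_ctt = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        d = rng.uniform(*pilot.d_ci) if pilot.d_ci[0] < pilot.d_ci[1] else pilot.d_estimate
        sig = (
            rng.uniform(*pilot.sigma_ci)
            if pilot.sigma_ci[0] < pilot.sigma_ci[1]
            else pilot.sigma_estimate
        )
        lo, hi = pilot.difficulties_ci[:, 0], pilot.difficulties_ci[:, 1]
        delta = np.where(lo < hi, rng.uniform(lo, hi), pilot.difficulties)
        bank = ItemBank(difficulties=delta)
        spec = LatentTraitSpec(mu1=-d / 2.0, d=d, sigma2=sig * sig)
        traits, groups = simulate_latent_traits(spec, n_per_group, rng)
        data = simulate_responses(traits, groups, bank, rng)
        try:
            fit = RaschModel(data, spec=FitSpecification(situation=3)).fit()
            if fit.converged:
                n_conv += 1
                if fit.wald_test(alpha).significant:
                    sig_irt += 1
        except ValueError:
            pass
        try:
            scores = compute_scores(data, weights=weights)
            n_ctt += 1
            if two_sample_t_test(scores, alpha).significant:
                sig_ctt += 1
        except ValueError:
            pass
    if n_conv == 0 or n_ctt == 0:
        raise RuntimeError("no usable replicates")
    p_irt = sig_irt / n_conv
    p_ctt = sig_ctt / n_ctt
    return PilotValidationResult(
        power_irt=p_irt,
        power_ctt=p_ctt,
        power_irt_ci=_prop_ci(p_irt, n_conv),
        power_ctt_ci=_prop_ci(p_ctt, n_ctt),
        n_converged=n_conv,
        n_replicates=n_replicates,
    )
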