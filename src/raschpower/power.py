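"""Monte-Carlo power study engine.

A scenario fixes the latent effect size, per-group sample size, questionnaire
length, item-parameter precision epsilon, analysis regime (Situation 1/2/3),
replicate count, alpha and a root seed.  Each replicate simulates a fresh
two-group Rasch dataset and analyses it with both arms:

* IRT — marginal-maximum-likelihood Rasch fit, Wald test of the group effect;
* CTT — unweighted sum score, pooled two-sample t-test, score-scale effect
  size.

Power is the proportion of significant tests among usable replicates, with a
normal-approximation Monte-Carlo confidence interval.  Replicates are driven
by deterministically split random streams, so any single replicate can be
reproduced in isolation from (seed, replicate_index).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ctt import DegenerateDataError, compute_scores, ctt_effect_size, two_sample_t_test
from .generative import (
    latent_spec_from_effect_size,
    make_item_difficulties,
    perturb_item_difficulties,
    simulate_latent_traits,
    simulate_responses,
)
from .model import FitSpecification, RaschModel, TestResult, wald_test_group_effect
from .samplesize import expected_power_normal

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "ScenarioResult",
    "ScenarioError",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "GRID_COLUMNS",
]

logger = logging.getLogger(__name__)


class ScenarioError(RuntimeError):
    """Raised when a scenario yields no usable replicates."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design."""

    es_irt: float
    n_per_group: int
    n_items: int
    epsilon: float = 0.0
    situation: int = 2
    n_replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.situation not in (1, 2, 3):
            raise ValueError("situation must be 1, 2 or 3")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def key(self) -> tuple:
        return (self.es_irt, self.n_per_group, self.n_items, self.epsilon, self.situation)


@dataclass(frozen=True)
class ReplicateResult:
    irt: TestResult | None
    ctt: TestResult | None
    es_ctt: float
    d_hat: float
    converged: bool
    failure: str | None = None


def _fit_spec_for(config: ScenarioConfig, bank) -> FitSpecification:
    if config.situation == 1:
        return FitSpecification(
            situation=1,
            fixed_mu1=-config.es_irt / 2.0,
            fixed_difficulties=bank.difficulties_for_analysis(),
        )
    if config.situation == 2:
        return FitSpecification(
            situation=2, fixed_difficulties=bank.difficulties_for_analysis()
        )
    return FitSpecification(situation=3)


def run_replicate(config: ScenarioConfig, replicate_index: int) -> ReplicateResult:
    """Simulate and analyse one dataset; deterministic in (seed, index).

    Situations 1-2 analyse with the perturbed difficulties delta_j* (drawn
    afresh each replicate when epsilon > 0); Situation 3 estimates its own.
    Analysis failures are recorded, never raised.
    """
    rng = np.random.default_rng([config.seed, replicate_index])
    bank = make_item_difficulties(config.n_items)
    if config.epsilon > 0:
        bank = perturb_item_difficulties(bank, config.epsilon, rng)
    spec = latent_spec_from_effect_size(config.es_irt)
    traits, groups = simulate_latent_traits(spec, config.n_per_group, rng)
    data = simulate_responses(traits, groups, bank, rng)

    irt: TestResult | None = None
    d_hat = math.nan
    converged = False
    failure = None
    try:
        fit = RaschModel(data, spec=_fit_spec_for(config, bank)).fit()
        d_hat = fit.d_hat
        converged = fit.converged
        if converged:
            irt = wald_test_group_effect(fit, config.alpha)
        else:
            failure = f"non-convergence: {fit.message}"
    except ValueError as exc:
        failure = f"irt: {exc}"

    ctt: TestResult | None = None
    es = math.nan
    try:
        scores = compute_scores(data)
        ctt = two_sample_t_test(scores, config.alpha)
        es = ctt_effect_size(scores)
    except (DegenerateDataError, ValueError) as exc:  # pragma: no cover - extreme data
        failure = (failure + "; " if failure else "") + f"ctt: {exc}"

    return ReplicateResult(
        irt=irt, ctt=ctt, es_ctt=es, d_hat=d_hat, converged=converged, failure=failure
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregated power estimates for one scenario."""

    config: ScenarioConfig
    power_irt: float
    power_ctt: float
    power_irt_ci: tuple[float, float]
    power_ctt_ci: tuple[float, float]
    mean_es_ctt: float
    es_ctt_ci: tuple[float, float]
    attenuation_ratio: float
    expected_power_normal: float
    n_converged: int
    n_replicates: int

    def to_row(self) -> dict:
        c = self.config
        return {
            "es_irt": c.es_irt,
            "n_per_group": c.n_per_group,
            "n_items": c.n_items,
            "epsilon": c.epsilon,
            "situation": c.situation,
            "alpha": c.alpha,
            "seed": c.seed,
            "n_replicates": self.n_replicates,
            "n_converged": self.n_converged,
            "power_irt": self.power_irt,
            "power_irt_lo": self.power_irt_ci[0],
            "power_irt_hi": self.power_irt_ci[1],
            "power_ctt": self.power_ctt,
            "power_ctt_lo": self.power_ctt_ci[0],
            "power_ctt_hi": self.power_ctt_ci[1],
            "mean_es_ctt": self.mean_es_ctt,
            "es_ctt_lo": self.es_ctt_ci[0],
            "es_ctt_hi": self.es_ctt_ci[1],
            "attenuation_ratio": self.attenuation_ratio,
            "expected_power_normal": self.expected_power_normal,
        }


GRID_COLUMNS = list(
    ScenarioResult(
        config=ScenarioConfig(es_irt=0.5, n_per_group=2, n_items=1, n_replicates=1),
        power_irt=0.0, power_ctt=0.0, power_irt_ci=(0.0, 0.0), power_ctt_ci=(0.0, 0.0),
        mean_es_ctt=0.0, es_ctt_ci=(0.0, 0.0), attenuation_ratio=0.0,
        expected_power_normal=0.0, n_converged=0, n_replicates=0,
    ).to_row().keys()
)

_KEY_COLS = ["es_irt", "n_per_group", "n_items", "epsilon", "situation"]


def _prop_ci(p: float, n: int) -> tuple[float, float]:
    if n == 0:
        return (math.nan, math.nan)
    half = 1.96 * math.sqrt(max(p * (1.0 - p), 0.0) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def run_scenario(config: ScenarioConfig, log_every: int = 100) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate both arms' power.

    Power denominators count only usable replicates (converged fits for the
    IRT arm, non-degenerate scores for CTT); divergent counts are reported.
    """
    sig_irt = n_conv = sig_ctt = n_ctt = 0
    es_vals: list[float] = []
    for rep in range(config.n_replicates):
        res = run_replicate(config, rep)
        if res.irt is not None:
            n_conv += 1
            sig_irt += int(res.irt.significant)
        elif res.failure:
            logger.info("replicate %d unusable (%s)", rep, res.failure)
        if res.ctt is not None:
            n_ctt += 1
            sig_ctt += int(res.ctt.significant)
            es_vals.append(res.es_ctt)
        if log_every and (rep + 1) % log_every == 0:
            logger.info(
                "scenario %s: %d/%d replicates", config.key(), rep + 1, config.n_replicates
            )
    if n_conv == 0 and n_ctt == 0:
        raise ScenarioError(f"all {config.n_replicates} replicates failed")
    p_irt = sig_irt / n_conv if n_conv else math.nan
    p_ctt = sig_ctt / n_ctt if n_ctt else math.nan
    es_arr = np.asarray(es_vals)
    mean_es = float(es_arr.mean()) if es_arr.size else math.nan
    es_half = (
        1.96 * float(es_arr.std(ddof=1)) / math.sqrt(es_arr.size) if es_arr.size > 1 else math.nan
    )
    return ScenarioResult(
        config=config,
        power_irt=p_irt,
        power_ctt=p_ctt,
        power_irt_ci=_prop_ci(p_irt, n_conv),
        power_ctt_ci=_prop_ci(p_ctt, n_ctt),
        mean_es_ctt=mean_es,
        es_ctt_ci=(mean_es - es_half, mean_es + es_half),
        attenuation_ratio=mean_es / config.es_irt if config.es_irt != 0 else math.nan,
        expected_power_normal=expected_power_normal(
            config.es_irt, config.n_per_group, config.alpha
        ),
        n_converged=n_conv,
        n_replicates=config.n_replicates,
    )


def run_grid(configs: list[ScenarioConfig], out_path: str | Path | None = None) -> pd.DataFrame:
    """Run a list of scenarios into a tidy table keyed by
    (es_irt, N, J, epsilon, situation).

    When ``out_path`` names an existing table, scenarios already present are
    skipped and the table is extended in place (resumable runs).
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    keys = [c.key() for c in configs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate scenario keys in grid")
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path)
        rows = existing.to_dict("records")
        done = {tuple(r[k] for k in _KEY_COLS) for r in rows}
    for config in configs:
        if tuple(config.key()) in done:
            logger.info("skipping completed scenario %s", config.key())
            continue
        rows.append(run_scenario(config).to_row())
        if out_path is not None:
            pd.DataFrame(rows, columns=GRID_COLUMNS).to_csv(out_path, index=False)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
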