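"""Generative side of the framework: item banks, latent-trait populations and
binary response matrices under the Rasch model.

The simulation design mirrors a two-group cross-sectional PRO study: each
patient carries a latent trait theta drawn from a group-specific normal
distribution, and answers J binary items whose difficulties are placed at
regularly spaced standard-normal quantiles.  A group effect ``d`` shifts the
second group's latent mean; with unit latent variance, ``d`` equals the
effect size on the latent scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ItemBank",
    "LatentTraitSpec",
    "ResponseData",
    "make_item_difficulties",
    "perturb_item_difficulties",
    "latent_spec_from_effect_size",
    "simulate_latent_traits",
    "item_response_probability",
    "simulate_responses",
]


@dataclass(frozen=True)
class ItemBank:
    """Item difficulty parameters, on the logit scale.

    ``difficulties`` are the simulation-truth values delta_j used to generate
    responses.  ``analysis_difficulties`` (delta_j*, present only after
    perturbation) are the values treated as *known* at analysis time; they
    differ from the truth by at most ``precision`` (epsilon).
    """

    difficulties: np.ndarray
    precision: float = 0.0
    analysis_difficulties: np.ndarray | None = None

    def __post_init__(self) -> None:
        diff = np.asarray(self.difficulties, dtype=float)
        object.__setattr__(self, "difficulties", diff)
        if diff.ndim != 1 or diff.size < 1:
            raise ValueError("difficulties must be a non-empty 1-d array")
        if not np.all(np.isfinite(diff)):
            raise ValueError("difficulties must be finite")
        if not (self.precision >= 0.0):
            raise ValueError("precision (epsilon) must be non-negative")
        if self.analysis_difficulties is not None:
            ad = np.asarray(self.analysis_difficulties, dtype=float)
            object.__setattr__(self, "analysis_difficulties", ad)
            if ad.shape != diff.shape:
                raise ValueError("analysis_difficulties must match difficulties in length")
            dev = float(np.max(np.abs(ad - diff)))
            if dev > self.precision + 1e-12:
                raise ValueError(
                    f"analysis difficulties deviate by {dev:.3g} > precision {self.precision:.3g}"
                )

    @property
    def n_items(self) -> int:
        return int(self.difficulties.size)

    def difficulties_for_analysis(self) -> np.ndarray:
        """Values to fix at analysis time: delta_j* if present, else delta_j."""
        if self.analysis_difficulties is not None:
            return self.analysis_difficulties
        return self.difficulties


@dataclass(frozen=True)
class LatentTraitSpec:
    """Two-group latent-trait population: theta ~ N(mu1 + d*g, sigma2)."""

    mu1: float
    d: float
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0.0 and np.isfinite(self.sigma2)):
            raise ValueError("sigma2 must be positive and finite")
        if not (np.isfinite(self.mu1) and np.isfinite(self.d)):
            raise ValueError("mu1 and d must be finite")

    @property
    def mu2(self) -> float:
        return self.mu1 + self.d

    @property
    def effect_size(self) -> float:
        """Effect size on the latent scale, d / sigma."""
        return self.d / float(np.sqrt(self.sigma2))


@dataclass
class ResponseData:
    """An N x J binary response matrix with 0/1 group labels.

    ``latent_traits`` keeps the simulation-truth theta_i when the data were
    simulated (diagnostics only; never used by the estimators).
    """

    responses: np.ndarray
    groups: np.ndarray
    latent_traits: np.ndarray | None = None

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses)
        grp = np.asarray(self.groups)
        if resp.ndim != 2:
            raise ValueError("responses must be a 2-d matrix")
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("responses must contain only 0/1 (no missing data supported)")
        if grp.shape != (resp.shape[0],):
            raise ValueError("groups must have one label per patient")
        if not np.isin(grp, (0, 1)).all():
            raise ValueError("group labels must be 0 (first group) or 1 (second group)")
        self.responses = resp.astype(np.int8)
        self.groups = grp.astype(np.int8)
        if self.latent_traits is not None:
            lt = np.asarray(self.latent_traits, dtype=float)
            if lt.shape != (resp.shape[0],):
                raise ValueError("latent_traits must have one value per patient")
            self.latent_traits = lt

    @property
    def n_patients(self) -> int:
        return int(self.responses.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.responses.shape[1])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"item{j + 1}": self.responses[:, j] for j in range(self.n_items)}
        return pd.DataFrame({"group": self.groups, **cols})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseData":
        if "group" not in df.columns:
            raise ValueError("expected a 'group' column")
        items = [c for c in df.columns if c != "group"]
        return cls(responses=df[items].to_numpy(), groups=df["group"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "ResponseData":
        return cls.from_dataframe(pd.read_csv(path))


def make_item_difficulties(n_items: int) -> ItemBank:
    """Build a bank of J difficulties at standard-normal quantiles.

    delta_j = Phi^{-1}(j / (J+1)) for j = 1..J: regularly spaced, strictly
    increasing, and exactly symmetric about 0 (so the mean item difficulty
    matches the pooled latent mean of 0).
    """
    if isinstance(n_items, bool) or not isinstance(n_items, (int, np.integer)):
        raise ValueError("n_items must be a positive integer")
    if n_items < 1:
        raise ValueError("n_items must be a positive integer")
    j = np.arange(1, n_items + 1, dtype=float)
    q = norm.ppf(j / (n_items + 1))
    # enforce exact symmetry (sum identically 0) against ppf rounding
    delta = (q - q[::-1]) / 2.0
    return ItemBank(difficulties=delta, precision=0.0)


def perturb_item_difficulties(
    bank: ItemBank, epsilon: float, rng: np.random.Generator
) -> ItemBank:
    """Return a copy whose analysis-time difficulties are the truth plus
    independent Uniform(-epsilon, +epsilon) noise.

    Models an instrument calibrated on an earlier sample: delta_j* is the
    published value fixed at analysis time, off the truth by at most epsilon.
    """
    if not (epsilon >= 0.0):
        raise ValueError("epsilon must be non-negative")
    if epsilon == 0.0:
        perturbed = bank.difficulties.copy()
    else:
        perturbed = bank.difficulties + rng.uniform(-epsilon, epsilon, size=bank.n_items)
    return dataclasses.replace(
        bank, precision=float(epsilon), analysis_difficulties=perturbed
    )


def latent_spec_from_effect_size(es_irt: float) -> LatentTraitSpec:
    """Latent population for a target effect size with unit variance.

    mu1 = -ES/2 and mu2 = +ES/2, so the pooled latent mean is 0, centred on
    the item bank.
    """
    if not np.isfinite(es_irt):
        raise ValueError("es_irt must be finite")
    return LatentTraitSpec(mu1=-es_irt / 2.0, d=float(es_irt), sigma2=1.0)


def simulate_latent_traits(
    spec: LatentTraitSpec, n_per_group: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent traits per group; group 2 carries the +d shift."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    sigma = float(np.sqrt(spec.sigma2))
    groups = np.repeat(np.array([0, 1], dtype=np.int8), n_per_group)
    means = np.where(groups == 0, spec.mu1, spec.mu2)
    traits = rng.normal(means, sigma)
    return traits, groups


def item_response_probability(theta, delta):
    """Rasch probability of a positive response.

    P(X=1 | theta, delta) = exp(theta - delta) / (1 + exp(theta - delta)),
    evaluated stably for large |theta - delta|.  Broadcasts over arrays.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(delta))):
        raise ValueError("theta and delta must be finite")
    p = expit(theta - delta)
    if p.ndim == 0:
        return float(p)
    return p


def simulate_responses(
    traits: np.ndarray,
    groups: np.ndarray,
    bank: ItemBank,
    rng: np.random.Generator,
) -> ResponseData:
    """Simulate the N x J response matrix: X_ij ~ Bernoulli(P(theta_i, delta_j)).

    Items are answered independently given theta (local independence), always
    from the simulation-truth difficulties.
    """
    traits = np.asarray(traits, dtype=float)
    groups = np.asarray(groups)
    if traits.shape != groups.shape:
        raise ValueError("traits and groups must have the same length")
    probs = expit(traits[:, None] - bank.difficulties[None, :])
    responses = (rng.random(probs.shape) < probs).astype(np.int8)
    return ResponseData(responses=responses, groups=groups, latent_traits=traits)
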