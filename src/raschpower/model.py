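"""Marginal maximum likelihood estimation of the Rasch model with a group
effect, in the statsmodels Model/Results style.

The observed data are an N x J binary matrix with two groups.  The latent
trait is integrated out against its group-specific normal distribution
N(mu1 + d*g_i, sigma^2) with fixed (non-adaptive) Gauss--Hermite quadrature,
and the free parameters are maximised by quasi-Newton iteration with analytic
gradients.  Three analysis regimes are supported:

* Situation 1 — mu1 and all item difficulties fixed (only d, sigma^2 free);
* Situation 2 — difficulties fixed, mu1 estimated;
* Situation 3 — everything estimated, with the identifiability constraint
  sum_j delta_j = 0 (mu1 absorbs the location).

Because the Rasch model's person-side sufficient statistic is the sum score,
the marginal likelihood is accumulated over (group, sum score) cells rather
than patients, which makes fits cheap even for J = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess3

from .generative import ResponseData

__all__ = [
    "FitSpecification",
    "RaschParams",
    "RaschModel",
    "RaschResults",
    "TestResult",
    "FitError",
    "marginal_loglikelihood",
    "fit_rasch_mml",
    "wald_test_group_effect",
]

_SQRT2 = np.sqrt(2.0)


class FitError(RuntimeError):
    """Raised when a fit is unusable (e.g. Wald test on a non-converged fit)."""


@dataclass(frozen=True)
class FitSpecification:
    """Which parameters are fixed at analysis time, and estimation controls.

    ``situation`` follows the study-design taxonomy: 1 = person and item
    parameters known (randomised trial with an instrument validated on the
    same population); 2 = item parameters known, latent mean shift estimated;
    3 = nothing known (classically validated instrument).
    """

    situation: int = 3
    fixed_mu1: float | None = None
    fixed_difficulties: np.ndarray | None = None
    quadrature_nodes: int = 61
    max_iterations: int = 500
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.situation not in (1, 2, 3):
            raise ValueError("situation must be 1, 2 or 3")
        if self.fixed_difficulties is not None:
            fd = np.asarray(self.fixed_difficulties, dtype=float)
            object.__setattr__(self, "fixed_difficulties", fd)
        if self.situation == 1 and (self.fixed_mu1 is None or self.fixed_difficulties is None):
            raise ValueError("situation 1 requires both fixed_mu1 and fixed_difficulties")
        if self.situation == 2 and (
            self.fixed_mu1 is not None or self.fixed_difficulties is None
        ):
            raise ValueError("situation 2 fixes the difficulties only")
        if self.situation == 3 and (
            self.fixed_mu1 is not None or self.fixed_difficulties is not None
        ):
            raise ValueError("situation 3 estimates all parameters")
        if self.quadrature_nodes < 2:
            raise ValueError("quadrature_nodes must be >= 2")


@dataclass(frozen=True)
class RaschParams:
    """A full parameter bundle (natural scale) for likelihood evaluation."""

    d: float
    sigma2: float
    mu1: float = 0.0
    difficulties: np.ndarray | None = None


@dataclass(frozen=True)
class TestResult:
    """Outcome of a significance test of the group effect."""

    statistic: float
    p_value: float
    alpha: float
    significant: bool
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significant flag inconsistent with p_value and alpha")


def _suffstats(data: ResponseData) -> tuple[np.ndarray, np.ndarray]:
    """Counts n[g, s] of patients in group g with sum score s, and per-item
    positive-response totals T[j]."""
    J = data.n_items
    scores = data.responses.sum(axis=1)
    counts = np.zeros((2, J + 1))
    for g in (0, 1):
        counts[g] = np.bincount(scores[data.groups == g], minlength=J + 1)
    totals = data.responses.sum(axis=0).astype(float)
    return counts, totals


def _loglik_core(
    mu1: float,
    d: float,
    sigma: float,
    delta: np.ndarray,
    counts: np.ndarray,
    totals: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
    want_grad: bool,
):
    """Marginal log-likelihood (and gradient) aggregated over sum scores.

    For a patient in group g with score s the marginal probability is
    exp(-sum_j x_ij delta_j) * Integral exp(s*theta - C(theta)) dPhi(theta),
    with C(theta) = sum_j log(1 + exp(theta - delta_j)); the pattern-specific
    factor sums to -sum_j delta_j T_j over the sample.
    """
    J = delta.size
    s = np.arange(J + 1, dtype=float)
    mu = np.array([mu1, mu1 + d])
    theta = mu[:, None] + _SQRT2 * sigma * nodes[None, :]  # (2, Q)
    z = theta[:, :, None] - delta[None, None, :]  # (2, Q, J)
    C = np.logaddexp(0.0, z).sum(axis=2)  # (2, Q)
    # log integrand per (group, score, node)
    M = s[None, :, None] * theta[:, None, :] - C[:, None, :] + log_weights[None, None, :]
    logf = logsumexp(M, axis=2)  # (2, J+1)
    ll = float(-(delta * totals).sum() + (counts * logf).sum())
    if not want_grad:
        return ll, None
    P = expit(z)  # (2, Q, J)
    Cp = P.sum(axis=2)  # (2, Q)
    w = np.exp(M - logf[:, :, None])  # posterior node weights, (2, J+1, Q)
    A = s[None, :, None] - Cp[:, None, :]  # d log integrand / d theta
    dll_dmu_g = (counts * (w * A).sum(axis=2)).sum(axis=1)  # (2,)
    g_mu1 = float(dll_dmu_g.sum())
    g_d = float(dll_dmu_g[1])
    g_sigma = float(
        (counts * (w * A * (_SQRT2 * nodes)[None, None, :]).sum(axis=2)).sum()
    )
    node_mass = (counts[:, :, None] * w).sum(axis=1)  # (2, Q)
    g_delta = -totals + np.einsum("gk,gkj->j", node_mass, P)
    return ll, (g_mu1, g_d, g_sigma, g_delta)


def marginal_loglikelihood(
    params: RaschParams, data: ResponseData, spec: FitSpecification
) -> float:
    """Evaluate the marginal log-likelihood at a full parameter bundle.

    Fixed components declared by ``spec`` take precedence over the bundle.
    """
    if not (params.sigma2 > 0.0):
        raise ValueError("sigma2 must be positive")
    if data.n_patients == 0:
        raise ValueError("data must be non-empty")
    mu1 = spec.fixed_mu1 if spec.fixed_mu1 is not None else params.mu1
    if spec.fixed_difficulties is not None:
        delta = np.asarray(spec.fixed_difficulties, dtype=float)
    elif params.difficulties is not None:
        delta = np.asarray(params.difficulties, dtype=float)
    else:
        raise ValueError("difficulties must be supplied by params or spec")
    if delta.size != data.n_items:
        raise ValueError("difficulties length must equal the number of items")
    counts, totals = _suffstats(data)
    nodes, weights = hermgauss(spec.quadrature_nodes)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)
    ll, _ = _loglik_core(
        float(mu1), float(params.d), float(np.sqrt(params.sigma2)), delta,
        counts, totals, nodes, log_weights, want_grad=False,
    )
    return ll


class RaschModel:
    """Two-group Rasch model estimated by marginal maximum likelihood.

    Parameters
    ----------
    data : ResponseData
        Binary response matrix with 0/1 group labels.
    spec : FitSpecification, optional
        Analysis regime and estimation controls; defaults to Situation 3
        (all parameters estimated) with 61 quadrature nodes.

    Notes
    -----
    In Situation 3, items answered identically by every patient carry no
    finite difficulty estimate; they are excluded from estimation and listed
    in ``excluded_items`` on the results object.
    """

    def __init__(self, data: ResponseData, spec: FitSpecification | None = None):
        if spec is None:
            spec = FitSpecification(situation=3)
        if spec.fixed_difficulties is not None and (
            spec.fixed_difficulties.size != data.n_items
        ):
            raise ValueError("fixed_difficulties length must equal the number of items")
        for g in (0, 1):
            if int((data.groups == g).sum()) < 2:
                raise ValueError("each group needs at least 2 patients")
        self.data = data
        self.spec = spec
        self.excluded_items: tuple[int, ...] = ()
        responses = data.responses
        if spec.situation == 3:
            col = responses.sum(axis=0)
            bad = (col == 0) | (col == responses.shape[0])
            if bad.any():
                self.excluded_items = tuple(int(j) for j in np.flatnonzero(bad))
                responses = responses[:, ~bad]
                if responses.shape[1] == 0:
                    raise ValueError("no estimable items: all items are constant")
        self._responses = responses
        self.n_items_used = responses.shape[1]
        self._counts, self._totals = _suffstats(
            ResponseData(responses=responses, groups=data.groups)
        )
        self._nodes, w = hermgauss(spec.quadrature_nodes)
        self._log_weights = np.log(w) - 0.5 * np.log(np.pi)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: FitSpecification | None = None
    ) -> "RaschModel":
        """Build from a tidy frame with a ``group`` column and item columns."""
        return cls(ResponseData.from_dataframe(df), spec=spec)

    # -- free-parameter packing ------------------------------------------
    # situation 1: x = [d, log sigma]
    # situation 2: x = [mu1, d, log sigma]
    # situation 3: x = [mu1, d, log sigma, delta_1..delta_{J-1}] (sum-zero)

    @property
    def k_params(self) -> int:
        sit = self.spec.situation
        if sit == 1:
            return 2
        if sit == 2:
            return 3
        return 3 + self.n_items_used - 1

    def param_names(self) -> list[str]:
        sit = self.spec.situation
        names = [] if sit == 1 else ["mu1"]
        names += ["d", "log_sigma"]
        if sit == 3:
            names += [f"delta{j + 1}" for j in range(self.n_items_used - 1)]
        return names

    def _unpack(self, x: np.ndarray):
        sit = self.spec.situation
        if sit == 1:
            mu1 = float(self.spec.fixed_mu1)
            d, log_sigma = x
            delta = self.spec.fixed_difficulties
        elif sit == 2:
            mu1, d, log_sigma = x
            delta = self.spec.fixed_difficulties
        else:
            mu1, d, log_sigma = x[:3]
            dfree = x[3:]
            delta = np.concatenate([dfree, [-dfree.sum()]])
        return float(mu1), float(d), float(np.exp(log_sigma)), np.asarray(delta, float)

    def start_params(self) -> np.ndarray:
        """mu1 = d = 0, sigma = 1, difficulties from centred per-item logits."""
        sit = self.spec.situation
        if sit == 1:
            return np.zeros(2)
        if sit == 2:
            return np.zeros(3)
        n = self._responses.shape[0]
        pbar = (self._totals + 0.5) / (n + 1.0)
        delta0 = np.log((1.0 - pbar) / pbar)  # difficulty = minus the easiness logit
        delta0 = delta0 - delta0.mean()
        return np.concatenate([np.zeros(3), delta0[:-1]])

    def loglike(self, x: np.ndarray) -> float:
        mu1, d, sigma, delta = self._unpack(np.asarray(x, float))
        ll, _ = _loglik_core(
            mu1, d, sigma, delta, self._counts, self._totals,
            self._nodes, self._log_weights, want_grad=False,
        )
        return ll

    def score(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of ``loglike`` with respect to the free vector."""
        mu1, d, sigma, delta = self._unpack(np.asarray(x, float))
        _, grads = _loglik_core(
            mu1, d, sigma, delta, self._counts, self._totals,
            self._nodes, self._log_weights, want_grad=True,
        )
        g_mu1, g_d, g_sigma, g_delta = grads
        g_log_sigma = g_sigma * sigma
        sit = self.spec.situation
        if sit == 1:
            return np.array([g_d, g_log_sigma])
        if sit == 2:
            return np.array([g_mu1, g_d, g_log_sigma])
        # sum-zero constraint: d ll / d delta_free_j = g_j - g_J
        gfree = g_delta[:-1] - g_delta[-1]
        return np.concatenate([[g_mu1, g_d, g_log_sigma], gfree])

    def fit(self, start_params: np.ndarray | None = None) -> "RaschResults":
        """Maximise the marginal likelihood; never raises on non-convergence
        (the ``converged`` flag is set instead)."""
        x0 = self.start_params() if start_params is None else np.asarray(start_params, float)
        res = minimize(
            lambda x: -self.loglike(x),
            x0,
            jac=lambda x: -self.score(x),
            method="L-BFGS-B",
            options={
                "maxiter": self.spec.max_iterations,
                "ftol": self.spec.tolerance,
                "gtol": 1e-5,
            },
        )
        hess = approx_hess3(res.x, lambda x: -self.loglike(x), epsilon=1e-4)
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.diag(cov))
            se_ok = bool(np.all(np.isfinite(bse)))
        except np.linalg.LinAlgError:
            cov = np.full((res.x.size, res.x.size), np.nan)
            bse = np.full(res.x.size, np.nan)
            se_ok = False
        converged = bool(res.success) and se_ok
        return RaschResults(
            model=self,
            params=res.x,
            cov_params=cov,
            bse=bse,
            llf=float(-res.fun),
            converged=converged,
            n_iterations=int(res.nit),
            message=str(res.message),
        )


@dataclass
class RaschResults:
    """MML estimates, standard errors and diagnostics for a fitted model."""

    model: RaschModel
    params: np.ndarray
    cov_params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n_iterations: int
    message: str = ""

    def __post_init__(self) -> None:
        mu1, d, sigma, delta = self.model._unpack(self.params)
        names = self.model.param_names()
        idx = names.index("d")
        self.d_hat = d
        self.se_d = float(self.bse[idx])
        self.sigma2_hat = sigma * sigma
        ls = names.index("log_sigma")
        # delta method: var(sigma^2) = (2 sigma^2)^2 var(log sigma)
        self.se_sigma2 = float(2.0 * self.sigma2_hat * self.bse[ls])
        self.mu1_hat = mu1 if self.model.spec.situation != 1 else None
        self.difficulties_hat = delta.copy() if self.model.spec.situation == 3 else None
        self.excluded_items = self.model.excluded_items

    def wald_test(self, alpha: float = 0.05) -> TestResult:
        return wald_test_group_effect(self, alpha)

    def to_record(self) -> dict:
        """Flat key-value record (one CSV row) of the fit."""
        rec = {
            "d_hat": self.d_hat,
            "se_d": self.se_d,
            "sigma2_hat": self.sigma2_hat,
            "se_sigma2": self.se_sigma2,
            "mu1_hat": self.mu1_hat if self.mu1_hat is not None else np.nan,
            "loglik": self.llf,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "situation": self.model.spec.situation,
            "n_items_used": self.model.n_items_used,
            "n_excluded_items": len(self.excluded_items),
        }
        if self.difficulties_hat is not None:
            for j, dj in enumerate(self.difficulties_hat):
                rec[f"delta{j + 1}_hat"] = float(dj)
        return rec

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Rasch model, marginal maximum likelihood",
            "=" * 54,
            f"Situation:            {spec.situation}",
            f"Patients:             {self.model.data.n_patients}"
            f"  (group sizes {int((self.model.data.groups == 0).sum())}"
            f"/{int((self.model.data.groups == 1).sum())})",
            f"Items used:           {self.model.n_items_used}"
            + (f"  (excluded: {list(self.excluded_items)})" if self.excluded_items else ""),
            f"Quadrature nodes:     {spec.quadrature_nodes}",
            f"Log-likelihood:       {self.llf:.4f}",
            f"Converged:            {self.converged} ({self.n_iterations} iterations)",
            "-" * 54,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
        ]
        rows = [("d (group)", self.d_hat, self.se_d), ("sigma2", self.sigma2_hat, self.se_sigma2)]
        if self.mu1_hat is not None:
            mu_idx = self.model.param_names().index("mu1")
            rows.insert(0, ("mu1", self.mu1_hat, float(self.bse[mu_idx])))
        for name, est, se in rows:
            lines.append(f"{name:<12}{est:>12.4f}{se:>12.4f}")
        if self.difficulties_hat is not None:
            for j, dj in enumerate(self.difficulties_hat):
                lines.append(f"{'delta' + str(j + 1):<12}{dj:>12.4f}{'':>12}")
        lines.append("=" * 54)
        return "\n".join(lines)


def fit_rasch_mml(data: ResponseData, spec: FitSpecification) -> RaschResults:
    """Convenience wrapper: build a :class:`RaschModel` and fit it."""
    return RaschModel(data, spec=spec).fit()


def wald_test_group_effect(fit: RaschResults, alpha: float = 0.05) -> TestResult:
    """Two-sided Wald test of d = 0 against a standard normal reference."""
    if not fit.converged:
        raise FitError("Wald test requires a converged fit")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    stat = fit.d_hat / fit.se_d
    p = float(2.0 * norm.sf(abs(stat)))
    return TestResult(
        statistic=float(stat), p_value=p, alpha=alpha,
        significant=bool(p < alpha), method="wald",
    )
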