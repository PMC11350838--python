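"""Site-stratified logistic regression core.

All fitting stages share this module: covariate encoding with per-site
fixed intercepts (the unconditional-ML analogue of conditioning on study
site; with five large strata it is asymptotically equivalent to conditional
logistic likelihood), Newton-Raphson maximum likelihood with an optional
per-row log-odds offset, and Wald odds-ratio machinery.

Column order of the design matrix is fixed and documented: site indicators
(sorted site labels, no global intercept), then for each requested
adjustment covariate -- ``male`` indicator, age centered at 60 years
(``age_c60``), smoking-status indicators with never as reference
(``smoke_former``, ``smoke_current``), then ``age_start_smoking``,
``years_since_quit``, ``pack_years`` as continuous with 0 for
non-applicable subjects (the status indicators absorb the level shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ADJUSTMENT_FIELDS",
    "AGE_CENTER",
    "DesignSpec",
    "LogisticFit",
    "SeparationError",
    "encode_covariates",
    "fit_logistic",
    "wald_or_ci",
    "bernoulli_loglik",
]

ADJUSTMENT_FIELDS = (
    "sex",
    "age",
    "smoking_status",
    "age_start_smoking",
    "years_since_quit",
    "pack_years",
)

AGE_CENTER = 60.0

#: coefficients beyond this magnitude on the log-odds scale are treated as
#: diverging (complete or quasi-complete separation).
SEPARATION_BOUND = 20.0


class SeparationError(RuntimeError):
    """Degenerate outcome structure (e.g. all-case or all-control data)."""


@dataclass(frozen=True)
class DesignSpec:
    """Which adjustment covariates enter the model.

    Site stratum intercepts are always present.  ``adjust`` defaults to the
    full six-covariate set (sex, age, smoking status, age at initiation,
    time since cessation, pack-years); stratified analyses drop entries.
    """

    adjust: tuple[str, ...] = ADJUSTMENT_FIELDS

    def __post_init__(self) -> None:
        unknown = set(self.adjust) - set(ADJUSTMENT_FIELDS)
        if unknown:
            raise ValueError(f"unknown adjustment fields: {sorted(unknown)}")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    ``params`` and ``cov`` are indexed by column name on the log-odds
    scale; ``cov`` is the inverse observed information.  The identity
    ``aic == 2*n_params - 2*loglik`` holds exactly.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    n_params: int
    converged: bool
    separation: bool
    n_iter: int
    n_obs: int


def encode_covariates(cohort: pd.DataFrame, spec: DesignSpec = DesignSpec()):
    """Build the (design matrix, response) pair for a cohort table.

    Returns ``(X, y)`` with ``X`` a float DataFrame (named columns in the
    documented order) and ``y`` an int array of case indicators.  Raises if
    any site lacks cases or controls (a perfect-separation hazard for its
    stratum intercept), naming the offending site.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    y = cohort["is_case"].to_numpy(int)
    sites = sorted(cohort["site"].astype(str).unique())
    for s in sites:
        ys = y[(cohort["site"].astype(str) == s).to_numpy()]
        if ys.min() == ys.max():
            raise SeparationError(
                f"site {s!r} has only {'cases' if ys[0] else 'controls'}; "
                "its stratum intercept is not estimable"
            )
    cols: dict[str, np.ndarray] = {}
    site_arr = cohort["site"].astype(str).to_numpy()
    for s in sites:
        cols[f"site_{s}"] = (site_arr == s).astype(float)
    for fieldname in spec.adjust:
        if fieldname == "sex":
            cols["male"] = (cohort["sex"] == "male").to_numpy(float)
        elif fieldname == "age":
            cols["age_c60"] = cohort["age"].to_numpy(float) - AGE_CENTER
        elif fieldname == "smoking_status":
            cols["smoke_former"] = (cohort["smoking_status"] == "former").to_numpy(float)
            cols["smoke_current"] = (cohort["smoking_status"] == "current").to_numpy(float)
        else:
            cols[fieldname] = cohort[fieldname].to_numpy(float)
    X = pd.DataFrame(cols, index=cohort.index)
    return X, y


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor ``eta`` (log-odds)."""
    # log p = -log(1+e^-eta); log(1-p) = -log(1+e^eta); stable via logaddexp
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_logistic(X, y, offset=None, max_iter: int = 100, start=None) -> LogisticFit:
    """Newton-Raphson maximum likelihood for a Bernoulli log-odds model.

    ``offset`` is an optional fixed per-row log-odds term (used by the
    excess-odds-ratio profiling machinery).  Convergence is declared when
    the maximum absolute score drops below 1e-8 or the relative
    log-likelihood change falls below 1e-10.  The design must be full rank
    (singular-value ratio tolerance 1e-8).  Coefficients diverging beyond
    |20| set the ``separation`` flag with a warning; an outcome vector with
    a single class raises :class:`SeparationError`.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, int)
    n, k = Xm.shape
    if n != len(y):
        raise ValueError("X and y length mismatch")
    if y.min() == y.max():
        raise SeparationError("response is constant; logistic model is degenerate")
    sv = np.linalg.svd(Xm, compute_uv=False)
    if sv[-1] <= 1e-8 * sv[0]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (singular-value ratio {sv[-1] / sv[0]:.2e})"
        )
    off = np.zeros(n) if offset is None else np.asarray(offset, float)

    beta = np.zeros(k) if start is None else np.asarray(start, float).copy()
    eta = Xm @ beta + off
    ll = bernoulli_loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        score = Xm.T @ (y - p)
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        H = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # damped Newton: halve until the log-likelihood does not decrease
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = bernoulli_loglik(y, Xm @ cand + off)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        eta = Xm @ beta + off
        ll_prev, ll = ll, bernoulli_loglik(y, eta)
        if abs(ll - ll_prev) < 1e-10 * (abs(ll_prev) + 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(f"logistic fit did not converge in {max_iter} iterations")

    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    if separation:
        warnings.warn(
            "coefficient magnitude exceeds 20 on the log-odds scale; "
            "possible complete separation -- estimates are unreliable"
        )
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Xm * w[:, None]).T @ Xm
    cov = np.linalg.inv(H)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        n_params=k,
        converged=converged,
        separation=separation,
        n_iter=it,
        n_obs=n,
    )


def wald_or_ci(fit: LogisticFit, contrast, level: float = 0.95):
    """Odds ratio with Wald CI and two-sided p for a coefficient contrast.

    ``contrast`` is a vector c of length ``fit.n_params``; returns
    ``(OR, lower, upper, p)`` with OR = exp(c'beta) and the normal-
    approximation interval exp(c'beta +/- z*sqrt(c'Sigma c)).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be strictly inside (0, 1)")
    c = np.asarray(contrast, float)
    if c.shape != (fit.n_params,):
        raise ValueError(f"contrast length {c.shape} != n_params {fit.n_params}")
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(max(c @ fit.cov.to_numpy() @ c, 0.0)))
    z = norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        return np.exp(est), np.exp(est), np.exp(est), p
    p = 2.0 * norm.sf(abs(est) / se)
    return float(np.exp(est)), float(np.exp(est - z * se)), float(np.exp(est + z * se)), float(p)
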