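"""Parametric excess-odds-ratio (EOR) dose-response models.

Five risk models link sIR exposure d (Bq/m^3) to the case odds ratio:

- ``logit``     OR(d) = exp(beta * d/100)            (log-linear)
- ``lnt``       OR(d) = 1 + beta * d/100             (linear no-threshold)
- ``lnt_plus``  OR(d) = 1 + beta * (d - delta)/100   (shifted linear)
- ``lt``        OR(d) = 1 + beta * max(0, d-delta)/100  (linear threshold)
- ``lmp``       OR(d) = 1 + beta * |d - delta|/100   (linear mirror point)

beta is the excess odds ratio per 100 Bq/m^3 (internally the models work
per Bq/m^3); delta is a threshold / shift / mirror point in Bq/m^3.  The
subject-level likelihood is Bernoulli with odds

    exp(site intercept + covariate terms) * (1 + beta * g(d; delta)),

maximised jointly over (covariates, beta) by Fisher scoring with a
positivity barrier at 1 + beta*g > 1e-6.  delta is profiled on a grid
(non-smooth likelihood: the kinks make grid profiling the robust choice);
the beta confidence interval is profile likelihood at the chi-square(1)
cutoff 3.841, the delta interval is the set of grid points within 1.92
log-likelihood units of the maximum.

Note: with free stratum intercepts the ``lnt_plus`` shift is not
identifiable (1 + beta*(d-delta)/100 rescales to an LNT model with a
different baseline), so its profile log-likelihood is flat in delta; ties
resolve to the smallest grid value.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .logistic import DesignSpec, encode_covariates, fit_logistic, bernoulli_loglik

__all__ = ["PARAMETRIC_KINDS", "EORFit", "eor_curve", "fit_eor", "compare_models", "sample_curves"]

PARAMETRIC_KINDS = ("logit", "lnt", "lnt_plus", "lt", "lmp")

CHI2_1_95 = 3.841458820694124  # chi-square(1) 95% quantile
_HALF_CUT = CHI2_1_95 / 2.0


def _g(kind: str, d: np.ndarray, delta: float) -> np.ndarray:
    """Dose transform g(d; delta) in Bq/m^3 units so OR = 1 + beta_int*g."""
    if kind == "lnt":
        return d
    if kind == "lnt_plus":
        return d - delta
    if kind == "lt":
        return np.maximum(0.0, d - delta)
    if kind == "lmp":
        return np.abs(d - delta)
    raise ValueError(f"kind {kind!r} has no excess-odds-ratio dose transform")


@dataclass
class EORFit:
    """A fitted parametric dose-response model.

    ``beta`` is the EOR per 100 Bq/m^3 with a profile-likelihood CI;
    ``delta`` (Bq/m^3) carries a profile-grid interval and is ``None`` for
    the logit and LNT models.  ``lre_implied`` is the exposure of minimum
    modelled risk over the observed exposure range.
    """

    kind: str
    beta: float
    beta_ci: tuple[float, float]
    delta: float | None
    delta_ci: tuple[float, float] | None
    loglik: float
    aic: float
    n_params: int
    lre_implied: float
    covariate_params: pd.Series
    converged: bool
    fingerprint: str
    exposure_range: tuple[float, float]
    beta_se: float = float("nan")
    profile: pd.DataFrame | None = field(default=None, repr=False)


def eor_curve(fit_or_kind, d, beta: float | None = None, delta: float | None = None) -> np.ndarray:
    """OR(d) of a parametric model relative to its zero-excess level.

    Accepts either an :class:`EORFit` or ``(kind, beta, delta)`` scalars;
    ``beta`` on the per-100-Bq/m^3 scale.  Raises if the curve is
    non-positive at any requested exposure.
    """
    if isinstance(fit_or_kind, EORFit):
        kind, beta, delta = fit_or_kind.kind, fit_or_kind.beta, fit_or_kind.delta
    else:
        kind = fit_or_kind
    d = np.asarray(d, float)
    b = beta / 100.0
    if kind == "logit":
        return np.exp(b * d)
    out = 1.0 + b * _g(kind, d, 0.0 if delta is None else delta)
    if np.any(out <= 0.0):
        raise ValueError(f"{kind} curve non-positive at some requested exposures")
    return out


def _fingerprint(y: np.ndarray, d: np.ndarray, X: pd.DataFrame) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(np.round(np.ascontiguousarray(d), 9).tobytes())
    h.update(",".join(X.columns).encode())
    return h.hexdigest()[:16]


def _beta_bounds(g: np.ndarray, tol: float = 1e-6) -> tuple[float, float]:
    """Admissible open interval for beta_int keeping 1 + beta*g > tol."""
    gmax = float(g.max(initial=0.0))
    gmin = float(g.min(initial=0.0))
    lo = -np.inf if gmax <= 0 else (tol - 1.0) / gmax
    hi = np.inf if gmin >= 0 else (tol - 1.0) / gmin
    return lo, hi


def _fit_fixed_delta(Xm, y, g, gamma0, beta0=0.0, max_iter=200):
    """Fisher-scoring fit of (gamma, beta_int) for fixed dose transform g.

    Returns (gamma, beta_int, loglik, fisher_information, converged).
    """
    n, k = Xm.shape
    lo_b, hi_b = _beta_bounds(g)
    gamma = np.asarray(gamma0, float).copy()
    beta = float(np.clip(beta0, lo_b + 1e-9 if np.isfinite(lo_b) else beta0,
                         hi_b - 1e-9 if np.isfinite(hi_b) else beta0))

    def loglik(gm, bt):
        eta = Xm @ gm + np.log1p(bt * g)
        return bernoulli_loglik(y, eta)

    ll = loglik(gamma, beta)
    converged = False
    I = None
    for _ in range(max_iter):
        u = 1.0 + beta * g
        eta = Xm @ gamma + np.log(u)
        p = expit(eta)
        a = g / u
        r = y - p
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = np.concatenate([Xm.T @ r, [float(a @ r)]])
        if np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
        Xa = Xm * w[:, None]
        I = np.empty((k + 1, k + 1))
        I[:k, :k] = Xa.T @ Xm
        I[:k, k] = Xm.T @ (w * a)
        I[k, :k] = I[:k, k]
        I[k, k] = float(w @ (a * a))
        try:
            step = np.linalg.solve(I, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(I, grad, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            bt = beta + t * step[k]
            if (bt <= lo_b) or (bt >= hi_b):
                t /= 2.0
                continue
            ll_new = loglik(gamma + t * step[:k], bt)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        else:
            converged = True  # no admissible improving step; at a boundary optimum
            break
        gamma = gamma + t * step[:k]
        beta = beta + t * step[k]
        ll_prev, ll = ll, loglik(gamma, beta)
        if abs(ll - ll_prev) < 1e-11 * (abs(ll_prev) + 1.0):
            converged = True
            break
    if I is None:
        u = 1.0 + beta * g
        p = expit(Xm @ gamma + np.log(u))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        a = g / u
        Xa = Xm * w[:, None]
        I = np.empty((k + 1, k + 1))
        I[:k, :k] = Xa.T @ Xm
        I[:k, k] = Xm.T @ (w * a)
        I[k, :k] = I[:k, k]
        I[k, k] = float(w @ (a * a))
    return gamma, beta, ll, I, converged


def _profile_loglik_beta(Xm, y, g, beta_int, gamma_start):
    """Max log-likelihood over covariates with beta fixed (offset fit)."""
    off = np.log1p(beta_int * g)
    fit = fit_logistic(Xm, y, offset=off, start=gamma_start)
    return fit.loglik, fit.params.to_numpy()


def _profile_beta_ci(Xm, y, g, beta_hat, ll_max, se_int, gamma_hat):
    """Profile-likelihood CI for beta_int at the chi2(1) 0.95 cutoff."""
    lo_b, hi_b = _beta_bounds(g)
    step = max(se_int, 1e-6) if np.isfinite(se_int) and se_int > 0 else 1e-3

    def deficit(b):
        ll, _ = _profile_loglik_beta(Xm, y, g, b, gamma_hat)
        return (ll_max - ll) - _HALF_CUT

    def bound(direction):
        b0 = beta_hat
        for i in range(1, 60):
            b1 = beta_hat + direction * step * (1.6 ** i)
            if b1 <= lo_b:
                b1 = lo_b + 1e-12 + (beta_hat - lo_b) * 1e-9
            if b1 >= hi_b:
                b1 = hi_b - 1e-12 - (hi_b - beta_hat) * 1e-9
            d1 = deficit(b1)
            if d1 > 0:
                return optimize.brentq(deficit, b0, b1, xtol=1e-9) if b0 != b1 else b1
            b0 = b1
            if b1 in (lo_b, hi_b) or abs(b1 - beta_hat) > 1e6 * step:
                break
        return b0  # boundary-limited

    return bound(-1.0), bound(+1.0)


def _implied_lre(kind, beta100, delta, d_lo, d_hi) -> float:
    grid = np.linspace(d_lo, d_hi, 2048)
    curve = eor_curve(kind, grid, beta=beta100, delta=delta)
    return float(grid[int(np.argmin(curve))])


def fit_eor(
    cohort: pd.DataFrame,
    kind: str,
    design: DesignSpec = DesignSpec(),
    delta_grid=None,
    profile_ci: bool = True,
) -> EORFit:
    """Fit one parametric dose-response model by maximum likelihood.

    For threshold-type kinds (``lnt_plus``, ``lt``, ``lmp``) the
    threshold ``delta`` is profiled over ``delta_grid`` (default 0..200
    Bq/m^3 in 1-unit steps, clipped to the 99th exposure percentile); grid
    points where the dose transform vanishes everywhere are skipped with a
    warning.  ``profile_ci=False`` skips the beta profile interval (Wald
    interval from the Fisher information is still reported), useful inside
    large simulation loops.
    """
    if kind not in PARAMETRIC_KINDS:
        raise ValueError(f"unknown parametric kind {kind!r}")
    X, y = encode_covariates(cohort, design)
    d = cohort["sir"].to_numpy(float)
    fp = _fingerprint(y, d, X)
    d_lo, d_hi = float(d.min()), float(d.max())

    if kind == "logit":
        X2 = X.copy()
        X2["sir_per100"] = d / 100.0
        fit = fit_logistic(X2, y)
        beta = float(fit.params["sir_per100"])
        se = float(np.sqrt(fit.cov.loc["sir_per100", "sir_per100"]))
        if profile_ci:
            Xm = X.to_numpy(float)
            gam = fit.params.drop("sir_per100").to_numpy()
            g100 = d / 100.0

            def prof(b):
                return fit_logistic(Xm, y, offset=b * g100, start=gam).loglik

            ll_max = fit.loglik

            def deficit(b):
                return (ll_max - prof(b)) - _HALF_CUT

            lo = optimize.brentq(deficit, beta - 20 * se, beta, xtol=1e-7) \
                if deficit(beta - 20 * se) > 0 else beta - 20 * se
            hi = optimize.brentq(deficit, beta, beta + 20 * se, xtol=1e-7) \
                if deficit(beta + 20 * se) > 0 else beta + 20 * se
            ci = (lo, hi)
        else:
            ci = (beta - 1.959964 * se, beta + 1.959964 * se)
        lre = d_lo if beta > 0 else d_hi
        return EORFit(
            kind=kind, beta=beta, beta_ci=ci, delta=None, delta_ci=None,
            loglik=fit.loglik, aic=fit.aic, n_params=fit.n_params,
            lre_implied=lre, covariate_params=fit.params.drop("sir_per100"),
            converged=fit.converged, fingerprint=fp,
            exposure_range=(d_lo, d_hi), beta_se=se,
        )

    Xm = X.to_numpy(float)
    k = Xm.shape[1]
    base = fit_logistic(Xm, y)
    gamma0 = base.params.to_numpy()

    if kind == "lnt":
        deltas = [0.0]
        extra_params = 1  # beta only
    else:
        if delta_grid is None:
            delta_grid = np.arange(0.0, 201.0, 1.0)
        hi_cap = float(np.quantile(d, 0.99))
        deltas = [float(x) for x in np.asarray(delta_grid, float) if 0.0 <= x <= hi_cap]
        if not deltas:
            raise ValueError("delta grid is empty after clipping to the 99th exposure percentile")
        extra_params = 2  # beta and delta

    best = None
    profile_rows = []
    gamma_ws, beta_ws = gamma0, 0.0
    for delta in deltas:
        g = _g(kind, d, delta)
        if not np.any(g != 0.0):
            warnings.warn(f"delta = {delta} leaves the dose transform identically zero; skipped")
            continue
        gamma, beta_int, ll, I, conv = _fit_fixed_delta(Xm, y, g, gamma_ws, beta_ws)
        gamma_ws, beta_ws = gamma, beta_int  # warm start along the grid
        profile_rows.append({"delta": delta, "loglik": ll, "beta_per100": beta_int * 100.0})
        if best is None or ll > best[2] + 1e-9:
            best = (gamma, beta_int, ll, I, conv, delta, g)
    if best is None:
        raise ValueError("all delta grid points were skipped; no model could be fitted")

    gamma, beta_int, ll, I, conv, delta_hat, g = best
    prof = pd.DataFrame(profile_rows)
    if kind == "lnt":
        delta_out, delta_ci = None, None
    else:
        delta_out = delta_hat
        ok = prof["loglik"] >= ll - _HALF_CUT
        delta_ci = (float(prof.loc[ok, "delta"].min()), float(prof.loc[ok, "delta"].max()))

    cov = np.linalg.pinv(I)
    se_int = float(np.sqrt(max(cov[k, k], 0.0)))
    if profile_ci:
        lo_i, hi_i = _profile_beta_ci(Xm, y, g, beta_int, ll, se_int, gamma)
        ci = (lo_i * 100.0, hi_i * 100.0)
    else:
        ci = ((beta_int - 1.959964 * se_int) * 100.0, (beta_int + 1.959964 * se_int) * 100.0)

    beta100 = beta_int * 100.0
    n_params = k + extra_params
    return EORFit(
        kind=kind, beta=beta100, beta_ci=ci, delta=delta_out, delta_ci=delta_ci,
        loglik=ll, aic=2.0 * n_params - 2.0 * ll, n_params=n_params,
        lre_implied=_implied_lre(kind, beta100, delta_out or 0.0, d_lo, d_hi),
        covariate_params=pd.Series(gamma, index=X.columns),
        converged=conv, fingerprint=fp, exposure_range=(d_lo, d_hi),
        beta_se=se_int * 100.0, profile=prof,
    )


def compare_models(fits: list[EORFit]) -> pd.DataFrame:
    """Rank parametric fits (same data, same adjustment set) by AIC."""
    if not fits:
        raise ValueError("no fits to compare")
    fps = {f.fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different data (fingerprint mismatch)")
    rows = [
        {
            "kind": f.kind,
            "beta_per100": f.beta,
            "beta_lo": f.beta_ci[0],
            "beta_hi": f.beta_ci[1],
            "delta": f.delta,
            "lre_implied": f.lre_implied,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows)
    table["delta_aic_vs_best"] = table["aic"] - table["aic"].min()
    return table.sort_values("aic", ignore_index=True)


def sample_curves(fits: list[EORFit], step: float = 1.0) -> pd.DataFrame:
    """Evaluate each fitted OR curve on a common exposure grid for export."""
    lo = min(f.exposure_range[0] for f in fits)
    hi = max(f.exposure_range[1] for f in fits)
    grid = np.arange(np.ceil(lo), np.floor(hi) + step / 2, step)
    out = pd.DataFrame({"sir": grid})
    for f in fits:
        out[f.kind] = eor_curve(f, grid)
    return out
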