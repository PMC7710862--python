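"""Experience-dependent colour-discrimination functions.

Psychometric curves :math:`\\pi(\\Delta C)` give the probability that a bee
correctly discriminates two colours separated by a hexagon distance
:math:`\\Delta C` (Hu).  Two closed forms are used, keyed by parameter
count:

* ``logistic3`` (successive viewing, one form per training colour):

  .. math:: \\pi = \\frac{M_o K}{M_o + (K - M_o)\\,e^{-r\\,\\Delta C}}

  ``K`` is the upper limit, ``Mo`` the value at :math:`\\Delta C = 0` and
  ``r`` the increment rate per Hu.

* ``logistic4`` (absolute conditioning):

  .. math:: \\pi = M_o + \\frac{K - M_o}{1 + e^{(xmid - \\Delta C)/scal}}

  ``K``/``Mo`` are the upper/lower asymptotes, ``xmid`` the inflection
  distance and ``scal`` the rate scale (both in Hu).

Because the behavioural task is two-alternative, reported probabilities are
clamped at the 0.5 chance floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LOGISTIC3",
    "LOGISTIC4",
    "DiscriminationFunction",
    "ChoiceDataset",
    "ModelComparison",
    "BootstrapResult",
    "eval_discrimination",
    "threshold_distance",
    "fit_discrimination",
    "lrt_compare",
    "bootstrap_mean_equality",
]

LOGISTIC3 = "logistic3"
LOGISTIC4 = "logistic4"

_PARAM_ORDER = {LOGISTIC3: ("K", "r", "Mo"), LOGISTIC4: ("K", "Mo", "xmid", "scal")}


def _logistic3(dc, K, r, Mo):
    return Mo * K / (Mo + (K - Mo) * np.exp(-r * dc))


def _logistic4(dc, K, Mo, xmid, scal):
    z = np.clip((xmid - dc) / scal, -700.0, 700.0)
    return Mo + (K - Mo) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class DiscriminationFunction:
    """A fitted or fixture psychometric curve.

    ``coefficients`` maps names to values in the canonical order of
    ``_PARAM_ORDER[form]``; ``ci95`` optionally maps the same names to
    (low, high) 95% intervals; ``loglik`` carries the fitted Gaussian
    log-likelihood when the object came from :func:`fit_discrimination`.
    """

    form: str
    coefficients: dict[str, float]
    clamp_floor: float = 0.5
    ci95: dict[str, tuple[float, float]] | None = None
    loglik: float | None = None
    n_obs: int | None = None
    n_params: int | None = None
    random_param: str | None = None

    def __post_init__(self) -> None:
        if self.form not in _PARAM_ORDER:
            raise ValueError(f"unknown form {self.form!r}")
        missing = set(_PARAM_ORDER[self.form]) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")
        c = self.coefficients
        if self.form == LOGISTIC3:
            if c["r"] <= 0 or c["Mo"] <= 0 or c["K"] < c["Mo"]:
                raise ValueError("logistic3 needs r > 0 and 0 < Mo <= K")
        else:
            if c["scal"] <= 0 or c["xmid"] < 0 or c["K"] < c["Mo"]:
                raise ValueError("logistic4 needs scal > 0, xmid >= 0, Mo <= K")

    # -- evaluation ---------------------------------------------------------
    def __call__(self, dc, clamp: bool = True):
        return eval_discrimination(self, dc, clamp=clamp)

    def threshold(self, target: float = 0.75) -> float:
        return threshold_distance(self, target)

    @property
    def K(self) -> float:
        return self.coefficients["K"]

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "form": self.form,
            "coefficients": dict(self.coefficients),
            "clamp_floor": self.clamp_floor,
        }
        if self.ci95 is not None:
            out["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        if self.loglik is not None:
            out["loglik"] = self.loglik
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminationFunction":
        ci = d.get("ci95")
        return cls(
            form=d["form"],
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            clamp_floor=float(d.get("clamp_floor", 0.5)),
            ci95={k: (float(v[0]), float(v[1])) for k, v in ci.items()} if ci else None,
            loglik=d.get("loglik"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiscriminationFunction":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def eval_discrimination(fn: DiscriminationFunction, dc, clamp: bool = True):
    """Evaluate :math:`\\pi(\\Delta C)`; with ``clamp`` the result never
    falls below the two-alternative chance floor (0.5 by default)."""
    dc = np.asarray(dc, dtype=float)
    if np.any(dc < 0):
        raise ValueError("colour distances must be non-negative")
    c = fn.coefficients
    if fn.form == LOGISTIC3:
        pi = _logistic3(dc, c["K"], c["r"], c["Mo"])
    else:
        pi = _logistic4(dc, c["K"], c["Mo"], c["xmid"], c["scal"])
    if clamp:
        pi = np.maximum(pi, fn.clamp_floor)
    return float(pi) if pi.ndim == 0 else pi


def threshold_distance(fn: DiscriminationFunction, target: float = 0.75) -> float:
    """The unique :math:`\\Delta C` with :math:`\\pi(\\Delta C) =` ``target``
    (e.g. the pi75 threshold), by monotone root finding to 1e-8 Hu.

    Raises
    ------
    ValueError
        If ``target`` is at or above the upper asymptote K, or at or below
        the function's value at zero distance (no solution exists).
    """
    lo_val = eval_discrimination(fn, 0.0, clamp=False)
    if not (max(lo_val, fn.clamp_floor) < target < fn.K):
        raise ValueError(
            f"target {target} outside the attainable range "
            f"({max(lo_val, fn.clamp_floor):.3f}, {fn.K:.3f})"
        )
    f = lambda dc: eval_discrimination(fn, dc, clamp=False) - target
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - guarded by the K check above
            raise ValueError("no solution below 1e6 Hu")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# Choice data
# ---------------------------------------------------------------------------

@dataclass
class ChoiceDataset:
    """Per-subject choice proportions at a set of colour distances.

    ``data`` holds columns ``subject_id``, ``delta_c_hu`` and either
    (``n_correct``, ``n_trials``) or ``proportion_correct``; a proportion
    column is derived if absent.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"subject_id", "delta_c_hu"}
        if not required <= set(df.columns):
            raise ValueError(f"choice data needs columns {sorted(required)}")
        if "proportion_correct" not in df.columns:
            if not {"n_correct", "n_trials"} <= set(df.columns):
                raise ValueError("need n_correct/n_trials or proportion_correct")
            df["proportion_correct"] = df["n_correct"] / df["n_trials"]
        if ((df["proportion_correct"] < 0) | (df["proportion_correct"] > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")
        if (df["delta_c_hu"] < 0).any():
            raise ValueError("colour distances must be non-negative")
        self.data = df

    @property
    def n_levels(self) -> int:
        return self.data["delta_c_hu"].nunique()

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class ModelComparison:
    chi_sq: float
    df: int
    p_value: float
    preferred: str


@dataclass(frozen=True)
class BootstrapResult:
    t_Ho: float
    p_value: float
    n_resamples: int


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _self_start(dc: np.ndarray, y: np.ndarray, form: str) -> np.ndarray:
    """Data-driven starting values: K from the top of the data, Mo from the
    bottom, the rate from the steepest observed rise."""
    order = np.argsort(dc)
    dc_s, y_s = dc[order], y[order]
    K0 = min(max(float(np.max(y)), 0.55), 0.999)
    Mo0 = min(max(float(np.min(y)), 0.45), K0 - 0.01)
    span = max(float(dc_s[-1] - dc_s[0]), 1e-3)
    if form == LOGISTIC3:
        return np.array([K0, 4.0 / span, max(Mo0, 0.45)])
    mid0 = float(dc_s[np.argmin(np.abs(y_s - (K0 + Mo0) / 2.0))])
    return np.array([K0, Mo0, max(mid0, 1e-3), span / 10.0])


def _predict(theta: np.ndarray, dc: np.ndarray, form: str) -> np.ndarray:
    if form == LOGISTIC3:
        return _logistic3(dc, *theta)
    return _logistic4(dc, *theta)


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    sigma2 = float(np.mean(resid**2))
    sigma2 = max(sigma2, 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _fit_nls(dc, y, form, n_restarts=8, seed=0):
    theta0 = _self_start(dc, y, form)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        start = theta0 if k == 0 else theta0 * rng.lognormal(0.0, 0.25, theta0.size)
        try:
            res = optimize.least_squares(
                lambda th: _predict(th, dc, form) - y, start,
                bounds=_nls_bounds(form), method="trf", max_nfev=5000,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("nonlinear least-squares failed to converge after restarts")
    return best


def _nls_bounds(form):
    if form == LOGISTIC3:
        return (np.array([0.45, 1e-3, 0.3]), np.array([1.2, 1e4, 1.2]))
    return (np.array([0.45, 0.3, 0.0, 1e-5]), np.array([1.2, 1.2, 2.0, 5.0]))


def fit_discrimination(
    data: ChoiceDataset,
    form: str = LOGISTIC3,
    random_param: str | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> DiscriminationFunction:
    """Fit a psychometric curve to choice proportions by nonlinear least
    squares (Gaussian residuals), optionally with a per-subject Gaussian
    random effect on one named coefficient.

    The mixed model marginalises the scalar random effect by Gauss-Hermite
    quadrature (21 nodes) and maximises the marginal likelihood with a
    derivative-free optimiser started from self-starting values; 95%
    confidence intervals come from the numerical Hessian at the optimum.

    Parameters
    ----------
    random_param : str or None
        Name of the coefficient carrying the subject-level deviation
        (e.g. ``"r"``); requires at least two subjects.
    """
    if form not in _PARAM_ORDER:
        raise ValueError(f"unknown form {form!r}")
    names = _PARAM_ORDER[form]
    min_levels = len(names)
    if data.n_levels < min_levels:
        raise ValueError(
            f"{form} needs >= {min_levels} distinct colour-distance levels, "
            f"got {data.n_levels}"
        )
    df = data.data
    dc = df["delta_c_hu"].to_numpy(dtype=float)
    y = df["proportion_correct"].to_numpy(dtype=float)

    if random_param is None:
        res = _fit_nls(dc, y, form, n_restarts=n_restarts, seed=seed)
        theta = res.x
        resid = _predict(theta, dc, form) - y
        ll = _gaussian_loglik(resid)
        ci = _nls_ci(res, resid, names)
        return DiscriminationFunction(
            form=form,
            coefficients=dict(zip(names, map(float, theta))),
            ci95=ci, loglik=ll, n_obs=y.size, n_params=len(names) + 1,
        )

    if random_param not in names:
        raise ValueError(f"{random_param!r} is not a coefficient of {form}")
    if data.n_subjects < 2:
        raise ValueError("a random effect needs at least two subjects")
    return _fit_mixed(df, dc, y, form, names, random_param, n_restarts, seed)


def _nls_ci(res, resid, names):
    n, p = resid.size, res.x.size
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    J = res.jac
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p, np.nan)
    tcrit = stats.t.ppf(0.975, dof)
    return {
        nm: (float(res.x[i] - tcrit * se[i]), float(res.x[i] + tcrit * se[i]))
        for i, nm in enumerate(names)
    }


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


def _fit_mixed(df, dc, y, form, names, random_param, n_restarts, seed):
    ridx = names.index(random_param)
    subjects = df["subject_id"].to_numpy()
    groups = [np.flatnonzero(subjects == s) for s in pd.unique(subjects)]

    start_nls = _fit_nls(dc, y, form, n_restarts=n_restarts, seed=seed)
    theta0 = start_nls.x
    resid0 = _predict(theta0, dc, form) - y
    sig0 = max(float(np.std(resid0)), 1e-3)
    scale_r = max(abs(theta0[ridx]), 1e-2)

    def nll(params):
        theta = params[: len(names)]
        log_sb, log_se = params[len(names)], params[len(names) + 1]
        sb, se_ = math.exp(log_sb), math.exp(log_se)
        if not np.all(np.isfinite(theta)):
            return 1e10
        total = 0.0
        # Gauss-Hermite: b = sqrt(2)*sb*z, weights w/sqrt(pi)
        bs = math.sqrt(2.0) * sb * _GH_NODES
        for idx in groups:
            dcg, yg = dc[idx], y[idx]
            ll_nodes = np.empty(bs.size)
            for k, b in enumerate(bs):
                th = theta.copy()
                th[ridx] = theta[ridx] + b
                try:
                    mu = _predict(th, dcg, form)
                except (FloatingPointError, ValueError):  # pragma: no cover
                    return 1e10
                r = yg - mu
                ll_nodes[k] = -0.5 * np.sum(r * r) / (se_ * se_) - yg.size * math.log(se_)
            m = ll_nodes.max()
            total += m + math.log(float(np.sum(_GH_WEIGHTS * np.exp(ll_nodes - m))) / math.sqrt(math.pi))
        total -= 0.5 * y.size * math.log(2.0 * math.pi)
        if not math.isfinite(total):
            return 1e10
        return -total

    p0 = np.concatenate([theta0, [math.log(0.1 * scale_r), math.log(sig0)]])
    rng = np.random.default_rng(seed + 1)
    best = None
    for k in range(max(n_restarts // 2, 1)):
        start = p0 if k == 0 else p0 + rng.normal(0.0, 0.1, p0.size)
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):  # pragma: no cover
        raise RuntimeError("mixed-model fit failed to converge")
    theta = best.x[: len(names)]
    ll = -best.fun
    ci = _hessian_ci(nll, best.x, len(names), names)
    return DiscriminationFunction(
        form=form,
        coefficients=dict(zip(names, map(float, theta))),
        ci95=ci, loglik=ll, n_obs=y.size, n_params=len(names) + 2,
        random_param=random_param,
    )


def _hessian_ci(nll, xhat, n_fixed, names, eps=1e-4):
    p = xhat.size
    H = np.empty((p, p))
    f0 = nll(xhat)
    steps = eps * np.maximum(np.abs(xhat), 1.0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = nll(xhat + ei + ej)
            fpm = nll(xhat + ei - ej)
            fmp = nll(xhat - ei + ej)
            fmm = nll(xhat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p, np.nan)
    z = 1.959963984540054
    return {
        nm: (float(xhat[i] - z * se[i]), float(xhat[i] + z * se[i]))
        for i, nm in enumerate(names)
    }


# ---------------------------------------------------------------------------
# Model comparison and bootstrap
# ---------------------------------------------------------------------------

def lrt_compare(fit_small: DiscriminationFunction, fit_large: DiscriminationFunction,
                alpha: float = 0.05) -> ModelComparison:
    """Likelihood-ratio test between nested fits on the same data; the
    simpler form is preferred when the test is not significant."""
    for f in (fit_small, fit_large):
        if f.loglik is None or f.n_obs is None or f.n_params is None:
            raise ValueError("lrt_compare needs fitted models (with log-likelihoods)")
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("fits are not on the same data (different n)")
    df_diff = fit_large.n_params - fit_small.n_params
    if df_diff <= 0:
        raise ValueError("fit_large must have more parameters than fit_small")
    chi = 2.0 * (fit_large.loglik - fit_small.loglik)
    chi = max(chi, 0.0)
    p = float(stats.chi2.sf(chi, df_diff))
    preferred = fit_large.form if p < alpha else fit_small.form
    return ModelComparison(chi_sq=float(chi), df=df_diff, p_value=p, preferred=preferred)


def bootstrap_mean_equality(a, b, n_resamples: int = 100_000,
                            seed: int | None = None) -> BootstrapResult:
    """Studentised two-sample bootstrap test of equal means.

    Both samples are recentred to the pooled mean before resampling so the
    null holds in the bootstrap world; the two-sided p-value is the fraction
    of resampled statistics at least as extreme as the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    # a sample of identical values is degenerate even when rounding leaves
    # its computed variance a hair above zero
    va = a.var(ddof=1) if (a.size > 1 and np.ptp(a) > 0) else 0.0
    vb = b.var(ddof=1) if (b.size > 1 and np.ptp(b) > 0) else 0.0
    if va <= 0 and vb <= 0:
        if np.isclose(a.mean(), b.mean()):
            return BootstrapResult(t_Ho=0.0, p_value=1.0, n_resamples=n_resamples)
        raise ValueError("zero-variance samples with different means")
    denom = math.sqrt(va / a.size + vb / b.size)
    t_obs = (a.mean() - b.mean()) / denom

    pooled = np.concatenate([a, b]).mean()
    a_c = a - a.mean() + pooled
    b_c = b - b.mean() + pooled
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_resamples, a.size))
    ib = rng.integers(0, b.size, size=(n_resamples, b.size))
    ra, rb = a_c[ia], b_c[ib]
    ma, mb = ra.mean(axis=1), rb.mean(axis=1)
    va_s = ra.var(axis=1, ddof=1) if a.size > 1 else np.zeros(n_resamples)
    vb_s = rb.var(axis=1, ddof=1) if b.size > 1 else np.zeros(n_resamples)
    den = np.sqrt(va_s / a.size + vb_s / b.size)
    den[den == 0] = np.inf
    t_star = (ma - mb) / den
    p = float(np.mean(np.abs(t_star) >= abs(t_obs)))
    return BootstrapResult(t_Ho=float(t_obs), p_value=p, n_resamples=n_resamples)
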