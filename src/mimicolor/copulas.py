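"""Bivariate copulas for flower-colour dependence structures.

Implements the three parametric families used to model dependence between
the two hexagon coordinates of a flower region — Gumbel, Joe and the
asymmetric Tawn type II — plus the independence copula, with 0/90/180/270
degree rotations (180 = "survival").

Gumbel and Tawn II are extreme-value copulas and share one code path via
their Pickands dependence function :math:`A(t)`:

.. math:: C(u,v) = \\exp\\{-(x+y)\\,A(t)\\}, \\qquad
          x = -\\ln u,\\; y = -\\ln v,\\; t = y/(x+y)

with Gumbel :math:`A(t) = (t^\\theta + (1-t)^\\theta)^{1/\\theta}` and
Tawn II :math:`A(t) = (1-\\psi)t + ((1-t)^\\theta + (\\psi t)^\\theta)^{1/\\theta}`
evaluated at :math:`t = x/(x+y)`, i.e. the asymmetry weight
:math:`\\psi \\in [0,1]` attaches to the first margin (:math:`\\psi = 1`
recovers Gumbel, :math:`\\psi = 0` independence).  Joe is
Archimedean with generator :math:`\\varphi(s) = -\\ln(1-(1-s)^\\theta)`.

Rotations are true rotations of the unit square (the convention of the
vine-copula literature): the density of the rotated copula is
90: ``c(v, 1-u)``, 180: ``c(1-u, 1-v)``, 270: ``c(1-v, u)``.  For the
exchangeable Gumbel and Joe families this is identical to per-axis
reflection; for the asymmetric Tawn family the distinction matters.  A
negative reported dependence parameter for 90/270 rotations corresponds to
:math:`|\\theta|` in the base family.  Sampling uses conditional inversion:
draw ``u, w ~ U(0,1)``, solve ``h(v | u) = w`` for ``v`` by vectorised
bisection of the base conditional CDF :math:`\\partial C/\\partial u`, then
map the base pair through the rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["CopulaModel", "fit_copula", "FAMILIES", "ROTATIONS"]

FAMILIES = ("independence", "gumbel", "joe", "tawn2")
ROTATIONS = (0, 90, 180, 270)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Pickands machinery for the extreme-value families
# ---------------------------------------------------------------------------

def _pickands(family: str, t, theta: float, psi: float):
    """A(t), A'(t), A''(t) for gumbel (psi=1) / tawn2."""
    t = np.asarray(t, dtype=float)
    om = 1.0 - t
    if family == "gumbel":
        psi = 1.0
    pt = psi * t
    S = om**theta + pt**theta
    g = psi**theta * t ** (theta - 1.0) - om ** (theta - 1.0)
    A = (1.0 - psi) * t + S ** (1.0 / theta)
    A1 = (1.0 - psi) + S ** (1.0 / theta - 1.0) * g
    A2 = (theta - 1.0) * (
        S ** (1.0 / theta - 1.0) * (psi**theta * t ** (theta - 2.0) + om ** (theta - 2.0))
        - S ** (1.0 / theta - 2.0) * g * g
    )
    return A, A1, A2


def _ev_parts(family, u, v, theta, psi):
    # t = x/(x+y): the Tawn asymmetry weight psi attaches to the first
    # (u) margin.  This matches the convention of the vine-copula software
    # the printed Tawn parameters were fitted with.
    x = -np.log(u)
    y = -np.log(v)
    s = x + y
    t = x / s
    A, A1, A2 = _pickands(family, t, theta, psi)
    ell = s * A
    lx = A + (1.0 - t) * A1        # d ell / dx
    ly = A - t * A1                # d ell / dy
    lxy = -t * (1.0 - t) * A2 / s  # d2 ell / dx dy
    C = np.exp(-ell)
    return C, lx, ly, lxy


def _ev_cdf(family, u, v, theta, psi):
    return _ev_parts(family, u, v, theta, psi)[0]


def _ev_density(family, u, v, theta, psi):
    C, lx, ly, lxy = _ev_parts(family, u, v, theta, psi)
    return C / (u * v) * (lx * ly - lxy)


def _ev_h(family, u, v, theta, psi):
    """Conditional CDF h(v|u) = dC/du."""
    C, lx, _, _ = _ev_parts(family, u, v, theta, psi)
    return C * lx / u


# ---------------------------------------------------------------------------
# Joe (Archimedean)
# ---------------------------------------------------------------------------

def _joe_terms(u, v, theta):
    ub = (1.0 - u) ** theta
    vb = (1.0 - v) ** theta
    return ub, vb, ub + vb - ub * vb


def _joe_cdf(u, v, theta):
    _, _, B = _joe_terms(u, v, theta)
    return 1.0 - B ** (1.0 / theta)


def _joe_density(u, v, theta):
    ub, vb, B = _joe_terms(u, v, theta)
    pref = (1.0 - u) ** (theta - 1.0) * (1.0 - v) ** (theta - 1.0)
    return pref * B ** (1.0 / theta - 2.0) * ((theta - 1.0) * (1.0 - ub) * (1.0 - vb) + theta * B)


def _joe_h(u, v, theta):
    ub, vb, B = _joe_terms(u, v, theta)
    return B ** (1.0 / theta - 1.0) * (1.0 - u) ** (theta - 1.0) * (1.0 - vb)


# ---------------------------------------------------------------------------
# Base-family dispatch
# ---------------------------------------------------------------------------

def _base_density(family, u, v, theta, psi):
    if family == "independence":
        return np.ones_like(np.asarray(u, dtype=float))
    if family == "joe":
        return _joe_density(u, v, theta)
    return _ev_density(family, u, v, theta, psi)


def _base_cdf(family, u, v, theta, psi):
    if family == "independence":
        return np.asarray(u, dtype=float) * np.asarray(v, dtype=float)
    if family == "joe":
        return _joe_cdf(u, v, theta)
    return _ev_cdf(family, u, v, theta, psi)


def _base_h(family, u, v, theta, psi):
    if family == "independence":
        return np.asarray(v, dtype=float) + 0.0 * np.asarray(u, dtype=float)
    if family == "joe":
        return _joe_h(u, v, theta)
    return _ev_h(family, u, v, theta, psi)


def _base_h2(family, u, v, theta, psi):
    """dC/dv: conditional CDF of the first argument given the second."""
    if family == "independence":
        return np.asarray(u, dtype=float) + 0.0 * np.asarray(v, dtype=float)
    if family == "joe":
        return _joe_h(v, u, theta)  # exchangeable
    C, _, ly, _ = _ev_parts(family, u, v, theta, psi)
    return C * ly / v


def _check_theta(family, theta):
    if family == "independence":
        return
    if theta < 1.0:
        raise ValueError(f"{family} requires dependence parameter >= 1, got {theta}")


# ---------------------------------------------------------------------------
# Public model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopulaModel:
    """A (possibly rotated) parametric copula.

    ``par1`` follows the reporting convention of the vine-copula literature:
    negative for 90/270 degree rotations, with the base family evaluated at
    ``abs(par1)``.  ``par2`` is the Tawn II asymmetry weight in [0, 1].
    """

    family: str
    rotation: int = 0
    par1: float = 0.0
    par2: float | None = None
    se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        if self.rotation not in ROTATIONS:
            raise ValueError(f"rotation must be one of {ROTATIONS}")
        if self.family != "independence":
            if self.rotation in (90, 270) and self.par1 > 0:
                raise ValueError("90/270-rotated copulas report a negative par1")
            if self.rotation in (0, 180) and self.par1 < 0:
                raise ValueError("0/180-rotated copulas report a positive par1")
            _check_theta(self.family, abs(self.par1))
        if self.family == "tawn2":
            if self.par2 is None or not (0.0 <= self.par2 <= 1.0):
                raise ValueError("tawn2 requires an asymmetry weight par2 in [0, 1]")

    # -- internals ----------------------------------------------------------
    @property
    def _theta(self) -> float:
        return abs(self.par1)

    @property
    def _psi(self) -> float:
        return self.par2 if self.par2 is not None else 1.0

    def _rotate_args(self, u, v):
        """Base-copula arguments whose density equals the rotated density."""
        if self.rotation == 0:
            return u, v
        if self.rotation == 90:
            return v, 1.0 - u
        if self.rotation == 180:
            return 1.0 - u, 1.0 - v
        return 1.0 - v, u

    @staticmethod
    def _rotate_sample(uv: np.ndarray, rotation: int) -> np.ndarray:
        """Map a base-copula sample through the rotation."""
        u, v = uv[:, 0], uv[:, 1]
        if rotation == 0:
            return uv
        if rotation == 90:
            return np.column_stack([1.0 - v, u])
        if rotation == 180:
            return np.column_stack([1.0 - u, 1.0 - v])
        return np.column_stack([v, 1.0 - u])

    # -- surface ------------------------------------------------------------
    def density(self, u, v):
        """Copula density c(u, v); arguments in the open unit square."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
            raise ValueError("copula arguments must lie strictly inside (0, 1)")
        ur, vr = self._rotate_args(u, v)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            out = _base_density(self.family, ur, vr, self._theta, self._psi)
        return float(out) if out.ndim == 0 else out

    def cdf(self, u, v):
        """Copula CDF C(u, v), with rotations by inclusion-exclusion."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        th, ps = self._theta, self._psi
        if self.rotation == 0:
            out = _base_cdf(self.family, u, v, th, ps)
        elif self.rotation == 90:
            out = v - _base_cdf(self.family, v, 1.0 - u, th, ps)
        elif self.rotation == 180:
            out = u + v - 1.0 + _base_cdf(self.family, 1.0 - u, 1.0 - v, th, ps)
        else:
            out = u - _base_cdf(self.family, 1.0 - v, u, th, ps)
        return float(out) if np.ndim(out) == 0 else out

    def h(self, u, v):
        """Conditional CDF P(V <= v | U = u)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        th, ps = self._theta, self._psi
        if self.rotation == 0:
            out = _base_h(self.family, u, v, th, ps)
        elif self.rotation == 90:
            out = _base_h2(self.family, v, 1.0 - u, th, ps)
        elif self.rotation == 180:
            out = 1.0 - _base_h(self.family, 1.0 - u, 1.0 - v, th, ps)
        else:
            out = 1.0 - _base_h2(self.family, 1.0 - v, u, th, ps)
        return float(out) if np.ndim(out) == 0 else out

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` pairs by conditional inversion (bisection to 1e-10).

        A base-copula pair is drawn by inverting the base conditional CDF,
        then mapped through the rotation.  Returns an (n, 2) array with
        uniform margins and this copula's dependence.
        """
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = np.random.default_rng(seed)
        if n == 0:
            return np.empty((0, 2))
        u = rng.uniform(_EPS, 1.0 - _EPS, n)
        w = rng.uniform(_EPS, 1.0 - _EPS, n)
        if self.family == "independence":
            return np.column_stack([u, w])
        lo = np.full(n, _EPS)
        hi = np.full(n, 1.0 - _EPS)
        th, ps = self._theta, self._psi
        # 50 halvings of (0,1) reach well below the 1e-10 tolerance
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            below = _base_h(self.family, u, mid, th, ps) < w
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        base = np.column_stack([u, 0.5 * (lo + hi)])
        return self._rotate_sample(base, self.rotation)

    def kendall_tau(self, n_quad: int = 200) -> float:
        """Kendall's tau by Gauss-Legendre integration of
        :math:`\\tau = 1 - 4\\int\\int \\partial_u C\\, \\partial_v C\\,du\\,dv`
        (uses only the smooth conditional CDFs, never samples)."""
        if self.family == "independence":
            return 0.0
        nodes, weights = np.polynomial.legendre.leggauss(n_quad)
        x = 0.5 * (nodes + 1.0)
        wq = 0.5 * weights
        U, V = np.meshgrid(x, x, indexing="ij")
        W = np.outer(wq, wq)
        th, ps = self._theta, self._psi
        cu = _base_h(self.family, U, V, th, ps)  # dC/du
        if self.family == "joe":
            # Joe is exchangeable: dC/dv(u,v) = dC/du(v,u)
            cv = _base_h(self.family, V, U, th, ps)
        else:
            C, _, ly, _ = _ev_parts(self.family, U, V, th, ps)
            cv = C * ly / V
        tau = 1.0 - 4.0 * float(np.sum(W * cu * cv))
        if self.rotation in (90, 270):
            tau = -tau
        return tau

    def loglik(self, uv: np.ndarray) -> float:
        u = np.clip(uv[:, 0], _EPS, 1.0 - _EPS)
        v = np.clip(uv[:, 1], _EPS, 1.0 - _EPS)
        with np.errstate(all="ignore"):
            d = np.asarray(self.density(u, v))
        # extreme parameter excursions during optimisation can produce
        # non-finite densities in the far tails; treat them as ~zero mass
        d = np.where(np.isfinite(d), d, 0.0)
        return float(np.sum(np.log(np.maximum(d, 1e-300))))

    @property
    def n_params(self) -> int:
        if self.family == "independence":
            return 0
        return 2 if self.family == "tawn2" else 1

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        out = {"family": self.family, "rotation": self.rotation, "par1": self.par1}
        if self.par2 is not None:
            out["par2"] = self.par2
        if self.se is not None:
            out["se"] = list(self.se)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CopulaModel":
        return cls(
            family=d["family"], rotation=int(d.get("rotation", 0)),
            par1=float(d.get("par1", 0.0)),
            par2=float(d["par2"]) if d.get("par2") is not None else None,
            se=tuple(d["se"]) if d.get("se") else None,
        )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _default_candidates() -> list[tuple[str, int]]:
    cands: list[tuple[str, int]] = [("independence", 0)]
    for fam in ("gumbel", "joe", "tawn2"):
        for rot in ROTATIONS:
            cands.append((fam, rot))
    return cands


def _signed_par1(theta: float, rotation: int) -> float:
    return -theta if rotation in (90, 270) else theta


def fit_copula(uv: np.ndarray, candidates=None) -> CopulaModel:
    """ML fit of a copula to pseudo-observations, family selected by AIC.

    Parameters
    ----------
    uv : (n, 2) array
        Pseudo-observations in the open unit square; n >= 20.
    candidates : iterable of (family, rotation), optional
        Defaults to the three parametric families in all four rotations
        plus independence.
    """
    uv = np.asarray(uv, dtype=float)
    if uv.ndim != 2 or uv.shape[1] != 2:
        raise ValueError("uv must be an (n, 2) array")
    if uv.shape[0] < 20:
        raise ValueError("copula fitting needs at least 20 observations")
    if np.any((uv <= 0) | (uv >= 1)):
        raise ValueError("pseudo-observations must lie strictly inside (0, 1)")
    candidates = _default_candidates() if candidates is None else list(candidates)

    best: tuple[float, CopulaModel] | None = None
    errors = []
    for fam, rot in candidates:
        try:
            model = _fit_one(uv, fam, rot)
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            errors.append(f"{fam}/{rot}: {exc}")
            continue
        aic = 2.0 * model.n_params - 2.0 * model.loglik(uv)
        if best is None or aic < best[0]:
            best = (aic, model)
    if best is None:
        raise RuntimeError("all copula candidates failed to converge: " + "; ".join(errors))
    return best[1]


def _fit_one(uv: np.ndarray, family: str, rotation: int) -> CopulaModel:
    if family == "independence":
        return CopulaModel("independence")
    u, v = uv[:, 0], uv[:, 1]

    def nll(raw):
        theta = 1.0 + math.exp(min(raw[0], 12.0))
        psi = 1.0 / (1.0 + math.exp(-raw[1])) if family == "tawn2" else None
        m = CopulaModel(family, rotation, _signed_par1(theta, rotation),
                        par2=psi)
        return -m.loglik(uv)

    # start from the empirical tau via the Gumbel relation theta = 1/(1-|tau|)
    from scipy.stats import kendalltau

    tau_emp = float(kendalltau(u, v).statistic)
    tau_abs = min(abs(tau_emp), 0.95)
    theta0 = max(1.0 / (1.0 - tau_abs), 1.05)
    x0 = [math.log(theta0 - 1.0 + 1e-6)]
    if family == "tawn2":
        x0.append(1.0)  # psi ~ 0.73
    res = optimize.minimize(nll, np.asarray(x0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("optimiser diverged")
    theta = 1.0 + math.exp(min(res.x[0], 12.0))
    psi = 1.0 / (1.0 + math.exp(-res.x[1])) if family == "tawn2" else None
    se = _param_se(uv, family, rotation, theta, psi)
    return CopulaModel(family, rotation, _signed_par1(theta, rotation), par2=psi, se=se)


def _param_se(uv, family, rotation, theta, psi, eps=1e-4):
    """Asymptotic SEs from the numerical Hessian of the log-likelihood."""
    params = [theta] if psi is None else [theta, psi]

    def nll(p):
        th = max(p[0], 1.0 + 1e-9)
        ps = min(max(p[1], 1e-9), 1.0 - 1e-9) if psi is not None else None
        m = CopulaModel(family, rotation, _signed_par1(th, rotation), par2=ps)
        return -m.loglik(uv)

    p = np.asarray(params, dtype=float)
    k = p.size
    H = np.empty((k, k))
    steps = eps * np.maximum(np.abs(p), 1.0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                nll(p + ei + ej) - nll(p + ei - ej) - nll(p - ei + ej) + nll(p - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
        return tuple(float(s) for s in np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
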