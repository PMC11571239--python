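"""Parametric survival extrapolation for the cost-effectiveness model.

Fits standard parametric families, mixture cure models, and Royston-Parmar
restricted-cubic-spline models to (pseudo-)individual patient data under
right censoring, selects among candidates by AIC, and converts fitted curves
into the monthly transition probabilities the cohort model consumes.

Parameterizations (time ``t`` in months, all scale/shape parameters > 0):

========== ==================== =========================================
family     params               survival function
========== ==================== =========================================
weibull    (shape k, scale b)   S(t) = exp(-(t/b)^k)
gompertz   (shape a, rate b)    S(t) = exp(-(b/a)(e^{a t} - 1)); a may be
                                negative (decelerating hazard, plateau at
                                exp(b/a)); a -> 0 recovers the exponential
loglogistic(scale a, shape p)   S(t) = 1 / (1 + (t/a)^p)
lognormal  (mu, sigma)          S(t) = 1 - Phi((ln t - mu)/sigma)
gengamma   (mu, sigma, Q)       Prentice form: w = (ln t - mu)/sigma;
                                Q != 0: S built from the gamma integral of
                                Q^{-2} e^{Q w}; Q -> 0 is the log-normal
========== ==================== =========================================

Mixture cure: S(t) = pi + (1 - pi) S_u(t) with latent S_u from one of the
families above; ``params`` stores the latent parameters followed by pi.

Royston-Parmar splines model a transform of S as a natural cubic spline in
x = ln t: g(S) = s(x).  ``scale='hazard'`` uses g = ln(-ln S) (log cumulative
hazard; a spline with only the linear term is exactly Weibull), ``'odds'``
uses g = ln(1/S - 1), ``'normal'`` uses g = -Phi^{-1}(S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "PseudoIPD",
    "SurvivalFit",
    "fit_standard",
    "fit_mixture_cure",
    "fit_rp_spline",
    "select_model",
    "ranking_table",
    "survival_at",
    "monthly_transition_prob",
    "km_max_abs_deviation",
]

FAMILIES = ("gengamma", "weibull", "gompertz", "loglogistic", "lognormal")

_TINY = 1e-300


# ---------------------------------------------------------------------------
# pseudo individual patient data
# ---------------------------------------------------------------------------

@dataclass
class PseudoIPD:
    """Per-subject (time, event) records for one arm and endpoint.

    ``time`` is in months; ``event`` is 1 for an observed event, 0 for
    right censoring.
    """

    time: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("all times must be finite")
        if np.any(self.time < 0):
            raise ValueError("times must be >= 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.time,
                "event": self.event,
                "arm": self.arm,
                "endpoint": self.endpoint,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        arm = str(df["arm"].iloc[0]) if "arm" in df else ""
        endpoint = str(df["endpoint"].iloc[0]) if "endpoint" in df else ""
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(),
                   arm=arm, endpoint=endpoint)


# ---------------------------------------------------------------------------
# family log-density / log-survival, natural parameters
# ---------------------------------------------------------------------------

def _w_logpdf(t, k, b):
    z = t / b
    return np.log(k / b) + (k - 1) * np.log(np.maximum(z, _TINY)) - z**k


def _w_logsf(t, k, b):
    return -((t / b) ** k)


def _gomp_cumhaz(t, a, b):
    # (b/a)(e^{at}-1), continuous through a = 0
    a = np.asarray(a, dtype=float)
    out = np.where(np.abs(a) < 1e-9, b * t, b * np.expm1(a * t) / np.where(a == 0, 1.0, a))
    return out


def _gomp_logpdf(t, a, b):
    return np.log(b) + a * t - _gomp_cumhaz(t, a, b)


def _gomp_logsf(t, a, b):
    return -_gomp_cumhaz(t, a, b)


def _llog_logpdf(t, a, p):
    z = np.maximum(t / a, _TINY)
    return np.log(p / a) + (p - 1) * np.log(z) - 2 * np.log1p(z**p)


def _llog_logsf(t, a, p):
    z = np.maximum(t / a, _TINY)
    return -np.log1p(z**p)


def _lnorm_logpdf(t, mu, sigma):
    t = np.maximum(t, _TINY)
    z = (np.log(t) - mu) / sigma
    return norm.logpdf(z) - np.log(sigma * t)


def _lnorm_logsf(t, mu, sigma):
    t = np.maximum(t, _TINY)
    return norm.logsf((np.log(t) - mu) / sigma)


def _gg_logpdf(t, mu, sigma, Q):
    if abs(Q) < 1e-6:
        return _lnorm_logpdf(t, mu, sigma)
    t = np.maximum(t, _TINY)
    w = (np.log(t) - mu) / sigma
    q2 = Q**-2
    return (
        np.log(abs(Q))
        + q2 * np.log(q2)
        - special.gammaln(q2)
        - np.log(sigma * t)
        + q2 * (Q * w - np.exp(np.minimum(Q * w, 700.0)))
    )


def _gg_logsf(t, mu, sigma, Q):
    if abs(Q) < 1e-6:
        return _lnorm_logsf(t, mu, sigma)
    t = np.maximum(t, _TINY)
    w = (np.log(t) - mu) / sigma
    q2 = Q**-2
    u = q2 * np.exp(np.minimum(Q * w, 700.0))
    if Q > 0:
        sf = special.gammaincc(q2, u)
    else:
        sf = special.gammainc(q2, u)
    return np.log(np.maximum(sf, _TINY))


_FAMILY_FUNCS = {
    "weibull": (_w_logpdf, _w_logsf),
    "gompertz": (_gomp_logpdf, _gomp_logsf),
    "loglogistic": (_llog_logpdf, _llog_logsf),
    "lognormal": (_lnorm_logpdf, _lnorm_logsf),
    "gengamma": (_gg_logpdf, _gg_logsf),
}

# unconstrained <-> natural transforms; positives go through log
_LOG_POS = {"weibull": [True, True], "gompertz": [False, True],
            "loglogistic": [True, True], "lognormal": [False, True],
            "gengamma": [False, True, False]}


def _to_natural(family, x):
    return np.array([np.exp(v) if lg else v for v, lg in zip(x, _LOG_POS[family])])


def _to_unconstrained(family, p):
    return np.array([np.log(v) if lg else v for v, lg in zip(p, _LOG_POS[family])])


def family_logpdf(family, t, params):
    return _FAMILY_FUNCS[family][0](np.asarray(t, dtype=float), *params)


def family_logsf(family, t, params):
    return _FAMILY_FUNCS[family][1](np.asarray(t, dtype=float), *params)


def family_sf(family, t, params):
    return np.exp(family_logsf(family, t, params))


def family_ppf(family, u, params):
    """Inverse survival-time CDF (quantile of the event-time distribution)."""
    u = np.asarray(u, dtype=float)
    if family == "weibull":
        k, b = params
        return b * (-np.log1p(-u)) ** (1 / k)
    if family == "gompertz":
        a, b = params
        if abs(a) < 1e-9:
            return -np.log1p(-u) / b
        arg = 1 - (a / b) * np.log1p(-u)
        # negative-shape Gompertz is improper: mass exp(b/a) never fails
        out = np.full(u.shape, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / a
        return out
    if family == "loglogistic":
        a, p = params
        return a * (u / (1 - u)) ** (1 / p)
    if family == "lognormal":
        mu, sigma = params
        return np.exp(mu + sigma * norm.ppf(u))
    if family == "gengamma":
        mu, sigma, Q = params
        if abs(Q) < 1e-6:
            return np.exp(mu + sigma * norm.ppf(u))
        q2 = Q**-2
        if Q > 0:
            g = special.gammaincinv(q2, u)
        else:
            g = special.gammainccinv(q2, u)
        return np.exp(mu + (sigma / Q) * np.log(g / q2))
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """A fitted extrapolation model exposing S(t), h(t) and the AIC."""

    family: str
    params: np.ndarray
    n_params: int
    loglik: float
    aic: float
    converged: bool = True
    message: str = ""
    knots: np.ndarray | None = None       # rp_spline only (log-time)
    scale: str | None = None              # rp_spline only
    cure_fraction: float | None = None    # mixture_cure only
    latent_family: str | None = None      # mixture_cure only
    vcov: np.ndarray | None = None        # inverse observed information
    warnings: list = field(default_factory=list)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        s = np.empty_like(t)
        zero = t <= 0
        s[zero] = 1.0
        if np.any(~zero):
            s[~zero] = self._sf_positive(t[~zero])
        s = np.clip(s, 0.0, 1.0)
        return float(s[0]) if scalar else s

    def _sf_positive(self, t):
        if self.family == "rp_spline":
            return _rp_sf(t, self.params, self.knots, self.scale)
        if self.family == "mixture_cure":
            pi = self.cure_fraction
            su = family_sf(self.latent_family, t, self.params[:-1])
            return pi + (1 - pi) * su
        return family_sf(self.family, t, self.params)

    def hazard(self, t, eps=1e-5):
        """Instantaneous hazard via a central difference of ln S."""
        t = np.asarray(t, dtype=float)
        lo = np.maximum(t - eps, 1e-9)
        hi = t + eps
        s_lo = np.maximum(self.survival(lo), _TINY)
        s_hi = np.maximum(self.survival(hi), _TINY)
        return -(np.log(s_hi) - np.log(s_lo)) / (hi - lo)

    def summary(self) -> dict:
        out = {
            "family": self.family,
            "params": np.asarray(self.params).tolist(),
            "n_params": self.n_params,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
        }
        if self.cure_fraction is not None:
            out["cure_fraction"] = self.cure_fraction
            out["latent_family"] = self.latent_family
        if self.knots is not None:
            out["knots"] = np.asarray(self.knots).tolist()
            out["scale"] = self.scale
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_fittable(ipd: PseudoIPD):
    if ipd.n < 10:
        raise ValueError(f"need >= 10 records to fit, got {ipd.n}")
    if ipd.n_events == 0:
        raise ValueError("all records censored; cannot fit a survival model")
    if ipd.n_events < 3:
        raise ValueError(f"need >= 3 events to fit, got {ipd.n_events}")


def _neg_loglik(family, x, t, e):
    params = _to_natural(family, x)
    with np.errstate(all="ignore"):
        ll = np.where(e == 1,
                      family_logpdf(family, t, params),
                      family_logsf(family, t, params))
    total = ll.sum()
    if not np.isfinite(total):
        return 1e10
    return -total


def _initial_values(family, t, e):
    te = np.maximum(t[e == 1], 1e-6)
    lt = np.log(te)
    m, s = lt.mean(), max(lt.std(), 0.1)
    rate = max(e.sum() / max(t.sum(), 1e-9), 1e-6)
    starts = []
    if family == "weibull":
        k0 = min(max(1.2 / s, 0.2), 10.0)
        starts = [[k0, np.exp(m + 0.5772 / k0)], [1.0, 1 / rate]]
    elif family == "gompertz":
        starts = [[0.01, rate], [-0.01, rate], [1e-4, rate], [0.05, rate / 2]]
    elif family == "loglogistic":
        starts = [[np.exp(m), min(max(1.8 / s, 0.2), 10.0)], [np.exp(m), 1.0]]
    elif family == "lognormal":
        starts = [[m, s], [m, 1.0]]
    elif family == "gengamma":
        starts = [[m, s, 0.5], [m, s, 1.0], [m, s, -0.5], [m, s, 1e-3]]
    return [_to_unconstrained(family, p) for p in starts]


def _optimize(fun, starts, seed=20240901):
    """Multi-start Nelder-Mead with a quasi-Newton polish."""
    rng = np.random.default_rng(seed)
    all_starts = list(starts)
    for x0 in starts[:1]:
        for _ in range(2):
            all_starts.append(np.asarray(x0) + rng.normal(0, 0.3, size=len(x0)))
    best = None
    for x0 in all_starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(fun, x0, method="Nelder-Mead",
                                    options={"fatol": 1e-10, "xatol": 1e-8,
                                             "maxiter": 4000, "maxfev": 6000})
        if best is None or res.fun < best.fun:
            best = res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polish = optimize.minimize(fun, best.x, method="BFGS",
                                   options={"gtol": 1e-8, "maxiter": 500})
    if polish.fun <= best.fun:
        best = polish
    return best


def _numeric_vcov(fun, x):
    """Inverse of a finite-difference Hessian of the negative log-likelihood."""
    n = len(x)
    h = 1e-4 * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.array(x), np.array(x)
            xpp = np.array(x); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = np.array(x); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = np.array(x); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = np.array(x); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def fit_standard(ipd: PseudoIPD, family: str, compute_vcov: bool = False) -> SurvivalFit:
    """Maximum-likelihood fit of one standard parametric family.

    Non-convergence is reported on the returned fit (``converged=False``
    with optimizer diagnostics), never silently replaced.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    _check_fittable(ipd)
    t, e = ipd.time, ipd.event
    fun = lambda x: _neg_loglik(family, x, t, e)
    res = _optimize(fun, _initial_values(family, t, e))
    params = _to_natural(family, res.x)
    ll = -res.fun
    k = len(params)
    fit = SurvivalFit(family=family, params=params, n_params=k,
                      loglik=ll, aic=2 * k - 2 * ll,
                      converged=bool(res.fun < 1e9),
                      message=str(res.message))
    if compute_vcov:
        fit.vcov = _numeric_vcov(fun, res.x)
    return fit


def fit_mixture_cure(ipd: PseudoIPD, latent_family: str) -> SurvivalFit:
    """Fit S(t) = pi + (1 - pi) S_u(t) with pi and the latent parameters
    estimated jointly by maximum likelihood."""
    if latent_family not in FAMILIES:
        raise ValueError(f"latent_family must be one of {FAMILIES}")
    _check_fittable(ipd)
    t, e = ipd.time, ipd.event

    def nll(x):
        lat = _to_natural(latent_family, x[:-1])
        pi = special.expit(x[-1])
        with np.errstate(all="ignore"):
            lf = family_logpdf(latent_family, t, lat) + np.log1p(-pi)
            su = np.exp(family_logsf(latent_family, t, lat))
            ls = np.log(np.maximum(pi + (1 - pi) * su, _TINY))
            total = np.where(e == 1, lf, ls).sum()
        return -total if np.isfinite(total) else 1e10

    km_tail = _km_estimate(ipd)[1][-1] if ipd.n else 0.3
    pi0 = np.clip(km_tail, 0.05, 0.9)
    starts = [np.append(x0, special.logit(pi0))
              for x0 in _initial_values(latent_family, t, e)]
    starts += [np.append(starts[0][:-1], special.logit(p)) for p in (0.2, 0.6)]
    res = _optimize(nll, starts)
    lat = _to_natural(latent_family, res.x[:-1])
    pi = float(special.expit(res.x[-1]))
    ll = -res.fun
    k = len(lat) + 1
    fit = SurvivalFit(family="mixture_cure", params=np.append(lat, pi),
                      n_params=k, loglik=ll, aic=2 * k - 2 * ll,
                      converged=bool(res.fun < 1e9), message=str(res.message),
                      cure_fraction=pi, latent_family=latent_family)
    if pi < 1e-4 or pi > 1 - 1e-4:
        fit.warnings.append(f"cure fraction at boundary: pi={pi:.2e}")
    return fit


# ---------------------------------------------------------------------------
# Royston-Parmar splines
# ---------------------------------------------------------------------------

def _rcs_basis(x, knots):
    """Restricted cubic spline basis v_j(x), natural beyond boundary knots."""
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (np.maximum(x - kj, 0) ** 3
             - lam * np.maximum(x - kmin, 0) ** 3
             - (1 - lam) * np.maximum(x - kmax, 0) ** 3)
        cols.append(v)
    return np.column_stack(cols)


def _rcs_basis_deriv(x, knots):
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (3 * np.maximum(x - kj, 0) ** 2
             - 3 * lam * np.maximum(x - kmin, 0) ** 2
             - 3 * (1 - lam) * np.maximum(x - kmax, 0) ** 2)
        cols.append(v)
    return np.column_stack(cols)


def _rp_sf(t, gamma, knots, scale):
    x = np.log(np.maximum(t, _TINY))
    s = _rcs_basis(x, knots) @ gamma
    if scale == "hazard":
        return np.exp(-np.exp(np.minimum(s, 700)))
    if scale == "odds":
        return special.expit(-s)
    if scale == "normal":
        return norm.sf(s)
    raise ValueError(f"unknown rp scale {scale!r}")


def _km_estimate(ipd: PseudoIPD):
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return t, s


def fit_rp_spline(ipd: PseudoIPD, n_knots: int, scale: str) -> SurvivalFit:
    """Royston-Parmar flexible parametric fit.

    ``n_knots`` counts all knots (two boundary + interior) and must be in
    {3, 4, 5}; boundary knots sit at the min and max uncensored log event
    times, interior knots at equally spaced quantiles of those.
    """
    if n_knots not in (3, 4, 5):
        raise ValueError("n_knots must be 3, 4 or 5")
    if scale not in ("hazard", "odds", "normal"):
        raise ValueError("scale must be 'hazard', 'odds' or 'normal'")
    _check_fittable(ipd)
    t, e = ipd.time, ipd.event
    lev = np.log(np.unique(t[(e == 1) & (t > 0)]))
    if lev.size < n_knots:
        raise ValueError(
            f"{lev.size} distinct event times < {n_knots} knots requested")
    qs = np.linspace(0, 1, n_knots)
    knots = np.quantile(np.log(t[(e == 1) & (t > 0)]), qs)
    knots[0], knots[-1] = lev.min(), lev.max()
    if np.unique(knots).size < n_knots:
        raise ValueError("degenerate (tied) knot locations")

    x = np.log(np.maximum(t, _TINY))
    B = _rcs_basis(x, knots)
    dB = _rcs_basis_deriv(x, knots)

    def nll(gamma):
        s = B @ gamma
        ds = dB @ gamma
        with np.errstate(all="ignore"):
            if scale == "hazard":
                es = np.exp(np.minimum(s, 700))
                logpdf = np.log(np.maximum(ds, _TINY)) - x + s - es
                logsf = -es
            elif scale == "odds":
                logpdf = (np.log(np.maximum(ds, _TINY)) - x + s
                          - 2 * np.log1p(np.exp(np.minimum(s, 700))))
                logsf = np.log(special.expit(-s))
            else:  # normal
                logpdf = np.log(np.maximum(ds, _TINY)) - x + norm.logpdf(s)
                logsf = norm.logsf(s)
            if np.any(ds[e == 1] <= 0):
                return 1e10
            total = np.where(e == 1, logpdf, logsf).sum()
        return -total if np.isfinite(total) else 1e10

    # initialize by regressing the KM transform on the basis
    km_t, km_s = _km_estimate(ipd)
    ok = (km_t > 0) & (km_s > 1e-4) & (km_s < 1 - 1e-4)
    g0 = np.zeros(n_knots)
    if ok.sum() >= n_knots:
        Sk = km_s[ok]
        if scale == "hazard":
            y = np.log(-np.log(Sk))
        elif scale == "odds":
            y = np.log(1 / Sk - 1)
        else:
            y = -norm.ppf(Sk)
        Bk = _rcs_basis(np.log(km_t[ok]), knots)
        g0, *_ = np.linalg.lstsq(Bk, y, rcond=None)
    res = _optimize(nll, [g0])
    ll = -res.fun
    k = n_knots
    return SurvivalFit(family="rp_spline", params=np.asarray(res.x),
                       n_params=k, loglik=ll, aic=2 * k - 2 * ll,
                       converged=bool(res.fun < 1e9), message=str(res.message),
                       knots=knots, scale=scale)


# ---------------------------------------------------------------------------
# selection and evaluation
# ---------------------------------------------------------------------------

def ranking_table(fits: list[SurvivalFit]) -> pd.DataFrame:
    rows = [
        {
            "family": f.family if f.latent_family is None
            else f"mixture_cure({f.latent_family})",
            "scale": f.scale,
            "n_params": f.n_params,
            "params": np.array2string(np.asarray(f.params), precision=5,
                                      separator=" "),
            "loglik": f.loglik,
            "aic": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)


def select_model(fits: list[SurvivalFit], km=None) -> SurvivalFit:
    """Lowest-AIC fit; ties broken by fewer parameters, then input order."""
    if not fits:
        raise ValueError("empty candidate list")
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].n_params, i))
    return fits[order[0]]


def survival_at(fit: SurvivalFit, t) -> float:
    return fit.survival(t)


def monthly_transition_prob(fit: SurvivalFit, t):
    """p(t) = 1 - S(t+1)/S(t), the probability of the event within the
    coming one-month cycle conditional on being event-free at t."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    s0 = fit.survival(t)
    s1 = fit.survival(t + 1.0)
    p = np.ones_like(s0)
    pos = s0 > 0
    p[pos] = 1.0 - s1[pos] / s0[pos]
    if np.any(~pos):
        warnings.warn("S(t) = 0: monthly transition probability set to 1")
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def km_max_abs_deviation(fit: SurvivalFit, ipd: PseudoIPD) -> float:
    """Max |fitted S - KM| over the KM support: the numerical stand-in for
    visual inspection of fit adequacy."""
    t, s = _km_estimate(ipd)
    return float(np.max(np.abs(fit.survival(t) - s)))
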