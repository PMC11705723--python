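"""Four-parameter log-logistic dose-response fitting and drug sensitivity scoring.

The response is modelled on the *inhibition* scale.  With ``x`` the drug
concentration (molar), the fitted curve is

    I(x) = c + (d - c) / (1 + (e / x)**b)

an increasing log-logistic with Hill slope ``b > 0``, baseline inhibition
``c`` (fixed at 0 by default -- the "lower boundary set to zero" convention),
maximal inhibition ``d`` (%; 100 for a fully efficacious drug, lower when a
viability floor remains), and midpoint concentration ``e`` where inhibition
reaches (c + d)/2.  Percent viability is ``V(x) = 100 - I(x)``.

The drug sensitivity score (DSS) is the normalised area of the fitted
inhibition curve above an activity threshold ``t`` over the tested
log10-concentration window, computed from the closed-form antiderivative of
the logistic (see :func:`dss`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LL4Fit",
    "DSSResult",
    "fit_ll4",
    "ic_p",
    "dss",
    "remove_outliers_and_refit",
    "ll4_inhibition",
    "ll4_viability",
]

_LN10 = math.log(10.0)

# slope and asymptote box constraints for the trf solver
_B_BOUNDS = (0.05, 25.0)
_D_BOUNDS = (0.0, 100.0)


def ll4_inhibition(x, b, c, d, e):
    """Percent inhibition at concentration ``x`` (vectorised; I(0) = c)."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(c))
    pos = x > 0
    with np.errstate(over="ignore"):
        ratio = (e / x[pos]) ** b
    out[pos] = c + (d - c) / (1.0 + ratio)
    return out if out.shape else float(out)


def ll4_viability(x, b, c, d, e):
    """Percent viability at concentration ``x``: 100 - I(x)."""
    return 100.0 - ll4_inhibition(x, b, c, d, e)


@dataclass
class LL4Fit:
    """A fitted four-parameter log-logistic inhibition curve.

    ``b`` Hill slope (> 0), ``c`` baseline inhibition (%), ``d`` maximal
    inhibition (%), ``e`` midpoint concentration (molar).
    """

    b: float
    c: float
    d: float
    e: float
    residual_sd: float
    converged: bool
    n_points: int
    outliers_removed: int = 0
    lower_fixed: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.e > 0):
                raise ValueError(f"midpoint e must be positive, got {self.e}")
            if self.c > self.d + 1e-9:
                raise ValueError(f"asymptotes inverted: c={self.c} > d={self.d}")

    @property
    def max_inhibition(self) -> float:
        return self.d

    @property
    def responder(self) -> bool:
        """Whether the curve shows a non-trivial response (> 10% span)."""
        return (self.d - self.c) > 10.0

    def inhibition(self, x):
        return ll4_inhibition(x, self.b, self.c, self.d, self.e)

    def viability(self, x):
        return ll4_viability(x, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class DSSResult:
    """Normalised-area drug sensitivity score over a log10-dose window."""

    dss: float
    variant: int
    t: float
    x_min: float
    x_max: float
    area: float  # raw integrated activity above t, in %.log10(M)

    def __post_init__(self):
        if not (0.0 <= self.dss <= 100.0):
            raise ValueError(f"dss out of [0, 100]: {self.dss}")


def _ll4_residuals(theta, log_x, y_inh, c_fixed):
    # free-baseline fits are parameterised as (b, span, loge, c) with
    # span = d - c >= 0, so the asymptotes can never invert
    if c_fixed is None:
        b, span, loge, c = theta
    else:
        b, span, loge = theta
        c = c_fixed
    pred = c + span / (1.0 + np.exp(-b * (log_x - loge)))
    return pred - y_inh


def fit_ll4(
    doses,
    viability,
    fix_lower_at_zero: bool = True,
    n_restarts: int = 5,
) -> LL4Fit:
    """Least-squares fit of the LL4 curve to (dose, % viability) data.

    Viability is converted to inhibition internally.  Requires at least three
    distinct positive doses when the baseline is fixed at zero, four
    otherwise.  Non-convergence after multi-start restarts is reported via
    ``converged=False`` (no exception); too few doses raises ``ValueError``.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have equal length")
    if not np.all(np.isfinite(viability)):
        raise ValueError("viability values must be finite")
    pos = doses > 0
    doses, viability = doses[pos], viability[pos]
    n_distinct = np.unique(doses).size
    n_required = 3 if fix_lower_at_zero else 4
    if n_distinct < n_required:
        raise ValueError(
            f"need >= {n_required} distinct positive doses, got {n_distinct}"
        )

    log_x = np.log(doses)
    y_inh = 100.0 - viability
    c_fixed = 0.0 if fix_lower_at_zero else None

    # initial values: d0 from the strongest observed response, e0 at the dose
    # nearest half of d0, b0 = 1
    order = np.argsort(doses)
    d0 = float(np.clip(np.max(y_inh), 1.0, 100.0))
    half = d0 / 2.0
    idx_half = int(np.argmin(np.abs(y_inh[order] - half)))
    loge0 = float(log_x[order][idx_half])
    starts = [(1.0, d0, loge0)]
    # deterministic jittered restarts over log-midpoint and slope
    jitters = [(0.5, 0.0), (2.0, 0.0), (1.0, -2.0), (1.0, 2.0), (0.5, 2.0),
               (2.0, -2.0)]
    for bj, lj in jitters[: max(0, n_restarts)]:
        starts.append((bj, d0, loge0 + lj))

    log_lo, log_hi = log_x.min() - 15.0, log_x.max() + 15.0
    if c_fixed is None:
        lower = [_B_BOUNDS[0], _D_BOUNDS[0], log_lo, 0.0]
        upper = [_B_BOUNDS[1], _D_BOUNDS[1], log_hi, 100.0]
    else:
        lower = [_B_BOUNDS[0], _D_BOUNDS[0], log_lo]
        upper = [_B_BOUNDS[1], _D_BOUNDS[1], log_hi]

    c0 = float(np.clip(np.min(y_inh), 0.0, 99.0))
    best = None
    n_success = 0
    for b0, dd0, le0 in starts:
        if c_fixed is not None:
            theta0 = [b0, dd0, le0]
        else:
            theta0 = [b0, max(dd0 - c0, 1.0), le0, c0]
        theta0 = np.clip(theta0, lower, upper)
        try:
            res = least_squares(
                _ll4_residuals,
                theta0,
                bounds=(lower, upper),
                args=(log_x, y_inh, c_fixed),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=5000,
            )
        except Exception:  # solver blow-up counts as a failed start
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
        n_success += res.success
        # an essentially exact fit, or two concordant successful starts,
        # ends the multi-start early
        if best.cost < 1e-10 or n_success >= 2:
            break

    n = doses.size
    if best is None:
        return LL4Fit(
            b=np.nan, c=0.0 if fix_lower_at_zero else np.nan, d=np.nan,
            e=np.nan, residual_sd=np.nan, converged=False, n_points=n,
            lower_fixed=fix_lower_at_zero, message="all starts failed",
        )

    if c_fixed is None:
        b, span, loge, c = best.x
        d = c + span
    else:
        (b, span, loge), c = best.x, c_fixed
        d = c + span
    n_params = 3 if fix_lower_at_zero else 4
    dof = max(n - n_params, 1)
    residual_sd = float(np.sqrt(2.0 * best.cost / dof))
    return LL4Fit(
        b=float(b), c=float(c), d=float(d), e=float(np.exp(loge)),
        residual_sd=residual_sd, converged=bool(best.success),
        n_points=n, lower_fixed=fix_lower_at_zero, message=best.message,
    )


def ic_p(fit: LL4Fit, p: float, relative: bool = False) -> float:
    """Concentration producing ``p`` % inhibition.

    Default convention is *absolute* inhibition on the normalised 0-100 scale
    (IC50 = the dose at 50% inhibition, i.e. 50% viability); ``relative=True``
    targets ``p`` % of the fitted span d - c instead.  Raises ``ValueError``
    when the target is not reached within the model range, e.g. IC90 of a
    curve plateauing at 50% maximal inhibition.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    b, c, d, e = fit.b, fit.c, fit.d, fit.e
    if relative:
        if not (0.0 < p < 100.0):
            raise ValueError("relative p must lie in (0, 100)")
        return float(e * (p / (100.0 - p)) ** (1.0 / b))
    if not (c < p < d):
        raise ValueError(
            f"IC{p:g} not reached within model range: inhibition spans "
            f"({c:g}, {d:g})%"
        )
    return float(e * ((p - c) / (d - p)) ** (1.0 / b))


def _logistic_antideriv(u, b, loge10):
    """F(u) = integral of (e/x)^-b logistic fraction in u = log10 x."""
    z = b * (u - loge10) * _LN10
    return np.logaddexp(0.0, z) / (b * _LN10)


def dss_area(b, c, d, e, x_min, x_max, t):
    """Closed-form area of (I(u) - t) over the sub-window of [x_min, x_max]
    (log10 molar) where fitted inhibition exceeds ``t``."""
    if d <= t:
        return 0.0, x_max  # empty integration region
    loge10 = math.log10(e)
    if t > c:
        s_star = (t - c) / (d - c)  # logistic fraction at the crossing
        u_star = loge10 + math.log10(s_star / (1.0 - s_star)) / b
    else:
        u_star = -math.inf  # whole window is above threshold
    ua = min(max(u_star, x_min), x_max)
    if ua >= x_max:
        return 0.0, x_max
    f = _logistic_antideriv
    area = (c - t) * (x_max - ua) + (d - c) * (
        f(x_max, b, loge10) - f(ua, b, loge10)
    )
    return float(max(area, 0.0)), ua


def dss(
    fit: LL4Fit,
    x_min: float,
    x_max: float,
    t: float = 10.0,
    variant: int = 2,
    force: bool = False,
) -> DSSResult:
    """Drug sensitivity score of a fitted curve over [x_min, x_max] (log10 M).

    Variant 1 normalises the activity area by the full window,
    ``100 * A / ((100 - t) (x_max - x_min))``.  Variant 2 multiplies variant 1
    by ``log10(d)/2``, penalising partial maximal inhibition (identity at
    d = 100).  Variant 3 additionally scales by the fraction of the window in
    which the curve is active.  All results are clamped to [0, 100].
    """
    if not fit.converged and not force:
        raise ValueError("refusing DSS of a non-converged fit (use force=True)")
    if not x_min < x_max:
        raise ValueError("x_min must be < x_max")
    if variant not in (1, 2, 3):
        raise ValueError(f"unknown DSS variant {variant}")
    b, c, d, e = fit.b, fit.c, fit.d, fit.e
    area, ua = dss_area(b, c, d, e, x_min, x_max, t)
    width = x_max - x_min
    score = 100.0 * area / ((100.0 - t) * width)
    if variant >= 2:
        score *= math.log10(max(d, 1.0)) / 2.0
    if variant == 3:
        score *= (x_max - ua) / width
    score = float(np.clip(score, 0.0, 100.0))
    return DSSResult(dss=score, variant=variant, t=t, x_min=x_min,
                     x_max=x_max, area=area)


def remove_outliers_and_refit(
    doses,
    viability,
    fix_lower_at_zero: bool = True,
    z_threshold: float = 3.0,
    max_removed_frac: float = 0.2,
) -> LL4Fit:
    """Single-pass outlier rejection against an initial fit, then one refit.

    Points whose absolute studentized residual exceeds ``z_threshold`` are
    dropped (at most ``max_removed_frac`` of the data, worst first).  If the
    removal would leave too few distinct doses the original fit is returned
    with no points removed.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size < 6:
        raise ValueError("need >= 6 points for outlier-screened fitting")
    fit0 = fit_ll4(doses, viability, fix_lower_at_zero=fix_lower_at_zero)
    if not fit0.converged or fit0.residual_sd == 0 or not np.isfinite(fit0.residual_sd):
        return fit0
    resid = (100.0 - viability) - fit0.inhibition(doses)
    z = np.abs(resid) / fit0.residual_sd
    flagged = np.flatnonzero(z > z_threshold)
    if flagged.size == 0:
        return fit0
    max_removed = int(math.floor(max_removed_frac * doses.size))
    if flagged.size > max_removed:
        flagged = flagged[np.argsort(z[flagged])[::-1][:max_removed]]
    keep = np.ones(doses.size, dtype=bool)
    keep[flagged] = False
    n_required = 3 if fix_lower_at_zero else 4
    if np.unique(doses[keep][doses[keep] > 0]).size < n_required:
        return replace(fit0, message=fit0.message + " | outlier removal skipped")
    fit1 = fit_ll4(doses[keep], viability[keep],
                   fix_lower_at_zero=fix_lower_at_zero)
    return replace(fit1, outliers_removed=int(flagged.size))
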