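"""Velocity-profile fitting and elongation-zone trait extraction.

The displacement velocity of root material, viewed from the tip, rises
sigmoidally from ~0 in the meristem to a plateau ``vf`` beyond the
elongation zone.  The flexible logistic model

    v(x) = vf * [1 + exp(-k (x - x0))]^(-1/n)

captures this with a location parameter ``x0``, steepness ``k`` and an
asymmetry parameter ``n``.  Its spatial derivative is the relative
elemental growth rate (REGR), the local strain rate of the tissue.  Four
traits summarise the zone: the elongation rate (``vf``), the maximum REGR,
the axial position of that maximum, and the zone length (the width over
which REGR exceeds a fixed fraction of its maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .types import KinematicTraits, VelocityPointCloud, VelocityProfileParams

MIN_CLOUD_POINTS = 10


def velocity_model(params: VelocityProfileParams, x) -> np.ndarray | float:
    """Evaluate the flexible logistic velocity profile at position(s) ``x`` (mm).

    Monotone nondecreasing in x, with limits 0 (x -> -inf) and ``vf``
    (x -> +inf).  Returns mm/h.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    u = np.exp(-params.k * (x - params.x0))
    out = params.vf * (1.0 + u) ** (-1.0 / params.n)
    return float(out) if out.ndim == 0 else out


def regr_profile(params: VelocityProfileParams, x) -> np.ndarray | float:
    """REGR = dv/dx, in fraction per hour (multiply by 100 for % per h).

    dv/dx = vf * (k/n) * u * (1+u)^(-(1 + 1/n)),  u = exp(-k (x - x0)).
    Nonnegative everywhere.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    # Work in log space: u overflows for x far tipward of x0 while REGR -> 0.
    logu = -params.k * (x - params.x0)
    e = 1.0 + 1.0 / params.n
    out = params.vf * (params.k / params.n) * np.exp(logu - e * np.logaddexp(0.0, logu))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics for one velocity point cloud.

    at_bound marks fits that terminated on a parameter bound; with noisy
    clouds these are ridge solutions of the weakly identified (k, n) pair
    and describe the curve shape adequately but carry meaningless
    individual parameters, so they are excluded from RIL averaging.
    """

    params: VelocityProfileParams
    rss: float
    converged: bool
    n_points: int
    at_bound: bool = False


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_velocity_profile`.

    Bounds confine the parameters to biologically plausible ranges for
    Arabidopsis primary roots (velocities below 2 mm/h, zone steepness
    0.1-100 per mm, asymmetry 0.02-50).  reject_outliers enables one pass
    of 3*MAD residual rejection followed by a refit; off by default
    (plain least squares).
    """

    reject_outliers: bool = False
    max_nfev: int = 2000
    lower: tuple[float, float, float, float] = (1e-6, -2.0, 0.1, 0.02)
    upper: tuple[float, float, float, float] = (2.0, 3.0, 100.0, 50.0)


def _initial_guess(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Data-driven starting values (vf, x0, k, n)."""
    vf0 = float(np.percentile(v, 95))
    if vf0 <= 0:
        vf0 = max(float(np.max(v)), 1e-3)
    half = vf0 / 2.0
    order = np.argsort(x)
    xs, vs = x[order], v[order]
    above = np.nonzero(vs >= half)[0]
    x00 = float(xs[above[0]]) if above.size else float(np.median(xs))
    # local slope around x00 -> k0 via the logistic relation dv/dx|_{x0} = vf*k/4
    win = (xs > x00 - 0.1) & (xs < x00 + 0.1)
    if win.sum() >= 3 and np.ptp(xs[win]) > 0:
        slope = float(np.polyfit(xs[win], vs[win], 1)[0])
    else:
        slope = vf0 / max(np.ptp(xs), 1e-6)
    k0 = max(4.0 * slope / vf0, 0.5)
    return np.array([vf0, x00, k0, 1.0])


def _residuals(theta: np.ndarray, x: np.ndarray, v: np.ndarray) -> np.ndarray:
    vf, x0, k, n = theta
    logu = -k * (x - x0)
    return vf * np.exp(-np.logaddexp(0.0, logu) / n) - v


def fit_velocity_profile(
    cloud: VelocityPointCloud, options: FitOptions | None = None
) -> FitResult:
    """Least-squares fit of the flexible logistic model to a point cloud.

    Bounded (positivity on vf, k, n), deterministic given the cloud and
    options.  Non-convergence is flagged in the result, never silent.

    Raises
    ------
    ValueError
        If the cloud has fewer than 10 points or a degenerate x range.
    """
    options = options or FitOptions()
    x, v = cloud.x, cloud.v
    if len(cloud) < MIN_CLOUD_POINTS:
        raise ValueError(
            f"need at least {MIN_CLOUD_POINTS} observations, got {len(cloud)}"
        )
    if np.ptp(x) <= 1e-9:
        raise ValueError("x range is degenerate; cannot fit a profile")

    theta0 = _initial_guess(x, v)
    lo = np.array(options.lower)
    hi = np.array(options.upper)
    theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

    def solve(xd: np.ndarray, vd: np.ndarray) -> optimize.OptimizeResult:
        return optimize.least_squares(
            _residuals,
            theta0,
            args=(xd, vd),
            bounds=(lo, hi),
            max_nfev=options.max_nfev,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )

    sol = solve(x, v)
    if options.reject_outliers:
        res = _residuals(sol.x, x, v)
        mad = np.median(np.abs(res - np.median(res)))
        if mad > 0:
            keep = np.abs(res - np.median(res)) <= 3.0 * 1.4826 * mad
            if keep.sum() >= MIN_CLOUD_POINTS:
                sol = solve(x[keep], v[keep])
                x, v = x[keep], v[keep]

    params = VelocityProfileParams(*sol.x)
    rss = float(2.0 * sol.cost)
    span = hi - lo
    at_bound = bool(
        np.any(sol.x - lo <= 1e-6 * span) or np.any(hi - sol.x <= 1e-6 * span)
    )
    return FitResult(params=params, rss=rss, converged=bool(sol.status > 0),
                     n_points=x.size, at_bound=at_bound)


def average_ril_params(
    fits: list[VelocityProfileParams | FitResult],
) -> VelocityProfileParams:
    """Arithmetic mean of vf, x0, k, n across replicate fits.

    The RIL-average velocity curve is the curve with the averaged
    parameters, not the pointwise mean of curves.
    """
    if not fits:
        raise ValueError("need at least one fit to average")
    arrs = []
    for f in fits:
        p = f.params if isinstance(f, FitResult) else f
        arrs.append(p.as_array())
    mean = np.mean(arrs, axis=0)
    return VelocityProfileParams(*mean)


def regr_max_position(params: VelocityProfileParams) -> float:
    """Axial position of the REGR maximum: x0 - ln(n)/k (mm)."""
    return params.x0 - np.log(params.n) / params.k


def regr_max(params: VelocityProfileParams) -> float:
    """Maximum REGR in fraction per hour: vf*k*(1+n)^(-(1+1/n))."""
    return params.vf * params.k * (1.0 + params.n) ** -(1.0 + 1.0 / params.n)


def extract_traits(
    params: VelocityProfileParams,
    zone_fraction: float = 0.2,
) -> KinematicTraits:
    """Derive the four elongation-zone traits from fitted parameters.

    elongation_rate = vf (mm/h); regr_max in % per h; regr_max_position in
    mm; zone_length = width of {x : REGR(x) >= zone_fraction * REGR_max},
    located by bracketed root-finding on each flank of the peak.
    """
    if not (0.0 < zone_fraction < 1.0):
        raise ValueError("zone_fraction must be in (0, 1)")
    peak_x = regr_max_position(params)
    peak_val = regr_max(params)
    target = zone_fraction * peak_val

    def f(x: float) -> float:
        return regr_profile(params, x) - target

    # REGR -> 0 on both flanks, so brackets at +-w/k around the peak are
    # guaranteed once exp(-w) terms drop below zone_fraction.
    w = max(50.0, 10.0 + 2.0 * abs(np.log(zone_fraction)) + 2.0 * abs(np.log(params.n)))
    lo_bracket = peak_x - w / params.k
    hi_bracket = peak_x + w * max(params.n, 1.0) / params.k
    if f(lo_bracket) >= 0 or f(hi_bracket) >= 0:  # pragma: no cover - guarded
        raise ValueError("failed to bracket the zone edges")
    left = optimize.brentq(f, lo_bracket, peak_x, xtol=1e-9)
    right = optimize.brentq(f, peak_x, hi_bracket, xtol=1e-9)
    return KinematicTraits(
        elongation_rate=params.vf,
        regr_max=100.0 * peak_val,
        regr_max_position=peak_x,
        zone_length=right - left,
    )


def traits_from_cloud_fits(
    fits: list[FitResult],
    zone_fraction: float = 0.2,
    exclude_nonconverged: bool = True,
) -> tuple[VelocityProfileParams, KinematicTraits]:
    """Average replicate fits for one RIL, then extract traits.

    Traits come from the averaged parameters (the RIL-average curve), not
    from averaging per-replicate traits.  Non-converged and boundary
    (ridge) replicates are excluded by default; if every replicate sits on
    a bound the least-bad set (all fits) is refused with an error rather
    than silently averaged.
    """
    usable = [
        f for f in fits
        if (f.converged or not exclude_nonconverged) and not f.at_bound
    ]
    if not usable:
        raise ValueError("no converged interior fits to average")
    avg = average_ril_params(usable)
    return avg, extract_traits(avg, zone_fraction=zone_fraction)
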