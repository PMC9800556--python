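"""Confidence-contour profiling and binding-flux partitioning.

The contour profile of a parameter is the chi-square of the global fit,
re-minimized over all remaining free parameters, as the parameter is
stepped over a grid and held fixed — normalized to the best-fit
chi-square.  The confidence threshold on the chi-square ratio comes from
the F distribution: ratio* = 1 + p/(n-p) * F^{-1}(1-alpha; p, n-p) for p
free parameters and n data points, so the interval where the profile
stays below ratio* is the (1-alpha) confidence interval.

Binding-flux shares partition DNA association events between the
enzyme's parallel binding sites by integrating the gross (one-way)
forward association flux k_site * [E][D] over the binding reaction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .core import ConfigurationError, simulate


def chi2_threshold(n_points, n_free_params, alpha=0.05):
    """F-statistic chi-square ratio bound for a (1-alpha) interval."""
    n, p = int(n_points), int(n_free_params)
    if not (n > p >= 1):
        raise ConfigurationError("need n_points > n_free_params >= 1")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return 1.0 + p / (n - p) * f_dist.ppf(1.0 - alpha, p, n - p)


@dataclass
class ContourProfile:
    symbol: str
    values: np.ndarray
    ratios: np.ndarray
    threshold: float
    best_value: float
    ci: tuple  # (lo, hi); an endpoint is None when only a one-sided limit
    failed: tuple = ()

    @property
    def one_sided(self):
        return self.ci[0] is None or self.ci[1] is None

    def covers(self, value):
        lo = self.ci[0] if self.ci[0] is not None else -np.inf
        hi = self.ci[1] if self.ci[1] is not None else np.inf
        return lo <= value <= hi

    def to_frame(self):
        return pd.DataFrame(
            {"param": self.symbol, "trial_value": self.values,
             "chi2_ratio": self.ratios}
        )


def _crossing(values, ratios, threshold):
    """Threshold crossing, interpolated with a local quadratic.

    The profile is locally parabolic in log10(value); a straight chord
    between coarse grid points overshoots a convex curve and biases the
    crossing inward, so fit a parabola through the bracketing pair plus
    the nearest third point and solve it for the threshold.
    """
    x = np.log10(values)
    for i in range(len(values) - 1):
        r0, r1 = ratios[i], ratios[i + 1]
        if (r0 - threshold) * (r1 - threshold) < 0:
            idx = [i, i + 1]
            if i + 2 < len(values):
                idx.append(i + 2)
            elif i - 1 >= 0:
                idx.insert(0, i - 1)
            if len(idx) == 3:
                coeffs = np.polyfit(x[idx], np.asarray(ratios)[idx], 2)
                roots = np.roots(coeffs - np.array([0.0, 0.0, threshold]))
                roots = roots[np.isreal(roots)].real
                inside = roots[(roots >= x[i] - 1e-12) & (roots <= x[i + 1] + 1e-12)]
                if inside.size:
                    return float(10 ** inside[0])
            w = (threshold - r0) / (r1 - r0)
            return float(10 ** (x[i] * (1 - w) + x[i + 1] * w))
    return None


def confidence_profile(
    fit_result,
    symbol,
    n_side=15,
    span_decades=0.5,
    alpha=0.05,
    max_expansions=2,
    max_nfev=None,
):
    """Profile one parameter of a converged global fit.

    Starting from the best fit, the parameter is clamped at log-spaced
    trial values (``n_side`` per side over ``span_decades``, expanded up
    to ``max_expansions`` times until the threshold is crossed or the
    parameter's bounds are hit) and the remaining free parameters are
    re-optimized from the best-fit values.  Re-optimization failures at
    individual grid points are flagged, not fatal.
    """
    problem = fit_result.problem
    if problem is None:
        raise ConfigurationError("fit result does not carry its problem")
    if symbol not in fit_result.free_symbols:
        raise ConfigurationError(f"{symbol!r} was not free in the fit")
    best = fit_result.values()
    chi2_min = max(fit_result.chi2, 1e-300)
    threshold = chi2_threshold(problem.n_points, fit_result.n_free_params, alpha)
    b0 = best[symbol]
    lo_b, hi_b = problem.base_rates[symbol].bounds

    def profile_point(val):
        try:
            r = problem.fit(start=best, fixed={symbol: val}, max_nfev=max_nfev)
            return r.chi2 / chi2_min, True
        except Exception:
            return np.nan, False

    vals = [b0]
    ratios = [1.0]
    ok = [True]
    span = span_decades
    for _ in range(max_expansions + 1):
        grid_lo = 10 ** np.linspace(np.log10(b0) - span, np.log10(b0), n_side + 1)[:-1]
        grid_hi = 10 ** np.linspace(np.log10(b0), np.log10(b0) + span, n_side + 1)[1:]
        grid = np.concatenate([grid_lo, grid_hi])
        grid = grid[(grid >= lo_b) & (grid <= hi_b)]
        new = [v for v in grid if not np.any(np.isclose(v, vals, rtol=1e-9))]
        for v in new:
            r, success = profile_point(v)
            vals.append(v)
            ratios.append(r)
            ok.append(success)
        order = np.argsort(vals)
        v_arr = np.asarray(vals)[order]
        r_arr = np.asarray(ratios)[order]
        good = ~np.isnan(r_arr)
        below = v_arr[good][v_arr[good] <= b0]
        rb = r_arr[good][v_arr[good] <= b0]
        above = v_arr[good][v_arr[good] >= b0]
        ra = r_arr[good][v_arr[good] >= b0]
        lo_cross = _crossing(below, rb, threshold)
        hi_cross = _crossing(above, ra, threshold)
        lo_done = lo_cross is not None or (len(below) and below[0] <= lo_b * 1.001)
        hi_done = hi_cross is not None or (len(above) and above[-1] >= hi_b * 0.999)
        if lo_done and hi_done:
            break
        span *= 2
    order = np.argsort(vals)
    v_arr = np.asarray(vals)[order]
    r_arr = np.asarray(ratios)[order]
    failed = tuple(v for v, okk in zip(vals, ok) if not okk)
    # ratios below 1 can occur within optimizer tolerance; clamp for reporting
    r_arr = np.maximum(r_arr, 1.0)
    return ContourProfile(
        symbol=symbol, values=v_arr, ratios=r_arr, threshold=float(threshold),
        best_value=b0, ci=(lo_cross, hi_cross), failed=failed,
    )


@dataclass
class FluxReport:
    """Gross association flux per binding site under one condition."""

    flux_uM: dict
    fractions: dict
    conditions: dict

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ConfigurationError("flux fractions must sum to 1")

    def to_json_dict(self):
        return {
            "flux_uM": self.flux_uM,
            "fractions": self.fractions,
            "conditions": self.conditions,
        }


def binding_flux_shares(
    mechanism,
    rates,
    dna_uM,
    enzyme_uM,
    horizon_s=None,
    bound_fraction=0.999,
    n_grid=2000,
):
    """Partition of initial DNA binding events between enzyme sites.

    Integrates the gross forward flux k_site*[E][D] of each association
    step (reactions tagged ``assoc:<site>``) from mixing until the free
    substrate has dropped to ``1 - bound_fraction`` of its initial value
    (or over ``horizon_s`` if given), then normalizes.
    """
    net = mechanism.compiled()
    assoc = [(j, net.tags[j].split(":", 1)[1])
             for j in range(net.n_directed) if net.tags[j].startswith("assoc:")]
    if not assoc:
        raise ConfigurationError("mechanism declares no tagged association steps")
    kvals = net.kvals(rates)
    state = {"D27": dna_uM, "E": enzyme_uM}
    if horizon_s is None:
        # characteristic pseudo-first-order binding time sets the scale
        ktot = sum(kvals[j] for j, _ in assoc)
        horizon_s = max(20.0 / max(ktot * enzyme_uM, 1e-6), 1e-3)
        for _ in range(20):
            times = np.linspace(0.0, horizon_s, n_grid)
            traj = simulate(mechanism, rates, state, times)
            free = traj.conc_of("D27")
            if free[-1] <= (1.0 - bound_fraction) * dna_uM:
                break
            horizon_s *= 4
    else:
        times = np.linspace(0.0, float(horizon_s), n_grid)
        traj = simulate(mechanism, rates, state, times)
    e = traj.conc_of("E")
    d = traj.conc_of("D27")
    flux = {}
    for j, site in assoc:
        flux[site] = flux.get(site, 0.0) + float(
            np.trapezoid(kvals[j] * e * d, traj.times)
        )
    total = sum(flux.values())
    fractions = {k: v / total for k, v in flux.items()}
    return FluxReport(
        flux_uM=flux,
        fractions=fractions,
        conditions={"dna_uM": dna_uM, "enzyme_uM": enzyme_uM,
                    "horizon_s": float(traj.times[-1])},
    )
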