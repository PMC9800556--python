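"""Equation-based fits, titration corrections, and global mechanism fitting.

The conventional fits mirror standard transient-kinetics practice:
rising/falling multi-exponentials ``y = A0 + sum_i A_i (1 - e^(-b_i t))``,
the tight-binding quadratic, and the hyperbola.  All are solved by
variable projection: amplitudes enter linearly and are eliminated
analytically, so the nonlinear search runs only over the rates (or K_d).

``GlobalFitProblem`` fits one mechanism's rate constants simultaneously
to heterogeneous datasets (anisotropy/fluorescence traces, titrations,
quench-flow concentration tables).  Per-dataset observable scalings are
linear nuisance parameters and are profiled out exactly at every residual
evaluation; kinetic parameters are optimized in log10 space with box
bounds, respecting locked / lower-limit / upper-limit statuses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ConfigurationError, RateConstantSet, RateExpr, SimulationError
from .protocols import ProtocolSimulator


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

@dataclass
class ExpFitResult:
    a0: float
    phases: tuple  # ((amplitude, rate), ...) rates descending
    sse: float
    converged: bool = True

    @property
    def rates(self):
        return tuple(r for _, r in self.phases)

    @property
    def amplitudes(self):
        return tuple(a for a, _ in self.phases)

    def dominant_rate(self):
        """Rate of the phase carrying the largest |amplitude|."""
        return max(self.phases, key=lambda p: abs(p[0]))[1]

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.a0)
        for a, b in self.phases:
            y = y + a * (1.0 - np.exp(-b * t))
        return y


def _exp_design(t, rates):
    cols = [np.ones_like(t)]
    for b in rates:
        cols.append(1.0 - np.exp(-b * t))
    return np.column_stack(cols)


def fit_exponentials(times, values, n_phases=1, n_starts=6):
    """Least-squares fit of a 1-3 exponential relaxation.

    Multi-start over log-spaced rate guesses; amplitudes are solved
    linearly at every step.  Rates are reported in descending order.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if not 1 <= n_phases <= 3:
        raise ConfigurationError("n_phases must be 1, 2 or 3")
    if len(t) < 3 * n_phases + 1:
        raise ConfigurationError("too few points for the requested phase count")
    dt = np.min(np.diff(np.unique(t)))
    span = t.max() - t.min()
    lo, hi = 0.2 / max(span, 1e-12), 2.0 / max(dt, 1e-12)

    def residual(logb):
        B = _exp_design(t, 10.0**logb)
        amps, *_ = np.linalg.lstsq(B, y, rcond=None)
        return B @ amps - y

    best = None
    for g in np.geomspace(max(lo * 3, 1e-6), hi / 3, n_starts):
        logb0 = np.log10([g / (10.0**i) for i in range(n_phases)])
        logb0 = np.clip(logb0, np.log10(lo), np.log10(hi))
        try:
            res = least_squares(
                residual, logb0,
                bounds=(np.log10(lo), np.log10(hi)), max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConfigurationError("exponential fit failed to start")
    rates = 10.0**best.x
    B = _exp_design(t, rates)
    amps, *_ = np.linalg.lstsq(B, y, rcond=None)
    order = np.argsort(rates)[::-1]
    phases = tuple((float(amps[1 + i]), float(rates[i])) for i in order)
    sse = float(np.sum((B @ amps - y) ** 2))
    return ExpFitResult(a0=float(amps[0]), phases=phases, sse=sse,
                        converged=bool(best.status > 0))


def choose_n_phases(times, values, max_phases=3, improvement=0.05):
    """Fewest phases whose extra phase fails to improve SSE by >5%."""
    y = np.asarray(values, dtype=float)
    floor = 1e-16 * max(float(np.sum((y - y.mean()) ** 2)), 1e-30)
    best = fit_exponentials(times, values, 1)
    for n in range(2, max_phases + 1):
        if best.sse <= floor:  # already at machine precision
            break
        try:
            trial = fit_exponentials(times, values, n)
        except ConfigurationError:
            break
        if trial.sse < (1.0 - improvement) * best.sse:
            best = trial
        else:
            break
    return best


# ---------------------------------------------------------------------------
# equilibrium-binding fits
# ---------------------------------------------------------------------------

@dataclass
class QuadFitResult:
    a0: float
    amplitude: float
    kd_nM: float
    fixed_uM: float
    sse: float
    at_bound: bool = False


def _quad_bound_fraction(kd, e, s):
    b = kd + e + s
    return (b - np.sqrt(np.maximum(b * b - 4.0 * e * s, 0.0))) / (2.0 * s)


def fit_quadratic_binding(enzyme_uM, values, fixed_uM, kd_bounds=(1e-7, 1e3)):
    """Tight-binding quadratic fit; K_d reported in nM.

    The root is chosen so the bound fraction never exceeds
    min(E, S)/S.  Amplitude and offset are profiled out linearly.
    """
    e = np.asarray(enzyme_uM, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(e) < 5:
        raise ConfigurationError("quadratic fit needs at least 5 points")
    s = float(fixed_uM)

    def residual(logkd):
        frac = _quad_bound_fraction(10.0**logkd[0], e, s)
        B = np.column_stack([np.ones_like(e), frac])
        c, *_ = np.linalg.lstsq(B, y, rcond=None)
        return B @ c - y

    lb, ub = np.log10(kd_bounds)
    best = None
    for g in np.geomspace(max(kd_bounds[0] * 10, 1e-6), min(kd_bounds[1] / 10, 10.0), 7):
        res = least_squares(residual, [np.log10(g)], bounds=(lb, ub), max_nfev=200)
        if best is None or res.cost < best.cost:
            best = res
    kd = 10.0**best.x[0]
    frac = _quad_bound_fraction(kd, e, s)
    B = np.column_stack([np.ones_like(e), frac])
    c, *_ = np.linalg.lstsq(B, y, rcond=None)
    at_bound = bool(
        abs(best.x[0] - lb) < 1e-6 or abs(best.x[0] - ub) < 1e-6
    )
    return QuadFitResult(
        a0=float(c[0]), amplitude=float(c[1]), kd_nM=float(kd * 1e3),
        fixed_uM=s, sse=float(2 * best.cost), at_bound=at_bound,
    )


def fit_hyperbola(conc_uM, values, kd_bounds=(1e-7, 1e3)):
    """Hyperbolic binding fit y = A0 + A1*S/(Kd+S); K_d in nM."""
    s = np.asarray(conc_uM, dtype=float)
    y = np.asarray(values, dtype=float)

    def residual(logkd):
        frac = s / (10.0**logkd[0] + s)
        B = np.column_stack([np.ones_like(s), frac])
        c, *_ = np.linalg.lstsq(B, y, rcond=None)
        return B @ c - y

    lb, ub = np.log10(kd_bounds)
    best = None
    for g in np.geomspace(max(kd_bounds[0] * 10, 1e-6), min(kd_bounds[1] / 10, 10.0), 7):
        res = least_squares(residual, [np.log10(g)], bounds=(lb, ub), max_nfev=200)
        if best is None or res.cost < best.cost:
            best = res
    kd = 10.0**best.x[0]
    frac = s / (kd + s)
    B = np.column_stack([np.ones_like(s), frac])
    c, *_ = np.linalg.lstsq(B, y, rcond=None)
    return QuadFitResult(
        a0=float(c[0]), amplitude=float(c[1]), kd_nM=float(kd * 1e3),
        fixed_uM=float("nan"), sse=float(2 * best.cost),
    )


# ---------------------------------------------------------------------------
# inner-filter / dilution correction
# ---------------------------------------------------------------------------

def inner_filter_factor(x):
    """(1 - 10**x) / (ln(10) * (-x)) with the analytic limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = (1.0 - 10.0 ** x[nz]) / (np.log(10.0) * (-x[nz]))
    return out


def correct_inner_filter(raw, titrant_uM, epsilon=0.805, dilution_factors=None):
    """Undo dilution, then divide out the inverse-inner-filter factor.

    ``raw -> corrected -> raw`` round-trips to machine precision via
    :func:`uncorrect_inner_filter`.
    """
    if epsilon < 0:
        raise ConfigurationError("epsilon must be nonnegative")
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(titrant_uM, dtype=float)
    if dilution_factors is not None:
        raw = raw / np.asarray(dilution_factors, dtype=float)
    return raw / inner_filter_factor(epsilon * t)


def uncorrect_inner_filter(corrected, titrant_uM, epsilon=0.805, dilution_factors=None):
    corrected = np.asarray(corrected, dtype=float)
    t = np.asarray(titrant_uM, dtype=float)
    out = corrected * inner_filter_factor(epsilon * t)
    if dilution_factors is not None:
        out = out * np.asarray(dilution_factors, dtype=float)
    return out


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

@dataclass
class FitDataset:
    """One experiment entering a global fit."""

    protocol: object
    data: pd.DataFrame
    weight: float = 1.0
    noise_frac: float = 0.02
    quench_frac: float = 0.03


@dataclass
class GlobalFitResult:
    rates: RateConstantSet
    chi2: float
    n_points: int
    n_free_params: int
    free_symbols: tuple
    scalings: list
    success: bool
    message: str
    nfev: int
    start: dict
    unidentifiable: tuple = ()
    residual_table: pd.DataFrame | None = field(repr=False, default=None)
    problem: object = field(repr=False, default=None)

    def values(self):
        return {s: self.rates[s].value for s in self.free_symbols}


class GlobalFitProblem:
    """Weighted least squares of one mechanism against many datasets.

    chi-square is sum over points of ((y - yhat)/sigma)^2 with sigma the
    dataset's noise scale: ``noise_frac`` of the dynamic range for traces
    and titrations, ``quench_frac`` of total DNA for quench tables, each
    times 1/sqrt(dataset weight).
    """

    def __init__(self, datasets, rates, simulator=None):
        self.datasets = list(datasets)
        self.base_rates = RateConstantSet(rates)
        self.simulator = simulator or ProtocolSimulator(rtol=1e-6, atol=1e-10)
        referenced = set()
        for ds in self.datasets:
            mech, _ = self.simulator.mechanism_for(ds.protocol)
            for slot in mech.compiled().kslots:
                if isinstance(slot, RateExpr):
                    referenced |= set(slot.symbols)
                else:
                    referenced.add(slot)
        self.free_symbols = [
            s for s in self.base_rates.free_symbols() if s in referenced
        ]
        self._prep = [self._prepare(ds) for ds in self.datasets]
        self.n_points = int(sum(p["n"] for p in self._prep))

    # -- dataset preparation -----------------------------------------
    def _prepare(self, ds):
        p = ds.protocol
        if p.signal == "primer-length-table":
            labels = [lab for lab, _ in p.series]
            wide = (
                ds.data.pivot_table(index="time_s", columns="series",
                                    values="conc_uM", sort=True)
                .reindex(columns=labels)
            )
            y = wide.to_numpy()
            sigma = ds.quench_frac * p.dna_uM / np.sqrt(ds.weight)
            return {"ds": ds, "kind": "quench", "y": y, "labels": labels,
                    "sigma": sigma, "n": y.size}
        if p.kind == "titration":
            eps = p.titration.epsilon
            raw = np.asarray(ds.data["value"], dtype=float)
            factor = inner_filter_factor(
                eps * np.asarray(ds.data["enzyme_uM"], dtype=float)
            )
            ycorr = raw / factor
            # instrument noise is homoscedastic on the raw signal, so the
            # corrected points carry per-point sigma = sigma_raw / factor
            sigma_raw = ds.noise_frac * (raw.max() - raw.min()) / np.sqrt(ds.weight)
            sigma = np.maximum(sigma_raw, 1e-12) / factor
            return {"ds": ds, "kind": "titration", "y": ycorr,
                    "sigma": sigma, "n": ycorr.size}
        y = np.asarray(ds.data["value"], dtype=float)
        sigma = ds.noise_frac * (y.max() - y.min()) / np.sqrt(ds.weight)
        return {"ds": ds, "kind": "trace", "y": y,
                "sigma": max(sigma, 1e-12), "n": y.size}

    # -- residuals ----------------------------------------------------
    def _dataset_residual(self, prep, values):
        ds = prep["ds"]
        pred = self.simulator.predict(ds.protocol, values)
        if prep["kind"] == "quench":
            model = pred.table[prep["labels"]].to_numpy()
            resid = (prep["y"] - model) / prep["sigma"]
            return resid.ravel(), None
        B = pred.basis
        y = prep["y"]
        sigma = prep["sigma"]
        if np.ndim(sigma):  # per-point sigma: weighted projection
            Bw = B / sigma[:, None]
            c, *_ = np.linalg.lstsq(Bw, y / sigma, rcond=None)
        else:
            c, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = (y - B @ c) / sigma
        return resid, c

    def residuals(self, values, collect_scalings=False):
        out, scalings = [], []
        for prep in self._prep:
            r, c = self._dataset_residual(prep, values)
            out.append(r)
            scalings.append(c)
        r = np.concatenate(out)
        return (r, scalings) if collect_scalings else r

    def chi2(self, values):
        return float(np.sum(self.residuals(values) ** 2))

    # -- optimization -------------------------------------------------
    def fit(self, start=None, fixed=None, max_nfev=None):
        fixed = dict(fixed or {})
        free = [s for s in self.free_symbols if s not in fixed]
        base = self.base_rates.values_dict()
        base.update(fixed)
        start = dict(start or {})
        x0 = np.array([np.log10(start.get(s, base[s])) for s in free])
        lo = np.array([np.log10(self.base_rates[s].bounds[0]) for s in free])
        hi = np.array([np.log10(self.base_rates[s].bounds[1]) for s in free])
        x0 = np.clip(x0, lo, hi)

        def fun(x):
            values = dict(base)
            for s, v in zip(free, 10.0**x):
                values[s] = v
            try:
                return self.residuals(values)
            except SimulationError:
                return np.full(self.n_points, 1e4)

        if free:
            res = least_squares(
                fun, x0, bounds=(lo, hi), method="trf",
                diff_step=1e-3, ftol=1e-6, xtol=1e-7,
                max_nfev=max_nfev or 30 * (len(free) + 1),
            )
            xbest, success, message, nfev = res.x, res.status > 0, res.message, res.nfev
            jac = res.jac
        else:
            xbest, success, message, nfev, jac = x0, True, "no free parameters", 1, None

        values = dict(base)
        for s, v in zip(free, 10.0**xbest):
            values[s] = v
        resid, scalings = self.residuals(values, collect_scalings=True)
        chi2 = float(np.sum(resid**2))
        unident = ()
        if jac is not None and jac.size:
            norms = np.linalg.norm(jac, axis=0)
            ref = norms.max() if norms.max() > 0 else 1.0
            unident = tuple(s for s, nrm in zip(free, norms) if nrm < 1e-8 * ref)
        updates = {s: values[s] for s in self.free_symbols}
        rates = self.base_rates.updated(updates)
        rows = []
        i0 = 0
        for prep in self._prep:
            n = prep["n"]
            rows.append(pd.DataFrame({
                "dataset": prep["ds"].protocol.name,
                "residual": resid[i0:i0 + n],
            }))
            i0 += n
        return GlobalFitResult(
            rates=rates, chi2=chi2, n_points=self.n_points,
            n_free_params=len(free), free_symbols=tuple(free),
            scalings=scalings, success=bool(success), message=str(message),
            nfev=int(nfev), start={s: float(10.0**v) for s, v in zip(free, x0)},
            unidentifiable=unident,
            residual_table=pd.concat(rows, ignore_index=True), problem=self,
        )


def global_fit(datasets, rates, start=None, simulator=None, **kw):
    """Convenience wrapper: build a :class:`GlobalFitProblem` and fit."""
    return GlobalFitProblem(datasets, rates, simulator=simulator).fit(start=start, **kw)
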