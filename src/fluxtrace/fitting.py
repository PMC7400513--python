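"""Weighted least-squares flux estimation from parallel labelling data.

The estimator minimizes the residual sum of squares between measured and
simulated fragment MIDs of all tracer experiments (one EMU solve per
tracer, sharing a single parameter vector) plus soft extracellular-flux
terms with relative error, subject to steady state (built into the
null-space parameterization), hard flux constraints and reaction bounds.
Optimization is multistart SLSQP; exchange fluxes are optimized on the
bounded transform e/(1+e); mixing-pool fractions are free parameters on
[0, 1]. Goodness of fit is a chi-squared test of the minimal RSS, and
per-flux confidence intervals are profile-likelihood grid searches with
bisection refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .correction import AbundanceTable, build_matrix
from .emu import EMUNetwork
from .errors import ConvergenceError, DegenerateFitError, EMUSingularityError
from .network import FluxVector, NetworkModel, parameterize

_PENALTY = 1e12


@dataclass
class MIDMeasurement:
    fragment: str
    experiment: str
    mean: np.ndarray
    sd: float | np.ndarray = 0.01

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("MID measurement SDs must be > 0")


@dataclass
class MeasurementSet:
    """Everything the flux fit consumes.

    mids: raw (derivatized-ion) or corrected (backbone) fragment MIDs per
    tracer experiment; soft_fluxes: {reaction: (value, relative sd)} fitted
    with relative error; hard_fluxes: {reaction: value} fixed exactly;
    fragments: {fragment id: FragmentSpec}; tracers: {experiment id:
    [TracerSpec]}.
    """

    mids: list
    soft_fluxes: dict
    hard_fluxes: dict
    fragments: dict
    tracers: dict
    quench_times: tuple = (24.0, 29.0, 32.0)
    space: str = "derivatized-raw"


@dataclass
class FitOptions:
    n_multistarts: int = 20
    seed: int = 0
    ftol: float = 1e-9
    max_iter: int = 300
    exchange_scale: float = 100.0
    exchange_umax: float = 0.99
    start_scale: float | None = None
    preferred_free: tuple = ()
    fitted_exchanges: tuple | None = None  # default: every reversible reaction

    def __post_init__(self):
        if self.n_multistarts < 1:
            raise ValueError("n_multistarts must be >= 1")


@dataclass
class ConfidenceInterval:
    reaction: str
    level: float
    lower: float | None  # None = not determined (unbounded direction)
    upper: float | None
    best: float

    def __post_init__(self):
        if self.lower is not None and self.upper is not None:
            if not (self.lower - 1e-9 <= self.best <= self.upper + 1e-9):
                raise ValueError(
                    f"CI for {self.reaction!r} does not contain the point estimate"
                )


@dataclass
class FitResult:
    flux: FluxVector
    mixing_fractions: dict
    rss: float
    n_measurements: int
    n_parameters: int
    theta: np.ndarray
    starts: list  # (rss, converged) per start
    problem: "FluxFitProblem" = field(repr=False, default=None)

    @property
    def dof(self) -> int:
        return self.n_measurements - self.n_parameters

    @property
    def chi2_threshold(self) -> float:
        return float(stats.chi2.ppf(0.95, self.dof))

    @property
    def passed(self) -> bool:
        return self.rss <= self.chi2_threshold


class FluxFitProblem:
    """Precompiled objective for one model + measurement set."""

    def __init__(
        self,
        model: NetworkModel,
        measurements: MeasurementSet,
        options: FitOptions | None = None,
        abundance: AbundanceTable | None = None,
    ):
        self.model = model
        self.measurements = measurements
        self.options = options or FitOptions()
        self.param = parameterize(
            model,
            fixed=measurements.hard_fluxes,
            preferred_free=list(self.options.preferred_free) or None,
        )
        self._rids = self.param.reaction_ids
        self._ridx = {r: i for i, r in enumerate(self._rids)}
        # v(u) = c + T u
        self._T = self.param.T
        self._c = self.param.v0 - self._T @ self.param.u0
        self.n_free = self.param.n_free

        if self.options.fitted_exchanges is None:
            self.exchange_ids = [r.id for r in model.reactions if r.reversible]
        else:
            self.exchange_ids = list(self.options.fitted_exchanges)
        self.n_exchange = len(self.exchange_ids)

        # mixing pools observed through fragments
        pools = []
        for frag in measurements.fragments.values():
            if frag.metabolite in model.mixing_rules and frag.metabolite not in pools:
                pools.append(frag.metabolite)
        self.mixing_pools = [(p, model.mixing_rules[p]) for p in sorted(pools)]
        self.n_mixing = sum(len(c) - 1 for _, c in self.mixing_pools)

        self.n_parameters = self.n_free + self.n_exchange + self.n_mixing

        self._mids = list(measurements.mids)
        if self._mids:
            frags = [measurements.fragments[f] for f in sorted(measurements.fragments)]
            self.emunet = EMUNetwork(model, frags)
            table = abundance or AbundanceTable.default()
            self._corr = {
                f.id: build_matrix(f, table).matrix
                for f in frags
            }
        else:
            self.emunet = None
            self._corr = {}
        self._soft = sorted(measurements.soft_fluxes.items())
        self.n_measurements = sum(len(m.mean) for m in self._mids) + len(self._soft)

        # direction-flux compilation
        if self.emunet is not None:
            self._dir_ridx = np.array(
                [self._ridx[r.id] for r, _ in self.emunet.directions], dtype=int
            )
            self._dir_sense = np.array(
                [s for _, s in self.emunet.directions], dtype=float
            )
            exch_pos = {rid: j for j, rid in enumerate(self.exchange_ids)}
            self._dir_exch = np.array(
                [
                    exch_pos.get(r.id, -1) if r.reversible else -1
                    for r, _ in self.emunet.directions
                ],
                dtype=int,
            )

        # reaction bound inequality: G theta + g >= 0 (skip infinite bounds)
        rows, offs = [], []
        for i, r in enumerate(model.reactions):
            trow = np.zeros(self.n_parameters)
            trow[: self.n_free] = self._T[i]
            if r.lower > -1e29:
                rows.append(trow.copy())
                offs.append(self._c[i] - r.lower)
            if r.upper < 1e29:
                rows.append(-trow)
                offs.append(r.upper + (-self._c[i]))
        # mixing: remaining fraction of each pool must stay >= 0
        pos = self.n_free + self.n_exchange
        for _, contributors in self.mixing_pools:
            k = len(contributors) - 1
            row = np.zeros(self.n_parameters)
            row[pos : pos + k] = -1.0
            rows.append(row)
            offs.append(1.0)
            pos += k
        self._G = np.array(rows)
        self._g = np.array(offs)

    # -- parameter vector handling ----------------------------------------

    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        u = theta[: self.n_free]
        eu = theta[self.n_free : self.n_free + self.n_exchange]
        mix = theta[self.n_free + self.n_exchange :]
        return u, eu, mix

    def exchange_values(self, eu) -> np.ndarray:
        s = self.options.exchange_scale
        return s * eu / (1.0 - eu)

    def net_vector(self, u) -> np.ndarray:
        return self._c + self._T @ u

    def mixing_dict(self, mix) -> dict:
        out = {}
        pos = 0
        for pool, contributors in self.mixing_pools:
            k = len(contributors) - 1
            fr = list(mix[pos : pos + k]) + [1.0 - float(np.sum(mix[pos : pos + k]))]
            out[pool] = dict(zip(contributors, fr))
            pos += k
        return out

    def flux_vector(self, theta) -> FluxVector:
        u, eu, _ = self.split(theta)
        v = self.net_vector(u)
        exch = dict(zip(self.exchange_ids, self.exchange_values(eu)))
        return FluxVector(net=dict(zip(self._rids, v)), exchange=exch)

    def bounds(self):
        b = []
        for rid in self.param.free_flux_ids:
            r = self.model.reaction(rid)
            b.append((r.lower, r.upper))
        b += [(0.0, self.options.exchange_umax)] * self.n_exchange
        b += [(0.0, 1.0)] * self.n_mixing
        return b

    # -- objective ---------------------------------------------------------

    def residuals(self, theta) -> np.ndarray:
        u, eu, mix = self.split(theta)
        v = self.net_vector(u)
        out = []
        if self._mids:
            exch = self.exchange_values(eu)
            f = v[self._dir_ridx] * self._dir_sense
            np.maximum(f, 0.0, out=f)
            has = self._dir_exch >= 0
            f[has] += exch[self._dir_exch[has]]
            sims = self.emunet.simulate_from_directions(
                f, self.measurements.tracers, self.mixing_dict(mix)
            )
            corrected_space = self.measurements.space == "backbone"
            for m in self._mids:
                sim = sims[m.experiment][m.fragment]
                if not corrected_space:
                    raw = self._corr[m.fragment] @ sim
                    total = raw.sum()
                    if not np.isfinite(total) or total <= 1e-12:
                        raise EMUSingularityError(
                            0, [f"fragment {m.fragment} ({m.experiment})"]
                        )
                    sim = raw / total
                n = len(m.mean)
                out.append((sim[:n] - m.mean) / m.sd)
        for rid, (value, rel_sd) in self._soft:
            out.append(np.atleast_1d((v[self._ridx[rid]] - value) / (rel_sd * abs(value))))
        return np.concatenate(out) if out else np.zeros(0)

    def rss(self, theta) -> float:
        try:
            r = self.residuals(theta)
        except EMUSingularityError:
            return _PENALTY
        return float(r @ r)

    # -- optimization ------------------------------------------------------

    def _constraints(self):
        if self._G.size == 0:
            return []
        return [
            {
                "type": "ineq",
                "fun": lambda th: self._G @ th + self._g,
                "jac": lambda th: self._G,
            }
        ]

    def _minimize(self, x0, extra_constraints=(), maxiter=None):
        res = optimize.minimize(
            self.rss,
            x0,
            method="SLSQP",
            bounds=self.bounds(),
            constraints=self._constraints() + list(extra_constraints),
            options={
                "maxiter": maxiter or self.options.max_iter,
                "ftol": self.options.ftol,
            },
        )
        return res

    def draw_start(self, rng) -> np.ndarray:
        scale = self.options.start_scale
        if scale is None:
            anchors = [abs(x) for x in self.measurements.hard_fluxes.values()] + [
                abs(val) for val, _ in self.measurements.soft_fluxes.values()
            ]
            scale = 1.5 * max(anchors) if anchors else 100.0
        theta = np.empty(self.n_parameters)
        for j, rid in enumerate(self.param.free_flux_ids):
            r = self.model.reaction(rid)
            lo = max(r.lower, -scale / 4)
            hi = min(r.upper, scale)
            theta[j] = rng.uniform(lo, hi)
        theta[self.n_free : self.n_free + self.n_exchange] = rng.uniform(
            0.01, 0.7, self.n_exchange
        )
        theta[self.n_free + self.n_exchange :] = rng.uniform(0.1, 0.9, self.n_mixing)
        return theta

    def fit(self) -> FitResult:
        rng = np.random.default_rng(self.options.seed)
        best = None
        starts = []
        for _ in range(self.options.n_multistarts):
            x0 = self.draw_start(rng)
            try:
                res = self._minimize(x0)
                # polish: SLSQP restarts often shave the tail of convergence
                res2 = self._minimize(res.x)
                if res2.fun <= res.fun:
                    res = res2
            except (ValueError, np.linalg.LinAlgError):
                starts.append((np.inf, False))
                continue
            starts.append((float(res.fun), bool(res.success)))
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError(
                "no SLSQP start converged", diagnostics=starts
            )
        theta = best.x
        return FitResult(
            flux=self.flux_vector(theta),
            mixing_fractions=self.mixing_dict(self.split(theta)[2]),
            rss=float(best.fun),
            n_measurements=self.n_measurements,
            n_parameters=self.n_parameters,
            theta=theta,
            starts=starts,
            problem=self,
        )


# ---------------------------------------------------------------------------
# public operations

def residual_ss(candidate, measurements: MeasurementSet, model: NetworkModel,
                options: FitOptions | None = None) -> float:
    """Weighted RSS of a candidate parameter vector (free net fluxes,
    transformed exchange fluxes, mixing fractions)."""
    problem = FluxFitProblem(model, measurements, options)
    r = problem.residuals(np.asarray(candidate, dtype=float))
    return float(r @ r)


def fit_fluxes(
    model: NetworkModel, measurements: MeasurementSet, options: FitOptions | None = None
) -> FitResult:
    """Best-of-multistart SLSQP flux estimate; deterministic given the seed."""
    return FluxFitProblem(model, measurements, options).fit()


@dataclass
class GoodnessOfFit:
    rss: float
    dof: int
    threshold: float
    passed: bool


def goodness_of_fit(fit: FitResult, alpha: float = 0.05) -> GoodnessOfFit:
    """Chi-squared acceptance of the minimal RSS at the given alpha."""
    if fit.dof <= 0:
        raise DegenerateFitError(
            f"model is overparameterized: {fit.n_measurements} measurements for "
            f"{fit.n_parameters} parameters"
        )
    threshold = float(stats.chi2.ppf(1 - alpha, fit.dof))
    return GoodnessOfFit(
        rss=fit.rss, dof=fit.dof, threshold=threshold, passed=fit.rss <= threshold
    )


def _profile(problem, theta0, eq_constraint):
    try:
        res = problem._minimize(theta0, extra_constraints=[eq_constraint])
    except (ValueError, np.linalg.LinAlgError):
        return None, None
    if not res.success and res.fun >= _PENALTY / 2:
        return None, None
    return float(res.fun), res.x


def grid_search_ci(
    fit: FitResult,
    reaction: str,
    level: float = 0.95,
    kind: str = "net",
    initial_step_frac: float = 0.05,
    min_step: float = 1.0,
    refine_frac: float = 0.001,
    max_steps: int = 60,
) -> ConfidenceInterval:
    """Profile-likelihood CI by outward grid scan with bisection refinement.

    The interval is {v : min RSS with the flux pinned at v <= RSS_best +
    chi2(level, 1)}. A direction whose profile never crosses the threshold
    before the flux bound is flagged not-determined (None).
    """
    problem = fit.problem
    threshold = fit.rss + float(stats.chi2.ppf(level, 1))

    if kind == "net":
        if reaction in problem.measurements.hard_fluxes:
            value = problem.measurements.hard_fluxes[reaction]
            return ConfidenceInterval(reaction, level, value, value, value)
        offset, row = problem.param.reaction_row(reaction)
        grad = np.zeros(problem.n_parameters)
        grad[: problem.n_free] = row
        if not np.any(np.abs(row) > 1e-12):
            value = float(offset)
            return ConfidenceInterval(reaction, level, value, value, value)
        best_val = float(fit.flux.net[reaction])
        r = problem.model.reaction(reaction)
        lo_bound, hi_bound = r.lower, r.upper

        def make_eq(c):
            return {
                "type": "eq",
                "fun": lambda th: np.array([offset + row @ th[: problem.n_free] - c]),
                "jac": lambda th: grad[None, :],
            }

    elif kind == "exchange":
        j = problem.exchange_ids.index(reaction)
        idx = problem.n_free + j
        s = problem.options.exchange_scale
        best_val = float(fit.flux.exchange[reaction])
        umax = problem.options.exchange_umax
        lo_bound, hi_bound = 0.0, s * umax / (1 - umax)
        grad = np.zeros(problem.n_parameters)
        grad[idx] = 1.0

        def make_eq(c):
            u = c / (s + c)
            return {
                "type": "eq",
                "fun": lambda th: np.array([th[idx] - u]),
                "jac": lambda th: grad[None, :],
            }

    else:
        raise ValueError("kind must be 'net' or 'exchange'")

    step0 = max(initial_step_frac * abs(best_val), min_step)
    tol = max(refine_frac * max(abs(best_val), min_step), 1e-9)

    def scan(direction):
        inside_val, inside_theta = best_val, fit.theta
        step = step0
        for _ in range(max_steps):
            c = inside_val + direction * step
            bound_hit = c <= lo_bound if direction < 0 else c >= hi_bound
            if bound_hit:
                c = lo_bound if direction < 0 else hi_bound
            rss_c, theta_c = _profile(problem, inside_theta, make_eq(c))
            if rss_c is None:
                warnings.warn(
                    f"profile re-optimization failed at {reaction}={c:.6g}; "
                    "point treated as outside the confidence region",
                    stacklevel=3,
                )
                rss_c = np.inf
            if rss_c <= threshold:
                inside_val, inside_theta = c, theta_c
                if bound_hit:
                    return None  # threshold never crossed: not determined
                step *= 1.6
                continue
            # bisection refinement between inside_val and c
            outside_val = c
            while abs(outside_val - inside_val) > tol:
                mid = 0.5 * (inside_val + outside_val)
                rss_m, theta_m = _profile(problem, inside_theta, make_eq(mid))
                if rss_m is not None and rss_m <= threshold:
                    inside_val, inside_theta = mid, theta_m
                else:
                    outside_val = mid
            return 0.5 * (inside_val + outside_val)
        return None

    lower = scan(-1.0)
    upper = scan(+1.0)
    if lower is not None:
        lower = min(lower, best_val)
    if upper is not None:
        upper = max(upper, best_val)
    return ConfidenceInterval(reaction, level, lower, upper, best_val)


@dataclass
class SignificanceCall:
    reaction: str
    significant: bool | None  # None = indeterminate (ND bound in the way)
    direction: str | None  # "increased"/"decreased" in condition B vs A


def compare_conditions(cis_a: dict, cis_b: dict) -> dict:
    """Significance by the no-overlap rule on 95% CIs.

    Takes {reaction: ConfidenceInterval} per condition. Touching intervals
    overlap (closed intervals) and are not significant; a not-determined
    bound that prevents the decision marks the reaction indeterminate.
    """
    out = {}
    for rid in cis_a:
        if rid not in cis_b:
            continue
        a, b = cis_a[rid], cis_b[rid]
        if a.upper is not None and b.lower is not None and a.upper < b.lower:
            out[rid] = SignificanceCall(rid, True, "increased")
        elif b.upper is not None and a.lower is not None and b.upper < a.lower:
            out[rid] = SignificanceCall(rid, True, "decreased")
        elif None in (a.lower, a.upper, b.lower, b.upper):
            out[rid] = SignificanceCall(rid, None, None)
        else:
            out[rid] = SignificanceCall(rid, False, None)
    return out


def assess_stationarity(times, mids_by_fragment: dict, alpha: float = 0.05) -> dict:
    """Isotopic stationarity per fragment across quench times.

    For each mass fraction, a linear regression slope against time is
    t-tested against zero; a fragment is stationary when no slope is
    significant at alpha after Bonferroni correction across its masses.
    Returns {fragment: True/False/None} (None = single time point).
    """
    times = np.asarray(times, dtype=float)
    out = {}
    for frag, mids in mids_by_fragment.items():
        mids = np.asarray(mids, dtype=float)
        if len(np.unique(times)) < 2:
            out[frag] = None
            continue
        n_masses = mids.shape[1]
        p_min = 1.0
        for m in range(n_masses):
            y = mids[:, m]
            res = stats.linregress(times, y)
            if res.stderr == 0 or not np.isfinite(res.stderr):
                p = 1.0 if abs(res.slope) < 1e-12 else 0.0
            else:
                p = res.pvalue
            p_min = min(p_min, p)
        out[frag] = bool(p_min >= alpha / n_masses)
    return out
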