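"""Extracellular rate estimation from culture time courses.

Cells growing exponentially at specific rate mu consume or secrete a
medium component at specific rate q (nmol/10^6 cells/h, signed: secretion
positive, uptake negative) while the component degrades spontaneously at
first-order rate k (relevant for glutamine). The amount A(t) then solves
dA/dt = q X0 e^(mu t) - k A, giving

    A(t) = A0 e^(-k t) + q X0 (e^(mu t) - e^(-k t)) / (mu + k)

with the limits A0 + q X0 (e^(mu t) - 1)/mu for k -> 0 and A0 + q X0 t
for mu, k -> 0. mu comes from a semi-logarithmic regression of cell
counts, k from cell-free decay series, and (A0, q) from least squares on
the amount model; confidence intervals for q are parametric bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateFitError


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed flux tables)."""
    factor = 10.0 ** ndigits
    value = math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
    return int(value) if ndigits == 0 else value


@dataclass
class TimeCourse:
    """A measured series: cell counts or metabolite amounts over time.

    kind is one of {"cell_count", "concentration", "cell_free_concentration"};
    replicate measurements appear as repeated time points.
    """

    id: str
    times: np.ndarray
    values: np.ndarray
    kind: str = "concentration"
    replicate: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        unique = np.unique(self.times)
        if np.any(np.diff(unique) <= 0):  # pragma: no cover - np.unique sorts
            raise ValueError("times must be increasing")


@dataclass
class ExoFitParams:
    A0: float
    k: float
    mu: float
    X0: float
    q: float

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("degradation rate k must be >= 0")
        if self.X0 <= 0:
            raise ValueError("initial cell number X0 must be > 0")


def amount_model(t, A0, q, mu, X0, k=0.0):
    """A(t) for exponential growth with first-order degradation.

    The growth/degradation kernel is evaluated as e^(-kt)·expm1((mu+k)t)
    /(mu+k), which stays accurate as mu+k -> 0 (limit: t·e^(-kt))."""
    t = np.asarray(t, dtype=float)
    d = mu + k
    decay = np.exp(-k * t)
    if d == 0.0:
        g = t * decay
    else:
        g = decay * np.expm1(d * t) / d
    return A0 * decay + q * X0 * g


@dataclass
class RateFit:
    """Log-linear rate estimate with its regression confidence interval."""

    rate: float
    ci: tuple
    se: float
    intercept: float
    n: int


def fit_growth_rate(counts: TimeCourse, level: float = 0.95) -> RateFit:
    """Specific growth rate from a semi-logarithmic fit of cell counts."""
    if len(counts.values) < 3:
        raise DegenerateFitError("growth fit needs at least 3 counts")
    if np.any(counts.values <= 0):
        raise DegenerateFitError("growth fit requires strictly positive counts")
    res = stats.linregress(counts.times, np.log(counts.values))
    n = len(counts.values)
    tq = stats.t.ppf(0.5 + level / 2, n - 2) if n > 2 else np.inf
    se = res.stderr if np.isfinite(res.stderr) else 0.0
    return RateFit(
        rate=float(res.slope),
        ci=(float(res.slope - tq * se), float(res.slope + tq * se)),
        se=float(se),
        intercept=float(res.intercept),
        n=n,
    )


def fit_degradation_rate(cell_free: TimeCourse, level: float = 0.95) -> RateFit:
    """First-order degradation rate from a cell-free decay series (k >= 0)."""
    if len(cell_free.values) < 3:
        raise DegenerateFitError("degradation fit needs at least 3 points")
    if np.any(cell_free.values <= 0):
        raise DegenerateFitError("degradation fit requires positive amounts")
    res = stats.linregress(cell_free.times, np.log(cell_free.values))
    k = -float(res.slope)
    n = len(cell_free.values)
    tq = stats.t.ppf(0.5 + level / 2, n - 2)
    se = res.stderr if np.isfinite(res.stderr) else 0.0
    ci = (-float(res.slope) - tq * se, -float(res.slope) + tq * se)
    if k < 0:
        warnings.warn(
            f"{cell_free.id!r}: cell-free series increases; degradation rate clamped to 0",
            stacklevel=2,
        )
        k = 0.0
    return RateFit(rate=k, ci=(max(ci[0], 0.0) if k == 0 else ci[0], ci[1]),
                   se=float(se), intercept=float(res.intercept), n=n)


@dataclass
class ExoFluxResult:
    metabolite: str
    q: float  # signed: secretion > 0, uptake < 0
    ci_signed: tuple
    A0: float
    n: int

    @property
    def direction(self) -> str:
        return "secretion" if self.q >= 0 else "uptake"

    @property
    def magnitude(self) -> float:
        return abs(self.q)

    @property
    def ci(self) -> tuple:
        """95% CI on |q|, ordered; straddling zero collapses the lower bound."""
        lo, hi = self.ci_signed
        if lo <= 0.0 <= hi:
            return (0.0, max(abs(lo), abs(hi)))
        lo, hi = sorted((abs(lo), abs(hi)))
        return (lo, hi)


def fit_exchange_rate(
    conc: TimeCourse,
    mu: float,
    X0: float,
    k: float = 0.0,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> ExoFluxResult:
    """Specific exchange rate q (and A0) by least squares on the amount model.

    With mu, X0 and k known the model is linear in (A0, q); the CI is a
    seeded parametric bootstrap from the residual variance.
    """
    t, y = conc.times, conc.values
    if len(y) < 3:
        raise DegenerateFitError("exchange fit needs at least 3 points")
    design = np.column_stack([np.exp(-k * t), amount_model(t, 0.0, 1.0, mu, X0, k)])
    theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    A0_hat, q_hat = float(theta[0]), float(theta[1])
    resid = y - design @ theta
    dof = len(y) - 2
    sigma = math.sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0

    if sigma == 0.0 or n_boot == 0:
        ci = (q_hat, q_hat)
    else:
        rng = np.random.default_rng(seed)
        pinv = np.linalg.pinv(design)
        yhat = design @ theta
        samples = yhat[None, :] + rng.normal(0.0, sigma, size=(n_boot, len(y)))
        qs = (pinv @ samples.T)[1]
        lo, hi = np.quantile(qs, [0.5 - level / 2, 0.5 + level / 2])
        ci = (min(float(lo), q_hat), max(float(hi), q_hat))
    return ExoFluxResult(metabolite=conc.id, q=q_hat, ci_signed=ci, A0=A0_hat, n=len(y))


def percent_change(parental: float, fhdim: float) -> int:
    """Signed percent change of a flux between conditions, integer-rounded:
    100 x (altered - parental) / parental."""
    if parental == 0:
        raise ZeroDivisionError("percent change undefined for zero parental flux")
    return int(round_half_away(100.0 * (fhdim - parental) / parental))


def flux_ratio(numerator: float, denominator: float) -> float:
    """Flux ratio (e.g. lactate secretion / glucose uptake), 2 decimals."""
    if denominator <= 0:
        raise ZeroDivisionError("flux ratio undefined for non-positive denominator")
    return round_half_away(numerator / denominator, 2)


def exchange_report(parental: dict, fhdim: dict) -> "pandas.DataFrame":  # noqa: F821
    """Comparative uptake/secretion table from two {metabolite: ExoFluxResult}
    mappings: |flux| at 1 decimal, 95% CI, integer percent change."""
    import pandas as pd

    rows = []
    for met in parental:
        p, f = parental[met], fhdim.get(met)
        if f is None:
            continue
        rows.append(
            {
                "metabolite": met,
                "direction": p.direction,
                "parental_flux": round_half_away(p.magnitude, 1),
                "parental_ci_lb": round_half_away(p.ci[0], 1),
                "parental_ci_ub": round_half_away(p.ci[1], 1),
                "fhdim_flux": round_half_away(f.magnitude, 1),
                "fhdim_ci_lb": round_half_away(f.ci[0], 1),
                "fhdim_ci_ub": round_half_away(f.ci[1], 1),
                "percent_change": percent_change(p.q, f.q),
            }
        )
    return pd.DataFrame(rows)
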