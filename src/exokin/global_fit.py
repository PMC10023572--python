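"""Global constrained fitting of elementary rate constants.

All lanes of all supplied experiments (titrations and pulse-chase runs) are
fitted simultaneously: the residual is the difference between observed band
fractions and the forward model's prediction for the candidate rate set,
summed over every (concentration, time, species) band.  Minimization is
trust-region nonlinear least squares on transformed parameters (rates and
half-saturation constants in log space, processivities in logit space) with
optional seeded multi-start, optionally iterated over alternating blocks of
fixed and floating parameters while the overall chi-square is tracked.

Constraint scheme mirrored from the experimental practice:

* measured K1/2 values link dissociation and association rate constants
  (``koff = K1/2 * kon``, so the pair floats as one degree of freedom);
* measured ``k_obs_max`` values bound the forward rate constants;
* measured processivities initialize the ``kf : koff`` ratio.

Confidence bounds come from a profile-likelihood scan (the chi-square ratio
criterion): one parameter is stepped along a log grid while all others are
re-optimized, and the interval where ``chi2 / chi2_min`` stays below a
threshold is reported.  Uncertainties of compound quantities use the
standard first-order propagation formulas
``sigma_K = K * sqrt((s_koff/koff)^2 + (s_kon/kon)^2)`` and
``sigma_P = P(1-P) * sqrt((s_koff/koff)^2 + (s_kf/kf)^2)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .forward_sim import (
    PulseChaseProtocol,
    TitrationProtocol,
    simulate_pulse_chase,
    simulate_timecourse,
)
from .kinetic_scheme import KineticScheme, RateSet, StepRates
from .synthetic_data import LadderRateProfile

__all__ = [
    "Dataset",
    "ConstraintSpec",
    "FitResult",
    "PerLengthParameterization",
    "ProfileParameterization",
    "global_fit",
    "compute_chi2",
    "compute_r2",
    "profile_bounds",
    "propagate_khalf_sigma",
    "propagate_p_sigma",
]

_KEYS = ["enzyme_conc_nM", "time_s", "species_length_nt"]


@dataclass(frozen=True)
class Dataset:
    """A band table tagged with the protocol that produced it."""

    table: pd.DataFrame
    protocol: TitrationProtocol | PulseChaseProtocol
    include_product: bool = True
    weight: float = 1.0

    @property
    def kind(self) -> str:
        return "pulse_chase" if isinstance(self.protocol, PulseChaseProtocol) else "titration"


@dataclass
class ConstraintSpec:
    """Measurement-derived constraints and the fixed/floating iteration plan.

    ``khalf_links`` ties ``koff_p`` to ``kon_p`` at the given lengths
    (removing ``koff_p`` from the floating set); ``kf_bounds`` restricts
    forward rates; ``p_initializers`` sets the starting ``kf:koff`` ratio;
    ``blocks`` lists the floating-parameter groups of each alternation
    stage (everything not in the current block stays fixed).
    """

    khalf_links: dict[int, float] = field(default_factory=dict)
    kf_bounds: dict[int, tuple[float, float]] = field(default_factory=dict)
    p_initializers: dict[int, float] = field(default_factory=dict)
    blocks: list[list[str]] | None = None

    def validate(self, scheme: KineticScheme) -> None:
        lengths = set(int(n) for n in scheme.ladder.cleavable_lengths)
        for d in (self.khalf_links, self.kf_bounds, self.p_initializers):
            bad = set(d) - lengths
            if bad:
                raise ValueError(f"constraint references non-cleavable lengths {sorted(bad)}")
        for n, (lo, hi) in self.kf_bounds.items():
            if not (0 <= lo < hi):
                raise ValueError(f"kf_bounds for length {n} must satisfy 0 <= lo < hi")


# ---------------------------------------------------------------------------
# parameterizations: named transformed vectors <-> schemes

_LOG_BOUNDS = (np.log(1e-8), np.log(1e4))
_LOGIT_BOUNDS = (-10.0, 10.0)


def _to_transformed(name: str, value: float) -> float:
    if name == "first_p" or name.startswith("p["):
        v = np.clip(value, 1e-6, 1 - 1e-6)
        return float(np.log(v / (1 - v)))
    return float(np.log(max(value, 1e-12)))


def _from_transformed(name: str, x: float) -> float:
    if name == "first_p" or name.startswith("p["):
        return float(1.0 / (1.0 + np.exp(-x)))
    return float(np.exp(x))


def _natural_se(name: str, x: float, x_se: float) -> float:
    v = _from_transformed(name, x)
    if name == "first_p" or name.startswith("p["):
        return v * (1 - v) * x_se
    return v * x_se


class ProfileParameterization:
    """Floats named fields of a :class:`LadderRateProfile`.

    The profile family keeps the per-length rate surface smooth and
    low-dimensional, which is what makes a 30-species ladder fittable from
    gel data; ``float_names`` picks the fields under optimization.
    """

    def __init__(
        self,
        base: LadderRateProfile,
        full_length: int = 34,
        product_length: int = 5,
        junction_length: int | None = 18,
        float_names: Sequence[str] | None = None,
    ):
        self.base = base
        self.full_length = full_length
        self.product_length = product_length
        self.junction_length = junction_length
        default = ("first_kf", "first_p", "first_khalf", "np_khalf", "np_koff", "peak_kf", "second_koff")
        self.names: tuple[str, ...] = tuple(float_names) if float_names is not None else default
        for nm in self.names:
            if not hasattr(base, nm):
                raise ValueError(f"unknown profile field {nm!r}")

    def theta0(self) -> np.ndarray:
        return np.array([_to_transformed(nm, getattr(self.base, nm)) for nm in self.names])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for nm in self.names:
            b = _LOGIT_BOUNDS if nm == "first_p" else _LOG_BOUNDS
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def natural(self, theta: np.ndarray) -> dict[str, float]:
        return {nm: _from_transformed(nm, x) for nm, x in zip(self.names, theta)}

    def build(self, theta: np.ndarray) -> KineticScheme:
        prof = replace(self.base, **self.natural(theta))
        return prof.to_scheme(self.full_length, self.product_length, self.junction_length)


_PARAM_RE = re.compile(r"^(kon_p|koff_p|kf|kon_np|koff_np)\[(\d+)\]$")


class PerLengthParameterization:
    """Floats individual per-length elementary rate constants.

    Parameter names follow ``rate[length]`` (e.g. ``kf[8]``).  Rates that
    are zero in the template stay fixed at zero unless explicitly floated;
    K1/2-linked lengths float ``kon_p`` only, with ``koff_p`` derived.
    """

    def __init__(
        self,
        template: KineticScheme,
        constraints: ConstraintSpec | None = None,
        float_names: Sequence[str] | None = None,
    ):
        self.template = template
        self.constraints = constraints or ConstraintSpec()
        self.constraints.validate(template)

        rates = template.rates
        # processivity initializers reset the template's kf:koff ratio
        if self.constraints.p_initializers:
            steps = {int(n): rates[int(n)] for n in template.ladder.cleavable_lengths}
            for n, p in self.constraints.p_initializers.items():
                s = steps[n]
                steps[n] = replace(s, koff_p=s.kf * (1 - p) / max(p, 1e-9))
            rates = RateSet(steps)
            self.template = KineticScheme(template.ladder, rates)

        if float_names is None:
            names = []
            for n in self.template.ladder.cleavable_lengths:
                s = rates[int(n)]
                for rn in ("kon_p", "koff_p", "kf", "kon_np", "koff_np"):
                    if rn == "koff_p" and int(n) in self.constraints.khalf_links:
                        continue
                    if getattr(s, rn) > 0:
                        names.append(f"{rn}[{int(n)}]")
            self.names = tuple(names)
        else:
            for nm in float_names:
                m = _PARAM_RE.match(nm)
                if not m:
                    raise ValueError(f"bad parameter name {nm!r}")
                if m.group(1) == "koff_p" and int(m.group(2)) in self.constraints.khalf_links:
                    raise ValueError(f"{nm} is derived through a K1/2 link and cannot float")
            self.names = tuple(float_names)

    def _template_value(self, name: str) -> float:
        rn, n = _PARAM_RE.match(name).groups()
        return getattr(self.template.rates[int(n)], rn)

    def theta0(self) -> np.ndarray:
        return np.array([_to_transformed(nm, max(self._template_value(nm), 1e-8)) for nm in self.names])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(len(self.names), _LOG_BOUNDS[0])
        hi = np.full(len(self.names), _LOG_BOUNDS[1])
        for i, nm in enumerate(self.names):
            rn, n = _PARAM_RE.match(nm).groups()
            if rn == "kf" and int(n) in self.constraints.kf_bounds:
                b_lo, b_hi = self.constraints.kf_bounds[int(n)]
                lo[i] = np.log(max(b_lo, 1e-12))
                hi[i] = np.log(b_hi)
        return lo, hi

    def natural(self, theta: np.ndarray) -> dict[str, float]:
        return {nm: _from_transformed(nm, x) for nm, x in zip(self.names, theta)}

    def build(self, theta: np.ndarray) -> KineticScheme:
        values = self.natural(theta)
        steps: dict[int, StepRates] = {}
        for n in self.template.ladder.cleavable_lengths:
            n = int(n)
            kw = {rn: getattr(self.template.rates[n], rn) for rn in ("kon_p", "koff_p", "kf", "kon_np", "koff_np")}
            for rn in kw:
                key = f"{rn}[{n}]"
                if key in values:
                    kw[rn] = values[key]
            if n in self.constraints.khalf_links:
                kw["koff_p"] = self.constraints.khalf_links[n] * kw["kon_p"]
            steps[n] = StepRates(**kw)
        return KineticScheme(self.template.ladder, RateSet(steps))


# ---------------------------------------------------------------------------
# residuals

def _aligned_predictor(
    datasets: Sequence[Dataset], template: KineticScheme
) -> tuple[np.ndarray, np.ndarray, Callable[[KineticScheme], np.ndarray]]:
    """Observed vector, weights, and scheme -> aligned prediction vector."""
    obs_parts, w_parts, index_maps = [], [], []
    for ds in datasets:
        pred0 = _predict(template, ds)
        key_to_row = {k: i for i, k in enumerate(map(tuple, pred0[_KEYS].to_numpy()))}
        obs_keys = list(map(tuple, ds.table[_KEYS].to_numpy()))
        missing = [k for k in obs_keys if k not in key_to_row]
        if missing:
            raise ValueError(
                f"observed bands not produced by the protocol (first: {missing[0]})"
            )
        index_maps.append(np.array([key_to_row[k] for k in obs_keys]))
        obs_parts.append(ds.table["fraction"].to_numpy(float))
        w_parts.append(np.full(len(obs_keys), np.sqrt(ds.weight)))
    obs = np.concatenate(obs_parts)
    w = np.concatenate(w_parts)

    def predict(scheme: KineticScheme) -> np.ndarray:
        parts = []
        for ds, idx in zip(datasets, index_maps):
            pred = _predict(scheme, ds)
            parts.append(pred["fraction"].to_numpy(float)[idx])
        return np.concatenate(parts)

    return obs, w, predict


def _predict(scheme: KineticScheme, ds: Dataset) -> pd.DataFrame:
    if isinstance(ds.protocol, PulseChaseProtocol):
        return simulate_pulse_chase(scheme, ds.protocol, "pred", ds.include_product)
    return simulate_timecourse(scheme, ds.protocol, "pred", ds.include_product)


# ---------------------------------------------------------------------------
# results

@dataclass
class FitResult:
    parameterization: object
    theta: np.ndarray                      # transformed optimum
    params: dict[str, float]               # natural-unit estimates
    stderr: dict[str, float]               # natural-unit standard errors
    scheme: KineticScheme
    chi2: float
    r2: float
    chi2_trace: list[float]
    converged: bool
    seed: int
    n_points: int
    cov: np.ndarray | None = None          # covariance in transformed space
    _predict: Callable | None = None
    _obs: np.ndarray | None = None
    _weights: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return max(self.n_points - len(self.params), 1)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof


def _numeric_jacobian(fun: Callable[[np.ndarray], np.ndarray], x: np.ndarray) -> np.ndarray:
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = 1e-6 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        J[:, i] = (fun(xp) - f0) / h
    return J


def global_fit(
    datasets: Sequence[Dataset],
    scheme_template: KineticScheme,
    constraints: ConstraintSpec | None = None,
    seed: int = 0,
    parameterization: ProfileParameterization | PerLengthParameterization | None = None,
    n_starts: int = 1,
    jitter: float = 0.3,
    tol: float = 1e-8,
    max_cycles: int = 50,
    max_nfev: int | None = None,
    verbose: bool = False,
) -> FitResult:
    """Fit rate constants to all experiments simultaneously.

    ``parameterization`` defaults to floating every nonzero per-length rate
    of ``scheme_template`` subject to ``constraints``.  Reproducible for a
    fixed ``seed`` (the only randomness is multi-start jitter).  If
    ``constraints.blocks`` names parameter groups, the fit alternates
    through them, re-fitting each block while the rest stay fixed, until
    the relative chi-square improvement over a full cycle drops below
    ``tol`` (the chi-square trace of accepted steps is recorded).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if not any(ds.kind == "titration" for ds in datasets):
        raise ValueError("need at least one titration dataset")
    if parameterization is None:
        parameterization = PerLengthParameterization(scheme_template, constraints)
    par = parameterization
    obs, w, predict = _aligned_predictor(datasets, scheme_template)

    def resid(theta: np.ndarray) -> np.ndarray:
        return w * (predict(par.build(theta)) - obs)

    lo, hi = par.bounds()
    theta0 = np.clip(par.theta0(), lo, hi)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(n_starts - 1):
        starts.append(np.clip(theta0 + rng.normal(0, jitter, theta0.size), lo, hi))

    blocks = constraints.blocks if constraints is not None else None
    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for start in starts:
        theta = start.copy()
        trace = [float(np.sum(resid(theta) ** 2))]
        converged = False
        if blocks:
            name_idx = {nm: i for i, nm in enumerate(par.names)}
            for _cycle in range(max_cycles):
                chi_before = trace[-1]
                for block in blocks:
                    idx = np.array([name_idx[nm] for nm in block if nm in name_idx], int)
                    if idx.size == 0:
                        continue

                    def block_resid(sub: np.ndarray, _theta=theta, _idx=idx) -> np.ndarray:
                        full = _theta.copy()
                        full[_idx] = sub
                        return resid(full)

                    sol = least_squares(
                        block_resid, theta[idx], bounds=(lo[idx], hi[idx]),
                        xtol=1e-12, ftol=1e-12, max_nfev=max_nfev,
                    )
                    theta[idx] = sol.x
                    trace.append(float(np.sum(sol.fun**2)))
                chi_after = trace[-1]
                if chi_before - chi_after <= tol * max(chi_before, 1e-300):
                    converged = True
                    break
        else:
            sol = least_squares(
                resid, theta, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, max_nfev=max_nfev,
                verbose=2 if verbose else 0,
            )
            theta = sol.x
            trace.append(float(np.sum(sol.fun**2)))
            converged = bool(sol.status > 0)
        chi2 = trace[-1]
        if best is None or chi2 < best[0]:
            best = (chi2, theta, trace, converged)

    chi2, theta, trace, converged = best
    J = _numeric_jacobian(resid, theta)
    n_pts = obs.size
    dof = max(n_pts - theta.size, 1)
    s2 = chi2 / dof
    cov = None
    stderr = {nm: np.nan for nm in par.names}
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {nm: _natural_se(nm, theta[i], d[i]) for i, nm in enumerate(par.names)}
    except np.linalg.LinAlgError:
        pass

    scheme = par.build(theta)
    pred = predict(scheme)
    result = FitResult(
        parameterization=par,
        theta=theta,
        params=par.natural(theta),
        stderr=stderr,
        scheme=scheme,
        chi2=chi2,
        r2=_pooled_r2(obs, pred),
        chi2_trace=trace,
        converged=converged,
        seed=seed,
        n_points=n_pts,
        cov=cov,
        _predict=predict,
        _obs=obs,
        _weights=w,
    )
    return result


def _pooled_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def compute_chi2(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    weights: pd.Series | np.ndarray | float | None = None,
) -> float:
    """Weighted sum of squared band residuals over matched lanes.

    Tables are matched on (dataset, concentration, time, species length);
    any unmatched band raises.  Default weights are 1.
    """
    keys = ["dataset_id"] + _KEYS
    merged = observed.merge(predicted, on=keys, how="outer", suffixes=("_obs", "_pred"), indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", keys].iloc[0].tolist()
        raise ValueError(f"mismatched band keys between tables (first: {bad})")
    r = merged["fraction_obs"].to_numpy(float) - merged["fraction_pred"].to_numpy(float)
    if weights is None:
        weights = 1.0
    w = np.broadcast_to(np.asarray(weights, float), r.shape)
    return float(np.sum(w * r**2))


def compute_r2(observed: pd.DataFrame, predicted: pd.DataFrame) -> float:
    """Coefficient of determination of observed vs predicted band fractions.

    Pooled over all matched bands (the observed-versus-simulated scatter of
    the whole fit).  Undefined (nan) when the observed fractions have zero
    variance.
    """
    keys = ["dataset_id"] + _KEYS
    merged = observed.merge(predicted, on=keys, how="inner", suffixes=("_obs", "_pred"))
    if len(merged) != len(observed) or len(merged) != len(predicted):
        raise ValueError("mismatched band keys between tables")
    return _pooled_r2(
        merged["fraction_obs"].to_numpy(float), merged["fraction_pred"].to_numpy(float)
    )


def profile_bounds(
    fit: FitResult,
    parameter: str,
    chi2_ratio_threshold: float | None = None,
    max_decades: float = 4.0,
    n_grid: int = 25,
) -> tuple[float, float]:
    """Profile-likelihood interval of one parameter from the chi-square ratio.

    The parameter is scanned on a log grid (logit grid for probabilities)
    away from its estimate; at each grid point all other parameters are
    re-optimized and the interval where ``chi2 <= threshold * chi2_min`` is
    returned, by linear interpolation of the crossing.  The default
    threshold corresponds to a one-sigma increase rescaled by the reduced
    chi-square, ``1 + 1/dof``; bound widths depend directly on this choice.
    A side that never crosses within ``max_decades`` is reported as
    unbounded (0 or inf; probabilities clamp to [0, 1]).
    """
    if not fit.converged:
        raise ValueError("profile_bounds requires a converged fit")
    par = fit.parameterization
    if parameter not in par.names:
        raise KeyError(f"unknown parameter {parameter!r}")
    if chi2_ratio_threshold is None:
        chi2_ratio_threshold = 1.0 + 1.0 / fit.dof
    # absolute floor so that exactly-fitting (chi2 ~ 0) data do not turn
    # round-off fluctuations into spurious bounds
    threshold = chi2_ratio_threshold * fit.chi2 + 1e-12 * fit.n_points
    i = list(par.names).index(parameter)
    obs, w, predict = fit._obs, fit._weights, fit._predict
    lo_b, hi_b = par.bounds()
    free = np.array([j for j in range(len(par.names)) if j != i])

    def chi2_at(x_i: float) -> float:
        if free.size == 0:
            theta = fit.theta.copy()
            theta[i] = x_i
            r = w * (predict(par.build(theta)) - obs)
            return float(np.sum(r**2))

        def sub_resid(sub: np.ndarray) -> np.ndarray:
            theta = fit.theta.copy()
            theta[free] = sub
            theta[i] = x_i
            return w * (predict(par.build(theta)) - obs)

        sol = least_squares(sub_resid, fit.theta[free], bounds=(lo_b[free], hi_b[free]),
                            xtol=1e-10, ftol=1e-10)
        return float(np.sum(sol.fun**2))

    is_prob = parameter == "first_p" or parameter.startswith("p[")
    span = max_decades * np.log(10.0) if not is_prob else max_decades * 2.5

    def scan(direction: int) -> float:
        grid = fit.theta[i] + direction * np.linspace(0, span, n_grid)[1:]
        grid = np.clip(grid, _LOGIT_BOUNDS[0] if is_prob else _LOG_BOUNDS[0],
                       _LOGIT_BOUNDS[1] if is_prob else _LOG_BOUNDS[1])
        prev_x, prev_c = fit.theta[i], fit.chi2
        for x in grid:
            c = chi2_at(x)
            if c > threshold:
                # linear interpolation of the crossing in transformed space
                frac = (threshold - prev_c) / max(c - prev_c, 1e-300)
                return _from_transformed(parameter, prev_x + frac * (x - prev_x))
            prev_x, prev_c = x, c
            if x == grid[-1] or abs(x - (_LOGIT_BOUNDS if is_prob else _LOG_BOUNDS)[max(direction, 0)]) < 1e-12:
                break
        if is_prob:
            return 0.0 if direction < 0 else 1.0
        return 0.0 if direction < 0 else np.inf

    lower = scan(-1)
    upper = scan(+1)
    est = fit.params[parameter]
    lower = min(lower, est)
    upper = max(upper, est)
    return lower, upper


def propagate_khalf_sigma(khalf: float, koff: float, sigma_koff: float, kon: float, sigma_kon: float) -> float:
    """First-order error of ``K1/2 = koff/kon`` from the rate-constant errors."""
    if koff <= 0 or kon <= 0:
        raise ValueError("rates must be positive")
    return khalf * np.sqrt((sigma_koff / koff) ** 2 + (sigma_kon / kon) ** 2)


def propagate_p_sigma(p: float, kf: float, sigma_kf: float, koff: float, sigma_koff: float) -> float:
    """First-order error of ``P = kf/(kf+koff)`` from the rate-constant errors."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if kf <= 0 or koff <= 0:
        raise ValueError("rates must be positive")
    return p * (1 - p) * np.sqrt((sigma_koff / koff) ** 2 + (sigma_kf / kf) ** 2)
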