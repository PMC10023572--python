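"""Single-experiment kinetic estimators.

These are the stepping stones that precede the global fit:

* :func:`fit_exponential` -- observed decay rate ``k_obs`` of a species,
  from ``y = a1 * exp(-b1 * t) + c``.
* :func:`fit_cascade` -- per-step rates of a chain of irreversible
  pseudo-first-order reactions fitted to a whole gel time course.
* :func:`fit_isotherm` -- ``k_obs`` versus enzyme concentration fitted to
  the binding isotherm ``k_obs = k_obs_max * E / (K1/2 + E)``, yielding the
  functional half-saturation constant and the saturating rate.
* :func:`release_distribution` / :func:`estimate_processivity` -- the
  pulse-chase method: once rebinding is blocked, an enzyme productively
  bound at length ``m`` walks down the ladder, committing at each step with
  probability ``P`` and otherwise releasing the RNA, so the final species
  distribution is an exactly invertible function of the per-step
  processivities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import least_squares

from .forward_sim import propagate

__all__ = [
    "ExponentialFit",
    "CascadeFit",
    "ObservedRateCurve",
    "IsothermFit",
    "ProcessivityProfile",
    "fit_exponential",
    "fit_cascade",
    "fit_isotherm",
    "kobs_curve_from_titration",
    "release_distribution",
    "estimate_processivity",
    "processivity_from_lanes",
]

_LOGIT_CLIP = 16.0  # |logit P| beyond this is treated as a bound hit


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass
class ExponentialFit:
    amplitude: float
    kobs: float
    offset: float
    amplitude_se: float | None
    kobs_se: float | None
    offset_se: float | None
    rss: float
    non_decaying: bool


def fit_exponential(times: Sequence[float], substrate_fraction: Sequence[float]) -> ExponentialFit:
    """Fit ``y = a1 * exp(-b1 * t) + c`` to a substrate-disappearance trace.

    ``b1`` (the observed rate constant) is bounded below by zero.  A signal
    whose decay is indistinguishable from zero is returned with the
    ``non_decaying`` flag set rather than silently.
    """
    t = np.asarray(times, float)
    y = np.asarray(substrate_fraction, float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any((y < -1e-9) | (y > 1 + 1e-9)):
        raise ValueError("fractions must lie in [0, 1]")

    model = Model(lambda t, a1, b1, c: a1 * np.exp(-b1 * t) + c)
    span = max(y.max() - y.min(), 1e-12)
    # crude rate guess from the time to fall halfway through the span
    half_idx = int(np.argmin(np.abs(y - (y.min() + span / 2))))
    b0 = np.log(2) / max(t[half_idx], t[0])
    params = model.make_params(a1=span, b1=b0, c=y.min())
    params["b1"].set(min=0.0)
    result = model.fit(y, params, t=t)

    b1 = float(result.params["b1"].value)
    b1_se = result.params["b1"].stderr
    decay_scale = float(result.params["a1"].value) * (1 - np.exp(-b1 * t[-1]))
    non_decaying = (
        abs(decay_scale) < 1e-6
        or b1 * t[-1] < 1e-6
        or (b1_se is not None and np.isfinite(b1_se) and b1 <= 2 * b1_se and decay_scale < 0.05)
    )
    return ExponentialFit(
        amplitude=float(result.params["a1"].value),
        kobs=b1,
        offset=float(result.params["c"].value),
        amplitude_se=result.params["a1"].stderr,
        kobs_se=b1_se,
        offset_se=result.params["c"].stderr,
        rss=float(np.sum(result.residual**2)),
        non_decaying=bool(non_decaying),
    )


@dataclass
class CascadeFit:
    lengths: np.ndarray          # cleavable lengths, descending (one per step)
    rates: np.ndarray            # per-step first-order rates, 1/s
    se: np.ndarray               # standard errors (inf where unidentifiable)
    rss: float
    unidentifiable: np.ndarray   # boolean mask per step


def _cascade_generator(rates: np.ndarray) -> np.ndarray:
    """Generator of the linear chain S0 -> S1 -> ... -> product."""
    m = rates.size
    B = np.zeros((m + 1, m + 1))
    for i, k in enumerate(rates):
        B[i, i] = -k
        B[i + 1, i] = k
    return B


def cascade_fractions(rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Species fractions of a pure irreversible cascade at the given times.

    Shape ``(n_times, n_steps + 1)``; columns ordered from the starting
    species down to the terminal product.  Evaluated through the matrix
    exponential of the bidiagonal generator, which remains exact when rates
    coincide (where the classic Bateman closed form degenerates).
    """
    x0 = np.zeros(rates.size + 1)
    x0[0] = 1.0
    return propagate(_cascade_generator(np.asarray(rates, float)), x0, np.asarray(times, float))


def fit_cascade(band_table: pd.DataFrame, lane_key: tuple[str, float] | None = None) -> CascadeFit:
    """Fit per-step rates of a sequential irreversible cascade to a lane set.

    ``band_table`` must contain a single (dataset, enzyme concentration)
    series, or ``lane_key = (dataset_id, enzyme_conc)`` selects one.  The
    model function is the exact solution of the linear chain of
    pseudo-first-order reactions over the observed ladder; rates are fitted
    in log space.  Steps whose rate does not influence the data within the
    observation window are reported with infinite standard error.
    """
    df = band_table
    if lane_key is not None:
        df = df[(df["dataset_id"] == lane_key[0]) & (df["enzyme_conc_nM"] == lane_key[1])]
    keys = df[["dataset_id", "enzyme_conc_nM"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("fit_cascade needs a single (dataset, enzyme_conc) series")

    pivot = df.pivot_table(index="time_s", columns="species_length_nt", values="fraction", aggfunc="mean")
    pivot = pivot.sort_index()[sorted(pivot.columns, reverse=True)]
    times = pivot.index.to_numpy(float)
    y = pivot.to_numpy(float)
    lengths = np.array(pivot.columns, int)
    n_steps = lengths.size - 1  # last observed length is treated as terminal
    if times.size < 2 or n_steps < 1:
        raise ValueError("need at least two time points and two species")

    def resid(logk: np.ndarray) -> np.ndarray:
        return (cascade_fractions(np.exp(logk), times) - y).ravel()

    k0 = np.full(n_steps, np.log(np.log(2) / np.median(times)))
    sol = least_squares(resid, k0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    rates = np.exp(sol.x)

    J = sol.jac
    JTJ = J.T @ J
    dof = max(sol.fun.size - n_steps, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    se = np.full(n_steps, np.inf)
    col_norm = np.linalg.norm(J, axis=0)
    unident = col_norm < 1e-10 * max(col_norm.max(), 1.0)
    try:
        cov = np.linalg.inv(JTJ) * s2
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        se = np.where(unident, np.inf, rates * se_log)
    except np.linalg.LinAlgError:
        unident = np.ones(n_steps, bool)
    return CascadeFit(
        lengths=lengths[:-1],
        rates=rates,
        se=se,
        rss=float(sol.fun @ sol.fun),
        unidentifiable=unident,
    )


@dataclass
class ObservedRateCurve:
    """Observed decay rates across an enzyme titration."""

    enzyme_concs: np.ndarray
    kobs: np.ndarray
    kobs_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.enzyme_concs = np.asarray(self.enzyme_concs, float)
        self.kobs = np.asarray(self.kobs, float)
        if self.kobs_se is not None:
            self.kobs_se = np.asarray(self.kobs_se, float)
        if self.enzyme_concs.shape != self.kobs.shape:
            raise ValueError("enzyme_concs and kobs must have equal length")
        if self.kobs_se is not None and self.kobs_se.shape != self.kobs.shape:
            raise ValueError("kobs_se must match kobs length")
        if np.any(self.kobs < 0):
            raise ValueError("kobs must be >= 0")


@dataclass
class IsothermFit:
    kobs_max: float
    khalf: float
    kobs_max_se: float | None
    khalf_se: float | None
    rss: float
    span_warning: bool
    khalf_unidentifiable: bool


def fit_isotherm(curve: ObservedRateCurve) -> IsothermFit:
    """Weighted least-squares fit of the binding isotherm.

    Model: ``k_obs = k_obs_max * E / (K1/2 + E)``.  Weights are inverse
    variances when ``kobs_se`` is available.  A concentration grid that does
    not straddle the fitted K1/2 sets ``span_warning``; a grid entirely in
    saturation leaves K1/2 unidentifiable and is flagged.
    """
    E = curve.enzyme_concs
    if E.size < 3:
        raise ValueError("need at least 3 concentrations")
    y = curve.kobs
    weights = None
    if curve.kobs_se is not None and np.all(curve.kobs_se > 0):
        weights = 1.0 / curve.kobs_se

    model = Model(lambda E, kobs_max, khalf: kobs_max * E / (khalf + E))
    k_guess = max(y.max(), 1e-12)
    half = k_guess / 2
    khalf_guess = float(E[np.argmin(np.abs(y - half))])
    params = model.make_params(kobs_max=k_guess, khalf=max(khalf_guess, E.min() / 10))
    params["kobs_max"].set(min=1e-15)
    params["khalf"].set(min=1e-15)
    result = model.fit(y, params, E=E, weights=weights)

    khalf = float(result.params["khalf"].value)
    khalf_se = result.params["khalf"].stderr
    span_warning = not (E.min() < khalf < E.max())
    unident = khalf < E.min() / 20 or (
        khalf_se is not None and np.isfinite(khalf_se) and khalf_se > 2 * khalf
    )
    return IsothermFit(
        kobs_max=float(result.params["kobs_max"].value),
        khalf=khalf,
        kobs_max_se=result.params["kobs_max"].stderr,
        khalf_se=khalf_se,
        rss=float(np.sum(result.residual**2)),
        span_warning=bool(span_warning),
        khalf_unidentifiable=bool(unident),
    )


def kobs_curve_from_titration(band_table: pd.DataFrame, species_length: int) -> ObservedRateCurve:
    """Per-concentration exponential ``k_obs`` of one species' disappearance."""
    concs, rates, ses = [], [], []
    for E, sub in band_table[band_table["species_length_nt"] == species_length].groupby("enzyme_conc_nM"):
        trace = sub.groupby("time_s")["fraction"].mean()
        fit = fit_exponential(trace.index.to_numpy(), trace.to_numpy())
        concs.append(float(E))
        rates.append(fit.kobs)
        ses.append(fit.kobs_se if fit.kobs_se is not None else np.nan)
    se = np.asarray(ses, float)
    return ObservedRateCurve(
        np.asarray(concs), np.asarray(rates), se if np.all(np.isfinite(se) & (se > 0)) else None
    )


def release_distribution(p_values: Sequence[float]) -> np.ndarray:
    """Final release probabilities of a bound enzyme that cannot rebind.

    ``p_values[i]`` is the commitment probability of step ``i`` counted from
    the starting (longest) species.  Entry ``i`` of the result is the
    probability of final release at species ``i`` (survive the first ``i``
    steps, then dissociate); the last entry is the residual probability of
    degrading all the way to the end product.  Sums to one exactly.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("processivities must lie in [0, 1]")
    surv = np.concatenate(([1.0], np.cumprod(p)))
    out = np.empty(p.size + 1)
    out[:-1] = surv[:-1] * (1 - p)
    out[-1] = surv[-1]
    return out


def _superposed_release(p: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Final distribution over species for bound mass ``weights`` per start.

    ``weights[m]`` is the productively bound mass starting at step index
    ``m`` (0 = longest species); ``p`` are per-step processivities aligned
    to the same indexing.  Returns a vector of length ``len(p) + 1``
    (species bands down to the end product).
    """
    C = p.size
    out = np.zeros(C + 1)
    for m in range(C):
        w = weights[m]
        if w == 0:
            continue
        sub = release_distribution(p[m:])
        out[m : C + 1] += w * sub
    return out


@dataclass
class ProcessivityProfile:
    lengths: np.ndarray       # cleavable lengths, descending
    p: np.ndarray             # per-step processivity
    se: np.ndarray            # standard errors (nan where at bound / unidentifiable)
    at_bound: np.ndarray      # P pinned at 0 or 1
    unidentifiable: np.ndarray
    rss: float


def estimate_processivity(
    prechase_bound: Sequence[float],
    postchase_final: Sequence[float],
    lengths: Sequence[int] | None = None,
) -> ProcessivityProfile:
    """Invert the release-distribution model for per-step processivities.

    Parameters
    ----------
    prechase_bound:
        Productively bound mass per cleavable length (descending; sums to
        at most 1) at the moment of the chase.
    postchase_final:
        Fully relaxed distribution of that bound mass over all species
        (cleavable lengths descending, then the end product) once every
        complex has resolved.
    lengths:
        Optional cleavable lengths for labelling the profile.

    The per-step probabilities are fitted by bounded least squares in logit
    space; estimates pinned at 0 or 1 and steps carrying no information
    (no bound mass ever transits them) are flagged.
    """
    w = np.asarray(prechase_bound, float)
    obs = np.asarray(postchase_final, float)
    C = w.size
    if obs.size != C + 1:
        raise ValueError("postchase_final must have one more entry than prechase_bound")
    if np.any(w < -1e-12):
        raise ValueError("prechase_bound must be nonnegative")
    if w.sum() > 1 + 1e-9:
        raise ValueError("prechase_bound must sum to <= 1")
    if w.sum() <= 0:
        raise ValueError("no bound mass to invert")

    # a step is informative only if some bound mass can reach it
    reachable = np.maximum.accumulate(w > 0)

    def resid(theta: np.ndarray) -> np.ndarray:
        return _superposed_release(_expit(theta), w) - obs

    sol = least_squares(
        resid, np.zeros(C), bounds=(-_LOGIT_CLIP, _LOGIT_CLIP),
        xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=50000,
    )
    p = _expit(sol.x)
    margin = 1e-2  # trust-region solvers stop just short of the box edge
    at_bound = np.abs(sol.x) >= _LOGIT_CLIP - margin
    p = np.where(sol.x >= _LOGIT_CLIP - margin, 1.0, p)
    p = np.where(sol.x <= -(_LOGIT_CLIP - margin), 0.0, p)

    J = sol.jac
    col_norm = np.linalg.norm(J, axis=0)
    unident = (~reachable) | (col_norm < 1e-9 * max(col_norm.max(), 1.0))
    se = np.full(C, np.nan)
    ok = ~(unident | at_bound)
    if ok.any():
        dof = max(obs.size - int(ok.sum()), 1)
        s2 = float(sol.fun @ sol.fun) / dof
        Jok = J[:, ok]
        try:
            cov = np.linalg.pinv(Jok.T @ Jok) * s2
            dp = p[ok] * (1 - p[ok])  # d expit / d theta
            se[ok] = np.sqrt(np.clip(np.diag(cov), 0, None)) * dp
        except np.linalg.LinAlgError:
            pass
    if lengths is None:
        lengths = np.arange(C, 0, -1)
    return ProcessivityProfile(
        lengths=np.asarray(lengths, int),
        p=p,
        se=se,
        at_bound=at_bound,
        unidentifiable=unident,
        rss=float(sol.fun @ sol.fun),
    )


def processivity_from_lanes(
    prechase_lane: Sequence[float],
    postchase_lane: Sequence[float],
    prechase_bound: Sequence[float] | None = None,
    lengths: Sequence[int] | None = None,
) -> ProcessivityProfile:
    """Processivity profile from total-band gel lanes.

    Gel lanes report total mass per length (free + bound), not the bound
    fraction, so the redistribution attributable to productive complexes is
    ``postchase - (prechase - bound)``.  ``prechase_bound`` (productively
    bound mass per cleavable length, model-supplied or otherwise known)
    must be provided; when it is omitted, the mass lost from each band,
    ``max(prechase - postchase, 0)``, is used as a rough lower-bound proxy
    -- adequate only when release seldom lands on upstream bands.
    """
    pre = np.asarray(prechase_lane, float)
    post = np.asarray(postchase_lane, float)
    if pre.size != post.size:
        raise ValueError("lanes must have equal length")
    C = pre.size - 1
    if prechase_bound is None:
        prechase_bound = np.clip(pre[:-1] - post[:-1], 0, None)
    b = np.asarray(prechase_bound, float)
    redistributed = post - np.concatenate((pre[:-1] - b, [pre[-1]]))
    return estimate_processivity(b, redistributed, lengths)
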