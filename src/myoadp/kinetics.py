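"""Stopped-flow transient fitting and apparent ADP-affinity extraction.

ATP-induced dissociation of pyrene-labelled actomyosin produces a
fluorescence decay: single-exponential without ADP, double-exponential in
its presence (the slow phase reporting ADP dissociation). Competitive
binding of ADP against ATP suppresses the fast-phase observed rate as

    k_rel = k_obs / k_obs,0 = 1 / (1 + [ADP] / K_ADP)

so fitting the normalized fast-phase rates against [ADP] with this
one-parameter hyperbola yields the apparent ADP affinity K_ADP (µM);
smaller K_ADP means tighter binding. The curve passes through (0, 1) by
construction, not as a fitted offset, and predicts k_rel = 0.5 exactly at
[ADP] = K_ADP.

Exponential fits use unweighted nonlinear least squares with data-driven
initialization (tail peeling for the double exponential) and a log-spaced
multi-start fallback, since multi-phase exponential fits are sensitive to
their starting rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "ExpFitResult",
    "BindingCurve",
    "KadpFit",
    "FitError",
    "average_traces",
    "fit_single_exponential",
    "fit_double_exponential",
    "relative_kobs",
    "fit_kadp",
]


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best residual."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class FluorescenceTrace:
    """A (time, signal) transient with its mixing-condition metadata."""

    time: np.ndarray
    signal: np.ndarray
    adp_um: float = 0.0
    atp_um: float = 25.0
    replicate: int = 0
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 20:
            raise ValueError("trace must have at least 20 points")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def condition(self) -> tuple[float, float]:
        return (self.adp_um, self.atp_um)


@dataclass
class ExpFitResult:
    """Phases ordered fast → slow; ``rates`` > 0 by construction."""

    amplitudes: tuple
    rates: tuple
    offset: float
    residual_norm: float
    rate_se: tuple
    warnings: list = field(default_factory=list)

    @property
    def k_fast(self) -> float:
        return self.rates[0]

    @property
    def k_slow(self) -> float:
        return self.rates[-1]


def average_traces(traces: list[FluorescenceTrace]) -> FluorescenceTrace:
    """Pointwise mean of same-condition traces on the first trace's time base.

    Later traces are linearly interpolated onto the first time base (the
    standard way an averaged transient is built from ≥ 8 shots).
    """
    if not traces:
        raise ValueError("no traces to average")
    cond = traces[0].condition
    for t in traces[1:]:
        if t.condition != cond:
            raise ValueError(f"mixed conditions: {t.condition} vs {cond}")
    base = traces[0].time
    stack = [traces[0].signal]
    for t in traces[1:]:
        stack.append(np.interp(base, t.time, t.signal))
    return FluorescenceTrace(time=base.copy(), signal=np.mean(stack, axis=0),
                             adp_um=cond[0], atp_um=cond[1])


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _single(t, a, k, c):
    return a * np.exp(-k * t) + c


def _double(t, af, kf, as_, ks, c):
    return af * np.exp(-kf * t) + as_ * np.exp(-ks * t) + c


def _residual(model, t, y, popt) -> float:
    r = y - model(t, *popt)
    return float(np.sqrt((r * r).sum()))


def _rate_guess(t: np.ndarray, y: np.ndarray, c0: float) -> float:
    """Crude rate from the time the decay reaches half its span."""
    a0 = y[0] - c0
    if abs(a0) < 1e-30:
        return 1.0 / max(t[-1] - t[0], 1e-12)
    half = c0 + 0.5 * a0
    crossing = np.nonzero((y - half) * np.sign(a0) <= 0)[0]
    t_half = t[crossing[0]] if crossing.size else 0.5 * (t[0] + t[-1])
    t_half = max(t_half - t[0], t[1] - t[0])
    return np.log(2.0) / t_half


def fit_single_exponential(trace: FluorescenceTrace,
                           max_starts: int = 5) -> ExpFitResult:
    """Least-squares fit of A·exp(−kt) + C with multi-start initialization."""
    t, y = trace.time, trace.signal
    c0 = float(np.mean(y[-max(len(y) // 10, 3):]))
    a0 = float(y[0] - c0)
    k0 = _rate_guess(t, y, c0)
    best = None
    best_res = np.inf
    for factor in (1.0, 0.1, 10.0, 0.01, 100.0)[:max_starts]:
        try:
            popt, pcov = curve_fit(_single, t, y, p0=(a0, k0 * factor, c0), maxfev=5000)
        except RuntimeError:
            continue
        if popt[1] <= 0:
            continue
        res = _residual(_single, t, y, popt)
        if res < best_res:
            best, best_cov, best_res = popt, pcov, res
    if best is None:
        raise FitError("single-exponential fit did not converge", best_res)
    se = float(np.sqrt(best_cov[1, 1])) if np.isfinite(best_cov[1, 1]) else np.nan
    return ExpFitResult(amplitudes=(float(best[0]),), rates=(float(best[1]),),
                        offset=float(best[2]), residual_norm=best_res,
                        rate_se=(se,))


def fit_double_exponential(trace: FluorescenceTrace,
                           min_rate_ratio: float = 3.0) -> ExpFitResult:
    """Least-squares fit of A_f e^{−k_f t} + A_s e^{−k_s t} + C.

    Initialization peels the slow phase off the tail before the joint fit;
    if that fails, a grid of log-spaced rate pairs (4 decades around the
    single-phase rate) is scanned and the best residual kept. Phases are
    ordered so k_f > k_s; a rate ratio below ``min_rate_ratio`` triggers an
    identifiability warning; a near-zero slow amplitude is warned as a
    degenerate (effectively single-exponential) trace.
    """
    t, y = trace.time, trace.signal
    c0 = float(np.mean(y[-max(len(y) // 10, 3):]))
    single = fit_single_exponential(trace)
    k_ref = single.rates[0]

    starts = []
    # peeling start: slow phase from the tail half, fast from the remainder
    tail = t > t[0] + 0.5 * (t[-1] - t[0])
    if tail.sum() >= 5:
        ys = y[tail] - c0
        ts = t[tail]
        pos = ys * np.sign(ys[np.argmax(np.abs(ys))]) > 0
        if pos.sum() >= 5:
            coef = np.polyfit(ts[pos], np.log(np.abs(ys[pos])), 1)
            ks0 = max(-coef[0], 1e-6)
            as0 = np.sign(ys[pos][0]) * np.exp(coef[1])
            starts.append((y[0] - c0 - as0, max(k_ref, 3 * ks0), as0, ks0, c0))
    for ff in (3.0, 10.0, 30.0):
        for sf in (0.03, 0.1, 0.3):
            starts.append((0.7 * (y[0] - c0), k_ref * ff, 0.3 * (y[0] - c0),
                           k_ref * sf, c0))

    best = None
    best_res = np.inf
    for p0 in starts:
        try:
            popt, pcov = curve_fit(_double, t, y, p0=p0, maxfev=8000)
        except RuntimeError:
            continue
        if popt[1] <= 0 or popt[3] <= 0:
            continue
        res = _residual(_double, t, y, popt)
        if res < best_res:
            best, best_cov, best_res = popt, pcov, res
        if res <= 1.05 * single.residual_norm * 1e-3:  # early exit on near-perfect fit
            break
    if best is None:
        raise FitError("double-exponential fit did not converge",
                       best_res if np.isfinite(best_res) else None)

    af, kf, as_, ks, c = best
    se = np.sqrt(np.abs(np.diag(best_cov)))
    if kf < ks:  # order phases fast -> slow
        af, kf, as_, ks = as_, ks, af, kf
        se = se[[2, 3, 0, 1, 4]]
    warns = []
    if ks > 0 and kf / ks < 1.05:
        # rates collapsed onto each other: the trace is effectively
        # single-exponential, so report that solution with zero slow amplitude
        warns.append("slow amplitude ~ 0: trace is effectively single-exponential")
        warnings.warn(warns[-1], stacklevel=2)
        return ExpFitResult(amplitudes=(float(single.amplitudes[0]), 0.0),
                            rates=(float(single.rates[0]), float(single.rates[0])),
                            offset=single.offset,
                            residual_norm=single.residual_norm,
                            rate_se=(single.rate_se[0], np.nan), warnings=warns)
    if ks > 0 and kf / ks < min_rate_ratio:
        warns.append(f"phase rates within {min_rate_ratio}x: identifiability is weak")
        warnings.warn(warns[-1], stacklevel=2)
    amp_scale = max(abs(af), abs(as_), abs(y[0] - c))
    if abs(as_) < 1e-3 * amp_scale:
        warns.append("slow amplitude ~ 0: trace is effectively single-exponential")
        warnings.warn(warns[-1], stacklevel=2)
    return ExpFitResult(amplitudes=(float(af), float(as_)),
                        rates=(float(kf), float(ks)), offset=float(c),
                        residual_norm=best_res,
                        rate_se=(float(se[1]), float(se[3])), warnings=warns)


# ---------------------------------------------------------------------------
# binding curve / K_ADP
# ---------------------------------------------------------------------------

def relative_kobs(k_obs: float, k_obs_0: float) -> float:
    """k_rel = k_obs / k_obs,0 (reference must be positive)."""
    if k_obs_0 <= 0:
        raise ValueError("zero-ADP reference rate must be positive")
    return k_obs / k_obs_0


@dataclass
class BindingCurve:
    """k_rel vs [ADP] points, optionally with per-replicate curves.

    ``k_rel`` is the (mean) normalized fast-phase rate at each [ADP];
    ``replicates`` optionally holds an (n_replicates, n_points) array of
    individual-experiment curves; ``k0`` the zero-ADP reference rate (1/s).
    """

    adp_um: np.ndarray
    k_rel: np.ndarray
    k0: float = np.nan
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adp_um = np.asarray(self.adp_um, dtype=float)
        self.k_rel = np.asarray(self.k_rel, dtype=float)
        if self.adp_um.shape != self.k_rel.shape:
            raise ValueError("adp and k_rel must have equal length")
        if (self.adp_um < 0).any():
            raise ValueError("ADP concentrations must be non-negative")
        zero = np.isclose(self.adp_um, 0.0)
        if zero.any() and not np.allclose(self.k_rel[zero], 1.0, atol=1e-9):
            raise ValueError("k_rel at [ADP]=0 must equal 1 by definition")
        if self.replicates is not None:
            self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            if self.replicates.shape[1] != self.adp_um.size:
                raise ValueError("replicate curves must match the [ADP] grid")


@dataclass
class KadpFit:
    k_adp: float
    se: float
    replicate_estimates: list
    residual_norm: float
    warnings: list = field(default_factory=list)


def _binding_model(adp, k):
    return 1.0 / (1.0 + adp / k)


def _fit_k(adp: np.ndarray, krel: np.ndarray) -> tuple[float, float, float]:
    # initial guess: concentration where k_rel crosses 0.5, else the median
    below = np.nonzero(krel <= 0.5)[0]
    k0 = float(adp[below[0]]) if below.size and adp[below[0]] > 0 else float(np.median(adp[adp > 0]))
    popt, pcov = curve_fit(_binding_model, adp, krel, p0=(k0,), maxfev=5000)
    res = float(np.sqrt(((krel - _binding_model(adp, *popt)) ** 2).sum()))
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    return float(popt[0]), se, res


def fit_kadp(curve: BindingCurve) -> KadpFit:
    """One-parameter fit of k_rel = 1/(1 + [ADP]/K_ADP).

    Requires ≥ 4 distinct concentrations including 0. With per-replicate
    curves the SE is the SD of the per-replicate K estimates; otherwise it
    comes from the fit curvature. A non-monotone curve (increase beyond a
    small tolerance) is warned, not rejected.
    """
    adp, krel = curve.adp_um, curve.k_rel
    if np.unique(adp).size < 4 or not np.isclose(adp, 0.0).any():
        raise ValueError("need >= 4 distinct [ADP] values including 0")
    warns = []
    order = np.argsort(adp)
    if np.any(np.diff(krel[order]) > 0.05):
        warns.append("binding curve is not monotone decreasing beyond noise")
        warnings.warn(warns[-1], stacklevel=2)
    k, se_curv, res = _fit_k(adp, krel)
    if k <= 0:
        raise FitError("K_ADP fit returned a non-positive affinity", res)
    rep_estimates: list[float] = []
    se = se_curv
    if curve.replicates is not None and curve.replicates.shape[0] >= 2:
        for row in curve.replicates:
            rep_estimates.append(_fit_k(adp, row)[0])
        se = float(np.std(rep_estimates, ddof=1))
    return KadpFit(k_adp=k, se=se, replicate_estimates=rep_estimates,
                   residual_norm=res, warnings=warns)
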