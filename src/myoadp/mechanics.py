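"""Myofibril force-trace decomposition and group comparison.

A calcium-activation experiment produces a force trace with two solution
switches: activation (force rises exponentially at rate k_ACT to a steady
state) and relaxation. Relaxation is biphasic: an early, linear slow phase
(slope k_REL,slow after amplitude normalization, duration t_REL,slow)
reporting cross-bridge detachment under load, followed by a fast
exponential decay (k_REL,fast) back to baseline. The decomposition is a
two-segment change-point fit: a candidate transition grid is scanned, each
candidate scored by the summed squared residual of a linear fit before it
and an exponential fit after it, and the global minimizer taken.

Group comparisons (genotype × solution) use a type-II sums-of-squares
two-way ANOVA, which is well-defined for the unbalanced designs typical of
per-myofibril data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import FitError

__all__ = [
    "ForceTrace",
    "RelaxationDecomposition",
    "MECHANICS_COLUMNS",
    "average_activations",
    "steady_state_force",
    "fit_kact",
    "decompose_relaxation",
    "compare_mechanics",
]

#: Solution-switch dead time excluded from all fit windows, s.
DEAD_TIME = 0.005

MECHANICS_COLUMNS = ("myofibril", "genotype", "solution", "force", "k_act",
                     "k_rel_slow", "t_rel_slow", "k_rel_fast")


@dataclass
class ForceTrace:
    """Time/force series with solution-switch event markers.

    ``events`` is an ordered list of (label, time) with labels from
    {"activate", "relax"}; ``condition`` carries pCa label, genotype and the
    nucleotide mix (mM ATP, mM ADP). The "5.6ADP" label denotes the
    50%-ADP solution (2.5 mM ATP + 2.5 mM ADP).
    """

    time: np.ndarray
    force: np.ndarray
    events: list
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")
        labels = [lab for lab, _ in self.events]
        for lab, t in self.events:
            if not (self.time[0] <= t <= self.time[-1]):
                raise ValueError(f"event {lab!r} at {t} outside the time range")
        if "activate" in labels and "relax" in labels:
            if self.event_time("activate") >= self.event_time("relax"):
                raise ValueError("activation must precede relaxation")
        if self.condition.get("pCa") == "5.6ADP":
            mix = (self.condition.get("atp_mm"), self.condition.get("adp_mm"))
            if mix != (2.5, 2.5):
                raise ValueError("5.6ADP solution implies 2.5 mM ATP + 2.5 mM ADP")

    def event_time(self, label: str) -> float:
        for lab, t in self.events:
            if lab == label:
                return t
        raise KeyError(f"no event {label!r}")

    def baseline(self) -> float:
        """Mean force before the activation event."""
        pre = self.time < self.event_time("activate")
        if not pre.any():
            raise ValueError("no pre-activation samples for baseline estimation")
        return float(self.force[pre].mean())

    def noise_sd(self) -> float:
        """Noise estimate: SD of the pre-activation force."""
        pre = self.time < self.event_time("activate")
        return float(self.force[pre].std())


def _same_condition(a: ForceTrace, b: ForceTrace) -> bool:
    keys = set(a.condition) | set(b.condition)
    return all(a.condition.get(k) == b.condition.get(k) for k in keys)


def average_activations(traces: list[ForceTrace]) -> ForceTrace:
    """Event-aligned pointwise mean of sequential activations.

    Traces are shifted so their activation events coincide, interpolated
    onto the first trace's (shifted) time base, and averaged. Conditions
    must match.
    """
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for t in traces[1:]:
        if not _same_condition(first, t):
            raise ValueError("cannot average traces from different conditions")
    t0 = first.event_time("activate")
    base = first.time - t0
    stack = [first.force]
    for tr in traces[1:]:
        stack.append(np.interp(base, tr.time - tr.event_time("activate"), tr.force))
    events = [(lab, t - t0) for lab, t in first.events]
    return ForceTrace(time=base, force=np.mean(stack, axis=0), events=events,
                      condition=dict(first.condition))


def steady_state_force(trace: ForceTrace, window: float = 0.5) -> float:
    """Baseline-subtracted mean force over the plateau window ending at the
    relaxation switch."""
    t_rel = trace.event_time("relax")
    t_act = trace.event_time("activate")
    if t_rel - window <= t_act:
        raise ValueError("plateau window extends before the activation event")
    sel = (trace.time >= t_rel - window) & (trace.time <= t_rel)
    return float(trace.force[sel].mean()) - trace.baseline()


def _rise(t, a, k):
    return a * (1.0 - np.exp(-k * t))


def fit_kact(trace: ForceTrace) -> float:
    """Rate of force development: single-exponential rise fit from the
    activation event (dead time excluded) to the relaxation switch."""
    t_act = trace.event_time("activate")
    t_end = trace.event_time("relax")
    base = trace.baseline()
    sel = (trace.time >= t_act + DEAD_TIME) & (trace.time < t_end)
    t = trace.time[sel] - t_act
    y = trace.force[sel] - base
    a0 = float(np.mean(y[-max(len(y) // 10, 3):]))
    half = np.nonzero(y >= 0.5 * a0)[0]
    k0 = np.log(2.0) / max(t[half[0]], t[1] - t[0]) if half.size else 1.0 / t[-1]
    best, best_res = None, np.inf
    for factor in (1.0, 0.3, 3.0, 0.1, 10.0):
        try:
            popt, _ = curve_fit(_rise, t, y, p0=(a0, k0 * factor), maxfev=5000)
        except RuntimeError:
            continue
        if popt[1] <= 0:
            continue
        res = float(((y - _rise(t, *popt)) ** 2).sum())
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise FitError("activation-rise fit did not converge")
    return float(best[1])


@dataclass
class RelaxationDecomposition:
    """Two-segment description of relaxation after the solution switch."""

    k_rel_slow: float       # |linear slope| / force at relaxation onset, 1/s
    t_rel_slow: float       # duration of the linear phase, s
    k_rel_fast: float       # exponential rate of the fast phase, 1/s
    transition_time: float  # absolute time of the slow->fast change point, s
    residuals: dict = field(default_factory=dict)
    monophasic: bool = False


def _exp_seg_logfit(ts: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Amplitude-weighted log-linear exponential fit y ≈ B·exp(−k·ts).

    Weights are y² (the standard linearization weighting, making the log-LS
    solution approximate the linear-space LS solution). Only samples with
    y above 1/50 of the segment maximum enter the regression.
    """
    ymax = ys.max()
    ok = ys > max(ymax / 50.0, 1e-12)
    if ok.sum() < 2:
        return float(ymax), 0.0
    w = ys[ok] ** 2
    x = ts[ok]
    ly = np.log(ys[ok])
    sw = w.sum()
    xm = (w * x).sum() / sw
    lym = (w * ly).sum() / sw
    denom = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (ly - lym)).sum() / denom if denom > 0 else 0.0
    b = np.exp(lym - slope * xm)
    return float(b), float(-slope)


def changepoint_scan(t: np.ndarray, y: np.ndarray,
                     candidates: np.ndarray) -> tuple[int, dict]:
    """Exhaustive SSE scan for the linear→exponential transition.

    ``t`` is time since the relaxation event, ``y`` baseline-subtracted
    force, both starting after the dead time. For each candidate split
    index the objective is SSE(linear fit before) + SSE(exponential fit
    after, parameters from the weighted log-linear regression, SSE in
    linear space). Returns the index minimizing the total (first minimum
    on ties) plus per-candidate diagnostics.
    """
    best_idx, best_sse = -1, np.inf
    diag = {"candidates": candidates, "sse": np.full(candidates.size, np.inf)}
    for j, c in enumerate(candidates):
        t1, y1 = t[:c + 1], y[:c + 1]
        if t1.size < 3 or t.size - c < 3:
            continue
        coef = np.polyfit(t1, y1, 1)
        sse1 = float(((y1 - np.polyval(coef, t1)) ** 2).sum())
        t2, y2 = t[c:] - t[c], y[c:]
        b, k = _exp_seg_logfit(t2, y2)
        sse2 = float(((y2 - b * np.exp(-k * t2)) ** 2).sum())
        total = sse1 + sse2
        diag["sse"][j] = total
        if total < best_sse:
            best_idx, best_sse = j, total
    if best_idx < 0:
        raise FitError("no admissible change-point candidate")
    return best_idx, diag


def decompose_relaxation(trace: ForceTrace,
                         search_min: float = 0.010,
                         search_max: float = 1.0,
                         max_candidates: int = 2000) -> RelaxationDecomposition:
    """Change-point decomposition of the relaxation transient.

    From the relaxation event (dead time excluded): segment 1 is fit
    linearly, segment 2 as an exponential decay to the pre-activation
    baseline; the transition is the global SSE minimizer over a candidate
    grid spanning (relax + ``search_min``, relax + ``search_max``). The
    normalized slow rate is |slope| divided by the fitted force at the
    relaxation onset (units 1/s); the fast rate is refined by nonlinear
    least squares at the selected transition. A trace whose best interior
    split does not improve on a single-segment fit is flagged monophasic.
    """
    t_rel = trace.event_time("relax")
    base = trace.baseline()
    noise = trace.noise_sd()
    sel = trace.time >= t_rel + DEAD_TIME
    t = trace.time[sel] - t_rel
    y = trace.force[sel] - base
    if y.size < 10:
        raise ValueError("too few samples after the relaxation event")
    onset = float(np.interp(t_rel, trace.time, trace.force)) - base
    if noise > 0 and onset < 3.0 * noise:
        raise ValueError("force at the relaxation onset is within noise; "
                         "no resolvable relaxation transient")

    in_window = np.flatnonzero((t >= search_min) & (t <= search_max))
    if in_window.size == 0:
        raise ValueError("change-point search window contains no samples")
    stride = max(1, int(np.ceil(in_window.size / max_candidates)))
    candidates = in_window[::stride]
    best_j, diag = changepoint_scan(t, y, candidates)
    c = int(candidates[best_j])

    # single-segment references for the monophasic check
    coef_full = np.polyfit(t, y, 1)
    sse_lin = float(((y - np.polyval(coef_full, t)) ** 2).sum())
    b_full, k_full = _exp_seg_logfit(t, y)
    sse_exp = float(((y - b_full * np.exp(-k_full * t)) ** 2).sum())
    monophasic = diag["sse"][best_j] >= min(sse_lin, sse_exp)
    if monophasic:
        warnings.warn("no interior change point improves on a single-segment "
                      "fit; trace flagged monophasic", stacklevel=2)

    coef = np.polyfit(t[:c + 1], y[:c + 1], 1)
    slope = float(coef[0])
    f_onset = float(np.polyval(coef, 0.0))
    if f_onset <= 0:
        raise FitError("non-positive fitted force at the relaxation onset")
    t2, y2 = t[c:] - t[c], y[c:]
    b0, k0 = _exp_seg_logfit(t2, y2)
    try:
        popt, _ = curve_fit(lambda tt, b, k: b * np.exp(-k * tt), t2, y2,
                            p0=(b0, max(k0, 1e-3)), maxfev=5000)
        k_fast = float(popt[1])
        sse2 = float(((y2 - popt[0] * np.exp(-popt[1] * t2)) ** 2).sum())
    except RuntimeError:
        k_fast, sse2 = k0, float(((y2 - b0 * np.exp(-k0 * t2)) ** 2).sum())
    sse1 = float(((y[:c + 1] - np.polyval(coef, t[:c + 1])) ** 2).sum())

    return RelaxationDecomposition(
        k_rel_slow=abs(slope) / f_onset,
        t_rel_slow=float(t[c]),
        k_rel_fast=k_fast,
        transition_time=t_rel + float(t[c]),
        residuals={"linear_sse": sse1, "exp_sse": sse2,
                   "scan_sse": float(diag["sse"][best_j])},
        monophasic=bool(monophasic),
    )


def compare_mechanics(table: pd.DataFrame, response: str) -> dict:
    """Two-way (genotype × solution) type-II ANOVA plus pairwise contrasts.

    ``table`` must contain ``genotype``, ``solution`` and the response
    column, with every genotype × solution cell populated by ≥ 2
    observations. Type-II sums of squares keep the factor tests well
    defined for unbalanced group sizes. Pairwise genotype contrasts within
    each solution are Welch t-tests with Holm correction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    for colname in ("genotype", "solution", response):
        if colname not in table.columns:
            raise ValueError(f"table lacks column {colname!r}")
    counts = table.groupby(["genotype", "solution"], observed=True).size()
    genos = table["genotype"].unique()
    sols = table["solution"].unique()
    if len(genos) < 2 or len(sols) < 2:
        raise ValueError("both factors need at least two levels")
    for g in genos:
        for s in sols:
            n = counts.get((g, s), 0)
            if n == 0:
                raise ValueError(f"empty design cell: {g} x {s}")
            if n < 2:
                raise ValueError(f"cell {g} x {s} has fewer than 2 observations")

    df = table.rename(columns={response: "_y"})
    model = smf.ols("_y ~ C(genotype) * C(solution)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    raw_p, labels, tstats = [], [], []
    for s in sols:
        sub = table[table["solution"] == s]
        a = sub.loc[sub["genotype"] == genos[0], response]
        b = sub.loc[sub["genotype"] == genos[1], response]
        tt = sps.ttest_ind(a, b, equal_var=False)
        raw_p.append(tt.pvalue)
        tstats.append(tt.statistic)
        labels.append(f"{genos[0]} vs {genos[1]} @ {s}")
    adj = multipletests(raw_p, method="holm")[1]
    contrasts = pd.DataFrame({"contrast": labels, "t": tstats,
                              "p_raw": raw_p, "p_holm": adj})
    return {"anova": anova, "contrasts": contrasts, "model": model}
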