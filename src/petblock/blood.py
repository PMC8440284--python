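"""Arterial blood modelling: from discrete samples to a plasma input function.

The metabolite-corrected plasma input driving the compartment models is
composed as ``C_p(t) = C_b(t - delay) * POB(t - delay) * PPf(t - delay)``:

* ``C_b`` — whole-blood activity, fitted piecewise (linear rise to the
  measured peak, then a sum of 2-3 decaying exponentials, continuous at
  the peak; exponentials extrapolate beyond the last sample).
* ``POB`` — plasma-over-blood activity ratio, an extended Hill curve
  anchored at the earliest measured ratio.
* ``PPf`` — parent plasma fraction (fraction of plasma activity that is
  unmetabolised tracer), an extended Hill curve declining from 1:
  ``PPf(t) = 1 - a * t^b / (t^b + c)``.
* ``delay`` — a single time shift between blood sampling at the radial
  artery and the brain signal, fitted by a grid search that minimises the
  weighted residual of a one-tissue-compartment fit to the whole-brain TAC
  over the early part of the scan.

All activities are assumed decay-corrected; no decay constant is applied
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._conv import DEFAULT_DT, exp_conv, fine_grid, frame_average
from .frames import TAC

#: minutes at which discrete samples are manually withdrawn
MANUAL_SAMPLE_TIMES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
#: subset analysed by HPLC for the parent fraction
HPLC_SAMPLE_TIMES = (5.0, 10.0, 20.0, 30.0, 50.0, 70.0, 90.0)
#: samples used to cross-calibrate continuous and discrete sampling
CALIBRATION_TIMES = (5.0, 10.0, 15.0)


@dataclass
class BloodSeries:
    """Discrete arterial samples: whole blood, POB ratio and parent fraction.

    ``ppf`` may contain NaN at times without HPLC analysis.
    """

    times: np.ndarray
    wholeblood: np.ndarray
    pob: np.ndarray
    ppf: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wholeblood = np.asarray(self.wholeblood, dtype=float)
        self.pob = np.asarray(self.pob, dtype=float)
        self.ppf = np.asarray(self.ppf, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.wholeblood < 0):
            raise ValueError("whole-blood activity must be non-negative")
        if np.any(self.pob <= 0):
            raise ValueError("POB ratios must be positive")
        finite = np.isfinite(self.ppf)
        if np.any((self.ppf[finite] <= 0) | (self.ppf[finite] > 1)):
            raise ValueError("parent fractions must lie in (0, 1]")


# ---------------------------------------------------------------------------
# component models


@dataclass(frozen=True)
class HillFraction:
    """Extended Hill parent fraction: PPf(t) = 1 - a t^b / (t^b + c)."""

    a: float
    b: float
    c: float

    def __call__(self, t):
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        tb = np.power(t, self.b, where=t > 0, out=np.zeros_like(t))
        return 1.0 - self.a * tb / (tb + self.c)


@dataclass(frozen=True)
class HillRatio:
    """Extended Hill ratio anchored at r0: POB(t) = r0 + a t^b / (t^b + c)."""

    r0: float
    a: float
    b: float
    c: float

    def __call__(self, t):
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        tb = np.power(t, self.b, where=t > 0, out=np.zeros_like(t))
        return self.r0 + self.a * tb / (tb + self.c)


@dataclass(frozen=True)
class WholeBloodModel:
    """Piecewise whole-blood curve: 0, linear rise, multi-exponential decay.

    Zero before ``t_on``, linear from (t_on, 0) to (t_peak, peak), then
    ``sum_j amps[j] * exp(-lambdas[j] (t - t_peak))`` with
    ``sum(amps) == peak`` (continuity at the peak).
    """

    t_on: float
    t_peak: float
    peak: float
    amps: tuple
    lambdas: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_on < self.t_peak):
            raise ValueError("need 0 <= t_on < t_peak")
        if self.peak <= 0 or any(a < 0 for a in self.amps) or any(l < 0 for l in self.lambdas):
            raise ValueError("peak must be positive; amplitudes and rates non-negative")
        if abs(sum(self.amps) - self.peak) > 1e-6 * self.peak:
            raise ValueError("amplitudes must sum to the peak value")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rise = (t > self.t_on) & (t <= self.t_peak)
        out[rise] = self.peak * (t[rise] - self.t_on) / (self.t_peak - self.t_on)
        tail = t > self.t_peak
        dt = t[tail] - self.t_peak
        acc = np.zeros_like(dt)
        for a, l in zip(self.amps, self.lambdas):
            acc += a * np.exp(-l * dt)
        out[tail] = acc
        return out


@dataclass
class InputFunction:
    """Delay-corrected, metabolite-corrected plasma input function."""

    wholeblood_model: WholeBloodModel
    pob_model: HillRatio
    ppf_model: HillFraction
    delay: float = 0.0

    def wholeblood(self, t):
        return self.wholeblood_model(np.asarray(t, dtype=float) - self.delay)

    def plasma(self, t):
        ts = np.asarray(t, dtype=float) - self.delay
        cp = self.wholeblood_model(ts) * self.pob_model(ts) * self.ppf_model(ts)
        return np.maximum(cp, 0.0)

    def shifted(self, extra_delay: float) -> "InputFunction":
        return replace(self, delay=self.delay + extra_delay)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HillFit:
    model: object
    rmse: float
    converged: bool
    message: str = ""


def fit_parent_fraction(times, ppf_samples) -> HillFit:
    """Fit the extended Hill parent-fraction model to HPLC samples."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(ppf_samples, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 parent-fraction samples")
    if np.any((y <= 0) | (y > 1)):
        raise ValueError("parent fractions must lie in (0, 1]")

    a0 = float(np.clip(1.0 - y.min(), 0.0, 1.0))
    # time at which the decline reaches half its total extent, as a c guess
    if a0 > 0:
        half = 1.0 - 0.5 * a0
        idx = np.argmin(np.abs(y - half))
        t_half = max(t[idx], 1.0)
    else:
        t_half = 30.0
    b0 = 1.5
    x0 = np.array([a0, b0, t_half**b0])

    def resid(p):
        return HillFraction(*p)(t) - y

    res = least_squares(
        resid, x0, bounds=([0.0, 1e-3, 1e-6], [1.0, 10.0, 1e6]), xtol=1e-14, ftol=1e-14
    )
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return HillFit(HillFraction(*res.x), rmse, bool(res.success), res.message)


def fit_pob(times, pob_samples) -> HillFit:
    """Fit the plasma-over-blood ratio with the extended Hill family.

    The curve is anchored at the earliest measured ratio; the Hill term then
    models the (usually rising) deviation from that anchor.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(pob_samples, dtype=float)
    if np.any(y <= 0):
        raise ValueError("POB ratios must be positive")
    if t.size < 4:
        raise ValueError("need at least 4 POB samples")
    r0 = float(y[0])  # anchor: the earliest measured ratio initialises the offset
    a0 = float(y[-1] - r0)
    x0 = np.array([r0, a0, 1.2, 30.0])

    def resid(p):
        return HillRatio(*p)(t) - y

    res = least_squares(
        resid,
        x0,
        bounds=([1e-3, -20.0, 1e-3, 1e-6], [20.0, 20.0, 10.0, 1e6]),
        xtol=1e-14,
        ftol=1e-14,
    )
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return HillFit(HillRatio(*res.x), rmse, bool(res.success), res.message)


@dataclass
class WholeBloodFit:
    model: WholeBloodModel
    n_exp: int
    rmse: float
    converged: bool
    message: str = ""


def _stick_fractions(u: np.ndarray) -> np.ndarray:
    """Map k-1 unit-interval parameters to k non-negative fractions summing to 1."""
    fracs = []
    remaining = 1.0
    for ui in u:
        fracs.append(remaining * ui)
        remaining *= 1.0 - ui
    fracs.append(remaining)
    return np.asarray(fracs)


def fit_wholeblood(times, values, n_exp: Sequence[int] = (2, 3)) -> WholeBloodFit:
    """Fit the piecewise whole-blood model; exponential order chosen by AIC."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.all(y <= 0):
        raise ValueError("whole-blood curve is non-positive everywhere")
    ipk = int(np.argmax(y))
    if ipk == y.size - 1 or ipk == 0:
        raise ValueError("whole-blood peak not identifiable (monotone series)")
    t_peak, peak = float(t[ipk]), float(y[ipk])

    # onset from a straight line through the rising samples
    rising = (t < t_peak) & (y > 0.02 * peak)
    if rising.sum() >= 2:
        slope, intercept = np.polyfit(t[rising], y[rising], 1)
        t_on = -intercept / slope if slope > 0 else 0.0
        t_on = float(np.clip(t_on, 0.0, t_peak - 1e-3))
    else:
        t_on = 0.0

    post = t >= t_peak
    tp, yp = t[post], y[post]

    best = None
    for k in sorted(n_exp):
        u0 = np.full(k - 1, 0.75)
        lam0 = np.array([3.0, 0.3, 0.02][:k])
        x0 = np.concatenate([u0, lam0])
        lb = np.concatenate([np.full(k - 1, 1e-6), np.full(k, 1e-5)])
        ub = np.concatenate([np.full(k - 1, 1.0 - 1e-6), np.full(k, 60.0)])

        def resid(p, k=k):
            amps = peak * _stick_fractions(p[: k - 1])
            lam = p[k - 1 :]
            pred = np.zeros_like(yp)
            for a, l in zip(amps, lam):
                pred += a * np.exp(-l * (tp - t_peak))
            return pred - yp

        res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        rss = float(np.sum(res.fun**2))
        n = yp.size
        rss_floor = n * (1e-8 * peak) ** 2  # guard the log for near-perfect fits
        aic = n * np.log(max(rss, rss_floor) / n) + 2 * (2 * k - 1)
        if best is None or aic < best[0]:
            best = (aic, k, res, rss)

    _, k, res, rss = best
    amps = tuple(peak * _stick_fractions(res.x[: k - 1]))
    lam = tuple(res.x[k - 1 :])
    model = WholeBloodModel(t_on, t_peak, peak, amps, lam)
    rmse = float(np.sqrt(rss / yp.size))
    return WholeBloodFit(model, k, rmse, bool(res.success), res.message)


def calibrate_continuous_to_discrete(
    continuous_times,
    continuous_values,
    discrete_times,
    discrete_values,
    calibration_times: Sequence[float] = CALIBRATION_TIMES,
    tol: float = 1e-6,
) -> float:
    """Cross-calibration factor between sampling modalities.

    Least-squares-through-origin ratio of discrete to continuous activity at
    the shared calibration times; multiply the continuous series by the
    returned factor.
    """
    ct = np.asarray(continuous_times, dtype=float)
    cv = np.asarray(continuous_values, dtype=float)
    dt_ = np.asarray(discrete_times, dtype=float)
    dv = np.asarray(discrete_values, dtype=float)
    c, d = [], []
    for tc in calibration_times:
        i = np.argmin(np.abs(dt_ - tc))
        if abs(dt_[i] - tc) > tol:
            continue
        if tc < ct[0] or tc > ct[-1]:
            continue
        c.append(np.interp(tc, ct, cv))
        d.append(dv[i])
    if len(c) < 2:
        raise ValueError("need at least 2 overlapping calibration samples")
    c = np.asarray(c)
    d = np.asarray(d)
    return float(np.dot(c, d) / np.dot(c, c))


@dataclass
class DelayFit:
    delay: float
    grid: np.ndarray
    rss: np.ndarray
    boundary: bool
    degenerate: bool = False


def fit_delay(
    input_function: InputFunction,
    whole_brain_tac: TAC,
    search: tuple = (-1.0, 1.0),
    step: float = 0.01,
    t_max: float = 5.0,
    dt: float = DEFAULT_DT,
) -> DelayFit:
    """Fit the blood-to-brain time delay by a 1-D grid search.

    Each candidate delay shifts the input function; a one-tissue-compartment
    model (K1, k2, V_B) is fitted by WNLLS to the whole-brain TAC restricted
    to the first ``t_max`` minutes, and the delay with the lowest weighted
    residual is returned. Solutions on the search boundary are flagged.
    """
    sched = whole_brain_tac.schedule
    keep = sched.frame_end <= t_max + 1e-9
    if keep.sum() < 4:
        raise ValueError("need early frames (<= t_max) to fit a delay")
    from .frames import FrameSchedule  # local import to avoid cycle at module load

    sub = FrameSchedule(sched.frame_start[keep], sched.frame_duration[keep])
    tac = np.asarray(whole_brain_tac.activity, dtype=float)[keep]
    if np.allclose(tac, tac[0]):
        return DelayFit(0.0, np.array([0.0]), np.array([np.nan]), boundary=False, degenerate=True)

    tgrid = fine_grid(sub.total_duration, dt)
    w = sub.frame_duration / np.maximum(tac, max(1e-3 * tac.max(), 1e-12))
    w = w / w.sum()
    sw = np.sqrt(w)

    delays = np.arange(search[0], search[1] + 0.5 * step, step)
    rss = np.empty(delays.size)
    x0 = np.array([0.1, 0.1, 0.05])
    best_x = {}
    for i, d in enumerate(delays):
        shifted = input_function.shifted(d)
        cp = shifted.plasma(tgrid)
        cb = shifted.wholeblood(tgrid)

        def resid(p):
            k1, k2, vb = p
            tissue = k1 * exp_conv(cp, dt, k2)
            model = frame_average((1 - vb) * tissue + vb * cb, dt, sub)
            return sw * (model - tac)

        res = least_squares(
            resid, x0, bounds=([0.0, 1e-6, 0.0], [5.0, 5.0, 0.2]), xtol=1e-12, ftol=1e-12
        )
        rss[i] = 2 * res.cost
        x0 = res.x  # warm start the next grid point
        best_x[i] = res.x
    imin = int(np.argmin(rss))
    return DelayFit(
        delay=float(delays[imin]),
        grid=delays,
        rss=rss,
        boundary=imin in (0, delays.size - 1),
    )


def build_input_function(
    wholeblood_fit: WholeBloodFit | WholeBloodModel,
    pob_fit: HillFit | HillRatio,
    ppf_fit: HillFit | HillFraction,
    delay: float = 0.0,
) -> InputFunction:
    """Compose C_p(t) = C_b(t-delay) * POB(t-delay) * PPf(t-delay)."""
    wb = wholeblood_fit.model if isinstance(wholeblood_fit, WholeBloodFit) else wholeblood_fit
    pob = pob_fit.model if isinstance(pob_fit, HillFit) else pob_fit
    ppf = ppf_fit.model if isinstance(ppf_fit, HillFit) else ppf_fit
    return InputFunction(wb, pob, ppf, delay=delay)


def input_function_to_dict(inp: InputFunction) -> dict:
    """JSON-ready parameter record of a fitted input function."""
    import dataclasses

    return {
        "wholeblood": dataclasses.asdict(inp.wholeblood_model),
        "pob": dataclasses.asdict(inp.pob_model),
        "ppf": dataclasses.asdict(inp.ppf_model),
        "delay": inp.delay,
    }


def input_function_from_dict(d: dict) -> InputFunction:
    wb = d["wholeblood"]
    return InputFunction(
        WholeBloodModel(
            wb["t_on"], wb["t_peak"], wb["peak"], tuple(wb["amps"]), tuple(wb["lambdas"])
        ),
        HillRatio(**d["pob"]),
        HillFraction(**d["ppf"]),
        delay=d.get("delay", 0.0),
    )


def derive_input_function(
    blood: BloodSeries,
    continuous_times=None,
    continuous_values=None,
    whole_brain_tac: TAC | None = None,
) -> InputFunction:
    """Full blood-processing chain on one scan's samples.

    Calibrates the continuous line against discrete samples (when present),
    fits the whole-blood, POB and parent-fraction models, optionally fits the
    delay against the whole-brain TAC, and composes the input function.
    """
    if continuous_times is not None:
        factor = calibrate_continuous_to_discrete(
            continuous_times, continuous_values, blood.times, blood.wholeblood
        )
        ct = np.asarray(continuous_times, dtype=float)
        cv = factor * np.asarray(continuous_values, dtype=float)
        late = blood.times > ct[-1]
        wb_t = np.concatenate([ct, blood.times[late]])
        wb_v = np.concatenate([cv, blood.wholeblood[late]])
    else:
        wb_t, wb_v = blood.times, blood.wholeblood

    wb_fit = fit_wholeblood(wb_t, wb_v)
    pob_fit = fit_pob(blood.times, blood.pob)
    m = np.isfinite(blood.ppf)
    ppf_fit = fit_parent_fraction(blood.times[m], blood.ppf[m])
    inp = build_input_function(wb_fit, pob_fit, ppf_fit, delay=0.0)
    if whole_brain_tac is not None:
        dfit = fit_delay(inp, whole_brain_tac)
        inp = replace(inp, delay=dfit.delay)
    return inp
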