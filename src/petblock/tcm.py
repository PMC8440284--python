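"""Two-tissue compartment modelling of regional TACs by weighted NLLS.

The standard 2TCM describes tracer exchange between arterial plasma and two
tissue compartments (free/non-specific C1, specifically bound C2):

    dC1/dt = K1*C_p - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_model(t) = (1 - V_B) * (C1 + C2) + V_B * C_b(t)

with the total distribution volume V_T = (K1/k2) * (1 + k3/k4).

The 2TCM1K variant adds an irreversible vascular (endothelial) binding
compartment fed from whole blood at rate Kb, dCvasc/dt = Kb*C_b, whose
content is added to the measured signal; Kb does not enter V_T.

The tissue solution is the convolution of a bi-exponential impulse response
with the plasma input, evaluated on a fine uniform grid and averaged over
each frame interval (short early frames make midpoint evaluation biased).
Fits minimise sum_i w_i (TAC_i - model_i)^2 with w_i proportional to
frame_duration_i / TAC_i, matching count-statistics noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._conv import DEFAULT_DT, cumulative_trapezoid_grid, exp_conv, fine_grid, frame_average
from .blood import InputFunction
from .frames import TAC, FrameSchedule

#: exclusion thresholds for non-physiological fits
VT_EXCLUSION_LIMIT = 10.0  # mL/cm3
CV_EXCLUSION_LIMIT = 50.0  # percent

_PARAM_NAMES_2TCM = ("K1", "k2", "k3", "k4", "vB")
_PARAM_NAMES_2TCM1K = ("K1", "k2", "k3", "k4", "vB", "kb")


@dataclass
class TCMParams:
    """Micro-parameters: K1 (mL cm^-3 min^-1), k2..k4, Kb (min^-1), V_B (fraction)."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.05
    kb: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.K1, self.k2, self.k3, self.k4, self.vB, self.kb)
        if any(not np.isfinite(v) for v in vals):
            raise ValueError("compartment parameters must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("compartment parameters must be non-negative")
        if self.vB > 0.2:
            raise ValueError("V_B must lie in [0, 0.2]")


@dataclass
class PreparedInput:
    """Input function sampled on the fine grid for one frame schedule."""

    schedule: FrameSchedule
    dt: float
    tgrid: np.ndarray
    cp: np.ndarray
    cb: np.ndarray
    cb_int: np.ndarray  # running integral of whole blood, for the vascular trap

    @classmethod
    def from_input(
        cls, input_function: InputFunction, schedule: FrameSchedule, dt: float = DEFAULT_DT
    ) -> "PreparedInput":
        tgrid = fine_grid(schedule.total_duration, dt)
        cp = input_function.plasma(tgrid)
        cb = input_function.wholeblood(tgrid)
        return cls(schedule, dt, tgrid, cp, cb, cumulative_trapezoid_grid(cb, dt))


def _prepare(input_function, schedule, dt) -> PreparedInput:
    if isinstance(input_function, PreparedInput):
        return input_function
    return PreparedInput.from_input(input_function, schedule, dt)


def _impulse_coefficients(K1, k2, k3, k4):
    """Amplitudes and rates of the bi-exponential 2TCM impulse response."""
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    th1 = 0.5 * (s + sq)
    th2 = 0.5 * (s - sq)
    if th1 - th2 < 1e-12:  # coincident roots; nudge to keep the formula defined
        th1 += 5e-13
        th2 = max(th2 - 5e-13, 0.0)
    phi1 = K1 * (th1 - k3 - k4) / (th1 - th2)
    phi2 = K1 * (k3 + k4 - th2) / (th1 - th2)
    return (phi1, th1), (phi2, th2)


def _tissue_fine(params: TCMParams, prep: PreparedInput) -> np.ndarray:
    (phi1, th1), (phi2, th2) = _impulse_coefficients(params.K1, params.k2, params.k3, params.k4)
    tissue = np.zeros_like(prep.cp)
    if phi1 != 0.0:
        tissue += phi1 * exp_conv(prep.cp, prep.dt, th1)
    if phi2 != 0.0:
        tissue += phi2 * exp_conv(prep.cp, prep.dt, th2)
    return tissue


def model_2tcm(
    params: TCMParams,
    input_function,
    schedule: FrameSchedule,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Frame-averaged 2TCM tissue curve for the given parameters."""
    prep = _prepare(input_function, schedule, dt)
    fine = (1.0 - params.vB) * _tissue_fine(params, prep) + params.vB * prep.cb
    return frame_average(fine, prep.dt, prep.schedule)


def model_2tcm1k(
    params: TCMParams,
    input_function,
    schedule: FrameSchedule,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """2TCM plus the irreversible vascular trap Kb * int_0^t C_b ds."""
    prep = _prepare(input_function, schedule, dt)
    fine = (
        (1.0 - params.vB) * _tissue_fine(params, prep)
        + params.vB * prep.cb
        + params.kb * prep.cb_int
    )
    return frame_average(fine, prep.dt, prep.schedule)


def compute_vt(params: TCMParams) -> float:
    """Total distribution volume (K1/k2)(1 + k3/k4); Kb never contributes."""
    if params.k2 <= 0 or params.k4 <= 0:
        raise ValueError("V_T undefined for k2 <= 0 or k4 <= 0")
    return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)


def wnlls_weights(tac_values: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Frame weights duration_i / max(TAC_i, eps), normalised to sum to 1."""
    tac_values = np.asarray(tac_values, dtype=float)
    eps = max(1e-3 * np.max(np.abs(tac_values)), 1e-12)
    w = np.asarray(durations, dtype=float) / np.maximum(tac_values, eps)
    return w / w.sum()


def _vt_gradient(p: TCMParams) -> np.ndarray:
    """d V_T / d (K1, k2, k3, k4) for the delta method."""
    vnd = p.K1 / p.k2
    return np.array(
        [
            (1.0 + p.k3 / p.k4) / p.k2,
            -(vnd / p.k2) * (1.0 + p.k3 / p.k4),
            vnd / p.k4,
            -vnd * p.k3 / p.k4**2,
        ]
    )


@dataclass
class TCMFit:
    """One region/condition fit: parameters, V_T, precision and exclusion."""

    params: TCMParams
    model: str
    vt: float
    cv: dict
    cv_vt: float
    wrss: float
    converged: bool
    excluded: bool = False
    exclusion_reason: str = ""
    message: str = ""
    extra: dict = field(default_factory=dict)


def apply_exclusion_rules(vt: float, cv_vt: float) -> tuple[bool, str]:
    """Non-physiological fits: V_T above 10 mL/cm3 or CV(V_T) above 50%."""
    if not np.isfinite(vt) or vt > VT_EXCLUSION_LIMIT:
        return True, f"V_T>{VT_EXCLUSION_LIMIT:g}"
    if not np.isfinite(cv_vt) or cv_vt > CV_EXCLUSION_LIMIT:
        return True, f"CV>{CV_EXCLUSION_LIMIT:g}%"
    return False, ""


_DEFAULT_INIT = {"K1": 0.1, "k2": 0.1, "k3": 0.05, "k4": 0.05, "vB": 0.05, "kb": 0.01}
_BOUNDS = {
    "K1": (1e-6, 5.0),
    "k2": (1e-6, 5.0),
    "k3": (0.0, 2.0),
    "k4": (1e-6, 2.0),
    "vB": (0.0, 0.2),
    "kb": (0.0, 1.0),
}
_MULTISTART_SCALES = (1.0, 0.5, 2.0)


def fit_wnlls(
    tac: TAC,
    input_function,
    model: str = "2tcm",
    init: dict | None = None,
    weights: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
) -> TCMFit:
    """Weighted nonlinear least-squares fit of a compartment model to one TAC.

    Three multi-starts (the initial guess and x0.5/x2 rescalings of it) are
    run and the lowest weighted-RSS solution kept. Parameter CVs come from
    the Jacobian-based asymptotic covariance; CV(V_T) by the delta method.
    A singular covariance yields infinite CVs (forcing exclusion) rather
    than an error.
    """
    if model not in ("2tcm", "2tcm1k"):
        raise ValueError("model must be '2tcm' or '2tcm1k'")
    names = _PARAM_NAMES_2TCM1K if model == "2tcm1k" else _PARAM_NAMES_2TCM
    prep = _prepare(input_function, tac.schedule, dt)
    y = np.asarray(tac.activity, dtype=float)
    w = wnlls_weights(y, tac.schedule.frame_duration) if weights is None else np.asarray(weights)
    sw = np.sqrt(w)
    model_fn = model_2tcm1k if model == "2tcm1k" else model_2tcm

    init_map = dict(_DEFAULT_INIT)
    if init:
        init_map.update(init)
    x_base = np.array([init_map[n] for n in names])
    lb = np.array([_BOUNDS[n][0] for n in names])
    ub = np.array([_BOUNDS[n][1] for n in names])

    def resid(x):
        p = TCMParams(**dict(zip(names, x)))
        return sw * (model_fn(p, prep, tac.schedule, dt) - y)

    best = None
    for scale in _MULTISTART_SCALES:
        x0 = np.clip(x_base * scale, lb + 1e-12, ub - 1e-12)
        res = least_squares(resid, x0, bounds=(lb, ub), x_scale=np.maximum(x0, 1e-3))
        if best is None or res.cost < best.cost:
            best = res
    res = best

    x = res.x
    params = TCMParams(**dict(zip(names, x)))
    try:
        vt = compute_vt(params)
    except ValueError:
        vt = np.inf
    wrss = float(2 * res.cost)

    n, p = y.size, x.size
    cv = {nm: np.inf for nm in names}
    cv_vt = np.inf
    if n > p:
        s2 = wrss / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            var = np.clip(np.diag(cov), 0.0, None)
            for i, nm in enumerate(names):
                cv[nm] = 100.0 * np.sqrt(var[i]) / abs(x[i]) if x[i] != 0 else np.inf
            g = np.zeros(p)
            g[:4] = _vt_gradient(params)
            vvt = float(g @ cov @ g)
            cv_vt = 100.0 * np.sqrt(max(vvt, 0.0)) / vt if np.isfinite(vt) and vt > 0 else np.inf
        except np.linalg.LinAlgError:
            pass  # CVs stay infinite

    excluded, reason = apply_exclusion_rules(vt, cv_vt)
    return TCMFit(
        params=params,
        model=model,
        vt=float(vt),
        cv=cv,
        cv_vt=float(cv_vt),
        wrss=wrss,
        converged=bool(res.success),
        excluded=excluded,
        exclusion_reason=reason,
        message=res.message,
    )


def compute_suv(
    tac: TAC, injected_dose_mbq: float, weight_kg: float, summary: str = "mean"
) -> float:
    """Standardised uptake value: activity / (injected dose / body weight).

    Activity in kBq/mL against dose in kBq over weight in g, so SUV is
    unitless (assuming ~1 g/mL tissue). ``summary`` is the frame-duration
    weighted mean over the scan (default) or the final-frame value.
    """
    if injected_dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("injected dose and weight must be positive")
    suv_curve = np.asarray(tac.activity, dtype=float) / (
        injected_dose_mbq * 1000.0 / (weight_kg * 1000.0)
    )
    if summary == "mean":
        d = tac.schedule.frame_duration
        return float(np.sum(d * suv_curve) / np.sum(d))
    if summary == "final":
        return float(suv_curve[-1])
    raise ValueError("summary must be 'mean' or 'final'")
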