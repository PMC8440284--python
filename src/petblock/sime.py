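"""SIME: simultaneous estimation of a brain-wide V_ND from baseline data.

Blocking-free alternative to the occupancy plot: for each candidate V_ND on
a grid, the 2TCM is re-fitted to every regional baseline TAC with the
constraint K1/k2 = V_ND (k2 eliminated, free parameters K1, k3, k4, V_B);
the candidate minimising the pooled weighted residual sum of squares over
all regions and frames is the estimate. Only baseline scans enter; the
default grid spans 0.01 to 5 mL/cm3 in 0.01 steps, ties resolve to the
smaller value, and each grid point is warm-started from its neighbour's
solution (the grid sweep dominates the cost). Weights are the same
duration/TAC weights as the unconstrained kinetic modelling, normalised
within each region; regions pool with no cross-region reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from ._conv import DEFAULT_DT
from .frames import TAC
from .tcm import PreparedInput, TCMFit, TCMParams, _prepare, apply_exclusion_rules
from .tcm import compute_vt, model_2tcm, wnlls_weights

DEFAULT_GRID = np.round(np.arange(1, 501) * 0.01, 2)  # 0.01 .. 5.00 mL/cm3

_CON_BOUNDS = (
    np.array([0.0, 0.0, 1e-6, 0.0]),  # K1, k3, k4, vB
    np.array([5.0, 2.0, 2.0, 0.2]),
)
_CON_INIT = np.array([0.1, 0.05, 0.05, 0.05])


def _check_baseline(tac: TAC) -> None:
    if tac.condition and tac.condition != "baseline":
        raise ValueError(
            f"SIME uses baseline scans only; got a '{tac.condition}' TAC for '{tac.region}'"
        )


def fit_constrained_2tcm(
    tac: TAC,
    input_function,
    vnd_value: float,
    init: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
) -> TCMFit:
    """2TCM fit with K1/k2 pinned to ``vnd_value`` (k2 = K1 / V_ND)."""
    if vnd_value <= 0:
        raise ValueError("V_ND constraint must be positive")
    _check_baseline(tac)
    prep = _prepare(input_function, tac.schedule, dt)
    y = np.asarray(tac.activity, dtype=float)
    w = wnlls_weights(y, tac.schedule.frame_duration) if weights is None else np.asarray(weights)
    sw = np.sqrt(w)

    def resid(x):
        k1, k3, k4, vb = x
        p = TCMParams(K1=k1, k2=k1 / vnd_value, k3=k3, k4=k4, vB=vb)
        return sw * (model_2tcm(p, prep, tac.schedule, dt) - y)

    x0 = np.clip(_CON_INIT if init is None else np.asarray(init, dtype=float),
                 _CON_BOUNDS[0] + 1e-12, _CON_BOUNDS[1] - 1e-12)
    res = least_squares(resid, x0, bounds=_CON_BOUNDS, x_scale=np.maximum(x0, 1e-3))
    k1, k3, k4, vb = res.x
    params = TCMParams(K1=k1, k2=k1 / vnd_value, k3=k3, k4=k4, vB=vb)
    try:
        vt = compute_vt(params)
    except ValueError:
        vt = np.inf
    wrss = float(2 * res.cost)
    excluded, reason = apply_exclusion_rules(vt, 0.0)
    return TCMFit(
        params=params,
        model="2tcm-constrained",
        vt=float(vt),
        cv={},
        cv_vt=np.nan,
        wrss=wrss,
        converged=bool(res.success),
        excluded=excluded,
        exclusion_reason=reason,
        message=res.message,
        extra={"x": res.x, "vnd_constraint": float(vnd_value)},
    )


@dataclass
class SIMEResult:
    """RSS-vs-V_ND profile and its arg-min for one baseline scan."""

    grid: np.ndarray
    rss: np.ndarray
    vnd: float
    fits_at_optimum: dict
    degenerate: bool = False
    flags: list = field(default_factory=list)


def sime_vnd(
    baseline_tacs: dict[str, TAC],
    input_function,
    grid: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
) -> SIMEResult:
    """Grid-search the shared V_ND minimising the pooled weighted RSS.

    ``baseline_tacs`` maps region -> baseline TAC (blocking-labelled TACs
    are rejected). Returns the full profile for plotting; ties break to the
    smaller grid value.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("V_ND grid values must be positive")
    if len(baseline_tacs) < 3:
        raise ValueError("need at least 3 regions")
    for tac in baseline_tacs.values():
        _check_baseline(tac)
    first = next(iter(baseline_tacs.values()))
    prep = _prepare(input_function, first.schedule, dt)
    weights = {
        r: wnlls_weights(t.activity, t.schedule.frame_duration) for r, t in baseline_tacs.items()
    }

    rss = np.empty(grid.size)
    warm = {r: None for r in baseline_tacs}
    fits_by_grid: list[dict] = []
    for gi, v in enumerate(grid):
        total = 0.0
        fits = {}
        for region, tac in baseline_tacs.items():
            fit = fit_constrained_2tcm(
                tac, prep, v, init=warm[region], weights=weights[region], dt=dt
            )
            warm[region] = fit.extra["x"]
            total += fit.wrss
            fits[region] = fit
        rss[gi] = total
        fits_by_grid.append(fits)

    imin = int(np.argmin(rss))  # first minimum == smaller V_ND on ties
    flags = []
    # degenerate when the profile is flat or the data carry no weighted signal
    data_ss = sum(
        float(np.sum(weights[r] * np.asarray(t.activity, dtype=float) ** 2))
        for r, t in baseline_tacs.items()
    )
    flat = rss.max() - rss.min() <= 1e-5 * max(rss.max(), 1e-300)
    degenerate = bool(flat or data_ss <= 1e-12)
    if degenerate:
        flags.append("flat RSS profile: degenerate data")
    return SIMEResult(
        grid=grid,
        rss=rss,
        vnd=float(grid[imin]),
        fits_at_optimum=fits_by_grid[imin],
        degenerate=degenerate,
        flags=flags,
    )


def compare_sime_lassen(sime_vnds, lassen_vnds, subject_ids=None):
    """Paired per-subject comparison of SIME and occupancy-plot V_ND.

    Returns a dict with the per-subject relative differences
    100*(SIME - Lassen)/Lassen, their mean with population (divisor n) and
    sample SDs, column summaries, and a paired two-tailed t-test on the raw
    estimates.
    """
    s = np.asarray(sime_vnds, dtype=float)
    l = np.asarray(lassen_vnds, dtype=float)
    if s.shape != l.shape or s.ndim != 1 or s.size < 2:
        raise ValueError("need matched 1-D arrays of at least 2 subjects")
    rel = 100.0 * (s - l) / l
    d = s - l
    n = s.size
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        t_stat = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t_stat = float(d.mean() / (sd_d / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return {
        "subject_ids": list(subject_ids) if subject_ids is not None else list(range(n)),
        "rel_dif_pct": rel,
        "rel_dif_mean_pct": float(rel.mean()),
        "rel_dif_sd_pct": float(rel.std(ddof=0)),  # population SD
        "rel_dif_sample_sd_pct": float(rel.std(ddof=1)),
        "sime_mean": float(s.mean()),
        "sime_sd": float(s.std(ddof=0)),
        "sime_sample_sd": float(s.std(ddof=1)),
        "lassen_mean": float(l.mean()),
        "lassen_sd": float(l.std(ddof=0)),
        "t": t_stat,
        "df": n - 1,
        "p": p,
    }
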