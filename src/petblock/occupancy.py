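"""Occupancy (Lassen) plot estimation of drug occupancy and V_ND.

Under pharmacological blockade with V_ND unchanged and a single fractional
occupancy across regions,

    V_T,baseline - V_T,blocking = occupancy * (V_T,baseline - V_ND),

so regressing the V_T decrease on baseline V_T across regions gives the
occupancy as the slope and V_ND as the x-intercept. Individual-subject fits
use ordinary least squares (noise on the abscissa ignored, matching common
practice in occupancy studies; orthogonal regression is available behind a
flag). The population-constrained variant fits all subjects jointly with
one shared V_ND and subject-specific occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq, minimize_scalar


@dataclass
class VTPair:
    """One region's baseline/blocking V_T pair entering the plot."""

    region: str
    vt_baseline: float
    vt_blocking: float
    included: bool = True


def pairs_from_fits(baseline_fits: dict, blocking_fits: dict) -> list[VTPair]:
    """Build plot points from per-region TCMFit maps; both fits must be
    non-excluded for a region to be included."""
    pairs = []
    for region in baseline_fits:
        if region not in blocking_fits:
            continue
        b, k = baseline_fits[region], blocking_fits[region]
        pairs.append(VTPair(region, b.vt, k.vt, included=not (b.excluded or k.excluded)))
    return pairs


@dataclass
class OccupancyFit:
    """Occupancy (slope) and V_ND (x-intercept), with 95% CIs."""

    occupancy: float
    vnd: float
    occupancy_ci: tuple
    vnd_ci: tuple
    n_points: int
    residuals: np.ndarray
    sse: float
    flags: list = field(default_factory=list)
    subject_occupancies: dict = field(default_factory=dict)


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    use = [p for p in pairs if p.included]
    x = np.array([p.vt_baseline for p in use], dtype=float)
    y = x - np.array([p.vt_blocking for p in use], dtype=float)
    return x, y


def _ols_line(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _orthogonal_line(x, y):
    """Total least squares (Deming with equal error variances)."""
    xm, ym = x.mean(), y.mean()
    u = np.column_stack([x - xm, y - ym])
    _, _, vt = np.linalg.svd(u, full_matrices=False)
    a, b = vt[0]
    if a == 0:
        raise ValueError("orthogonal fit degenerate (vertical line)")
    slope = b / a
    return float(slope), float(ym - slope * xm)


def lassen_individual(
    pairs,
    n_boot: int = 2000,
    seed: int = 0,
    orthogonal: bool = False,
) -> OccupancyFit:
    """Occupancy plot for one subject's region pairs.

    OLS of (V_T,base - V_T,block) on V_T,base; occupancy = slope,
    V_ND = -intercept/slope. 95% CIs by nonparametric bootstrap over
    regions (percentile, ``n_boot`` resamples, fixed seed). Occupancies
    outside [0, 1] and non-positive slopes are flagged, never clipped.
    """
    x, y = _as_xy(pairs)
    if x.size < 3:
        raise ValueError("need at least 3 included region pairs")
    line = _orthogonal_line if orthogonal else _ols_line
    slope, intercept = line(x, y)
    flags = []
    if slope <= 0:
        vnd = np.nan
        flags.append("non-positive slope: V_ND undefined")
    else:
        vnd = -intercept / slope
    if slope > 1 or slope < 0:
        flags.append("occupancy outside [0, 1]")

    rng = np.random.default_rng(seed)
    occ_bs, vnd_bs = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.unique(x[idx]).size < 2:
            continue
        s, b = line(x[idx], y[idx])
        occ_bs.append(s)
        if s > 0:
            vnd_bs.append(-b / s)
    occ_ci = tuple(np.percentile(occ_bs, [2.5, 97.5])) if occ_bs else (np.nan, np.nan)
    vnd_ci = tuple(np.percentile(vnd_bs, [2.5, 97.5])) if vnd_bs else (np.nan, np.nan)

    resid = y - (slope * x + intercept)
    return OccupancyFit(
        occupancy=slope,
        vnd=float(vnd),
        occupancy_ci=occ_ci,
        vnd_ci=vnd_ci,
        n_points=int(x.size),
        residuals=resid,
        sse=float(np.sum(resid**2)),
        flags=flags,
    )


def _pooled_rss(vnd, xs, ys):
    """Profile RSS over the shared V_ND: subject occupancies are closed-form."""
    rss = 0.0
    for x, y in zip(xs, ys):
        z = x - vnd
        denom = np.dot(z, z)
        occ = np.dot(y, z) / denom if denom > 0 else 0.0
        r = y - occ * z
        rss += np.dot(r, r)
    return rss


def _profile_occupancies(vnd, xs, ys):
    occs = []
    for x, y in zip(xs, ys):
        z = x - vnd
        denom = np.dot(z, z)
        occs.append(float(np.dot(y, z) / denom) if denom > 0 else np.nan)
    return occs


def lassen_population(subject_pairs: dict, conf: float = 0.95) -> OccupancyFit:
    """Joint occupancy-plot fit with one V_ND shared by all subjects.

    ``subject_pairs`` maps subject id -> list of VTPair. The model
    dVT_ij = Occ_i * (VT_base,ij - V_ND) is solved by nonlinear least
    squares; for fixed V_ND each occupancy is closed-form, so the fit is a
    1-D profile minimisation. The V_ND CI comes from the profile
    likelihood (F threshold on the pooled RSS); the summary occupancy is
    mean +/- SD of the subject occupancies.
    """
    if len(subject_pairs) < 1:
        raise ValueError("need at least one subject")
    xs, ys, ids = [], [], []
    for sid, pairs in subject_pairs.items():
        x, y = _as_xy(pairs)
        if x.size < 3:
            raise ValueError(f"subject {sid}: need at least 3 included pairs")
        xs.append(x)
        ys.append(y)
        ids.append(sid)

    xmin = min(x.min() for x in xs)
    lo, hi = -10.0, xmin - 1e-9
    res = minimize_scalar(_pooled_rss, bounds=(lo, hi), args=(xs, ys), method="bounded",
                          options={"xatol": 1e-10})
    vnd_hat = float(res.x)
    rss_min = float(res.fun)

    flags = []
    # degenerate / non-identifiable profile
    probe = np.linspace(lo, hi, 50)
    prof = np.array([_pooled_rss(v, xs, ys) for v in probe])
    if prof.max() - prof.min() <= 1e-12 * (1.0 + rss_min):
        flags.append("flat pooled RSS profile: V_ND not identifiable")

    n_total = sum(x.size for x in xs)
    n_par = len(xs) + 1
    dof = n_total - n_par
    occs = _profile_occupancies(vnd_hat, xs, ys)

    vnd_ci = (np.nan, np.nan)
    if dof > 0 and not flags:
        thresh = rss_min * (1.0 + stats.f.ppf(conf, 1, dof) / dof)
        g = lambda v: _pooled_rss(v, xs, ys) - thresh
        lo_ci = lo if g(lo) <= 0 else brentq(g, lo, vnd_hat)
        hi_ci = hi if g(hi) <= 0 else brentq(g, vnd_hat, hi)
        if lo_ci == lo or hi_ci == hi:
            flags.append("profile CI truncated at the search boundary")
        vnd_ci = (float(lo_ci), float(hi_ci))

    occ_arr = np.array(occs)
    occ_mean = float(occ_arr.mean())
    occ_sd = float(occ_arr.std(ddof=1)) if occ_arr.size > 1 else 0.0
    resid = np.concatenate([y - o * (x - vnd_hat) for x, y, o in zip(xs, ys, occs)])
    if np.any((occ_arr < 0) | (occ_arr > 1)):
        flags.append("some subject occupancies outside [0, 1]")
    return OccupancyFit(
        occupancy=occ_mean,
        vnd=vnd_hat,
        occupancy_ci=(occ_mean - 1.96 * occ_sd, occ_mean + 1.96 * occ_sd),
        vnd_ci=vnd_ci,
        n_points=int(n_total),
        residuals=resid,
        sse=rss_min,
        flags=flags,
        subject_occupancies=dict(zip(ids, occs)),
    )


def specific_fraction(vt: float, vnd: float):
    """Fraction of V_T that is specific binding: (V_T - V_ND) / V_T.

    Negative values (V_T below V_ND) are returned as computed, with a flag.
    """
    if vt == 0:
        raise ValueError("V_T must be non-zero")
    frac = (vt - vnd) / vt
    return frac, (frac < 0)
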