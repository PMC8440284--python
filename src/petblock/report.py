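"""Study-level tables, summary statistics and the end-to-end pipeline.

Reproduces the blocking study's summary outputs from fit results: the
regional percent-V_T-change table (percent change computed from the two
group means, not the mean of per-subject changes, and displayed half-up
rounded to integer percent) and the per-subject V_ND comparison table with
its paired t-test.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import study_reference
from .occupancy import OccupancyFit, lassen_individual, lassen_population, pairs_from_fits
from .sime import compare_sime_lassen, sime_vnd
from .synth import CohortConfig, generate_cohort
from .tcm import compute_suv, fit_wnlls

log = logging.getLogger("petblock")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def percent_vt_change(mean_baseline: float, mean_block: float) -> float:
    """Relative difference of group-mean V_T: 100*(base - block)/base."""
    if mean_baseline == 0:
        raise ValueError("baseline mean must be non-zero")
    return 100.0 * (mean_baseline - mean_block) / mean_baseline


def paired_ttest(values_a, values_b):
    """Closed-form paired two-tailed t-test; df = n - 1.

    Returns ``(t, df, p)``. Identical vectors give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need matched 1-D samples of size >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, n - 1, p


def regional_change_table(vt_frame: pd.DataFrame) -> pd.DataFrame:
    """Regional mean +/- SD V_T per condition/model with percent change.

    ``vt_frame`` needs columns region, model, condition, subject, vt.
    The percent change is computed from the two means.
    """
    rows = []
    for (region, model), grp in vt_frame.groupby(["region", "model"], sort=False):
        base = grp.loc[grp["condition"] == "baseline", "vt"]
        block = grp.loc[grp["condition"] == "blocking", "vt"]
        if base.empty or block.empty:
            continue
        pct = percent_vt_change(base.mean(), block.mean())
        rows.append(
            {
                "region": region,
                "model": model,
                "vt_baseline_mean": base.mean(),
                "vt_baseline_sd": base.std(ddof=1) if base.size > 1 else 0.0,
                "vt_block_mean": block.mean(),
                "vt_block_sd": block.std(ddof=1) if block.size > 1 else 0.0,
                "pct_change": pct,
                "pct_change_display": round_half_up(pct),
            }
        )
    return pd.DataFrame(rows)


def reference_change_table() -> pd.DataFrame:
    """Percent V_T change recomputed from the published group means."""
    tab = study_reference.regional_vt_table()
    rows = []
    for _, r in tab.iterrows():
        for model in ("2tcm", "2tcm1k"):
            pct = percent_vt_change(r[f"vt_baseline_{model}"], r[f"vt_block_{model}"])
            rows.append(
                {
                    "region": r["region"],
                    "model": model,
                    "pct_change": pct,
                    "pct_change_display": round_half_up(pct),
                    "pct_change_printed": int(r[f"pct_change_{model}"]),
                }
            )
    return pd.DataFrame(rows)


def reference_sime_comparison() -> dict:
    """SIME-vs-Lassen statistics recomputed from the published per-subject
    V_ND columns."""
    tab = study_reference.subject_vnd_table()
    comp = compare_sime_lassen(
        tab["sime_vnd"].to_numpy(), tab["lassen_vnd_2tcm"].to_numpy(), tab["subject"]
    )
    comp["rel_dif_printed_pct"] = tab["rel_dif_pct"].to_numpy()
    return comp


# ---------------------------------------------------------------------------
# end-to-end pipeline on synthetic data


@dataclass
class StudyResult:
    """Everything the pipeline computes for one synthetic cohort."""

    config: CohortConfig
    vt_table: pd.DataFrame  # per subject/region/model/condition fits
    change_table: pd.DataFrame
    individual: dict  # subject -> {model: OccupancyFit}
    pooled: dict  # model -> OccupancyFit
    sime: dict  # subject -> SIMEResult (may cover a subset)
    comparison: dict | None
    suv_table: pd.DataFrame


def run_pipeline(
    config: CohortConfig,
    models: tuple = ("2tcm", "2tcm1k"),
    use_true_input: bool = False,
    sime_subjects: int | None = None,
    sime_grid=None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """simulate -> blood -> kinetic fits -> occupancy plots -> SIME -> tables.

    Deterministic given ``config.seed``. ``use_true_input`` skips the blood
    refitting stage and drives the kinetic fits with the generator's true
    input functions. ``sime_subjects`` limits the (expensive) SIME grid
    sweep to the first k subjects; None runs all.
    """
    from .blood import derive_input_function

    log.info("simulating cohort: %d subjects, seed %d", config.n_subjects, config.seed)
    subjects, manifest = generate_cohort(config, outdir=outdir, overwrite=True)

    fit_rows = []
    suv_rows = []
    fits_by = {}  # (subject, model, condition) -> {region: TCMFit}
    inputs = {}  # (subject, condition) -> input function used
    for subj in subjects:
        for cond, scan in subj.scans.items():
            if use_true_input:
                inp = scan.input_function
            else:
                wb_region = "whole_brain" if "whole_brain" in scan.tacs else None
                inp = derive_input_function(
                    scan.blood,
                    scan.continuous_times,
                    scan.continuous_wholeblood,
                    whole_brain_tac=scan.tacs[wb_region] if wb_region else None,
                )
            inputs[(subj.subject_id, cond)] = inp
            for model in models:
                fits = {}
                for region, tac in scan.tacs.items():
                    fit = fit_wnlls(tac, inp, model=model)
                    fits[region] = fit
                    fit_rows.append(
                        {
                            "subject": subj.subject_id,
                            "condition": cond,
                            "model": model,
                            "region": region,
                            "vt": fit.vt,
                            "cv_vt": fit.cv_vt,
                            "excluded": fit.excluded,
                            "true_vt": scan.true_vt[region],
                        }
                    )
                fits_by[(subj.subject_id, model, cond)] = fits
            for region, tac in scan.tacs.items():
                suv_rows.append(
                    {
                        "subject": subj.subject_id,
                        "condition": cond,
                        "region": region,
                        "suv": compute_suv(tac, scan.injected_dose_mbq, subj.weight_kg),
                    }
                )
        log.info("fitted subject %s", subj.subject_id)

    vt_table = pd.DataFrame(fit_rows)
    included = vt_table[~vt_table["excluded"]]
    change_table = regional_change_table(included)

    individual: dict = {}
    pooled: dict = {}
    for model in models:
        per_subject_pairs = {}
        for subj in subjects:
            pairs = pairs_from_fits(
                fits_by[(subj.subject_id, model, "baseline")],
                fits_by[(subj.subject_id, model, "blocking")],
            )
            per_subject_pairs[subj.subject_id] = pairs
            individual.setdefault(subj.subject_id, {})[model] = lassen_individual(pairs)
        pooled[model] = lassen_population(per_subject_pairs)
        log.info(
            "occupancy (%s): pooled V_ND %.3f CI (%.3f, %.3f)",
            model, pooled[model].vnd, *pooled[model].vnd_ci,
        )

    sime_results = {}
    k = config.n_subjects if sime_subjects is None else min(sime_subjects, config.n_subjects)
    for subj in subjects[:k]:
        res = sime_vnd(
            subj.baseline.tacs,
            inputs[(subj.subject_id, "baseline")],
            grid=sime_grid,
        )
        sime_results[subj.subject_id] = res
        log.info("SIME %s: V_ND %.2f", subj.subject_id, res.vnd)

    comparison = None
    if len(sime_results) >= 2:
        ids = list(sime_results)
        comparison = compare_sime_lassen(
            [sime_results[s].vnd for s in ids],
            [individual[s]["2tcm"].vnd for s in ids],
            ids,
        )

    result = StudyResult(
        config=config,
        vt_table=vt_table,
        change_table=change_table,
        individual=individual,
        pooled=pooled,
        sime=sime_results,
        comparison=comparison,
        suv_table=pd.DataFrame(suv_rows),
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    from . import io as pio

    outdir.mkdir(parents=True, exist_ok=True)
    result.vt_table.to_csv(outdir / "vt_fits.csv", index=False)
    result.change_table.to_csv(outdir / "vt_change_table.csv", index=False)
    result.suv_table.to_csv(outdir / "suv_table.csv", index=False)
    occ = {
        "pooled": {
            m: _occfit_dict(f) for m, f in result.pooled.items()
        },
        "individual": {
            s: {m: _occfit_dict(f) for m, f in d.items()} for s, d in result.individual.items()
        },
    }
    pio.write_json(outdir / "occupancy.json", occ)
    # plot-ready occupancy points: delta V_T vs baseline V_T per subject/model
    plot_rows = []
    vt = result.vt_table[~result.vt_table["excluded"]]
    piv = vt.pivot_table(
        index=["subject", "model", "region"], columns="condition", values="vt"
    ).reset_index()
    if {"baseline", "blocking"} <= set(piv.columns):
        piv["delta_vt"] = piv["baseline"] - piv["blocking"]
        plot_rows = piv[["subject", "model", "region", "baseline", "delta_vt"]]
        plot_rows.to_csv(outdir / "occupancy_points.tsv", sep="\t", index=False)
    if result.sime:
        pio.write_json(
            outdir / "sime.json",
            {
                s: {"vnd": r.vnd, "grid": r.grid, "rss": r.rss, "flags": r.flags}
                for s, r in result.sime.items()
            },
        )
    if result.comparison is not None:
        pio.write_json(outdir / "sime_vs_lassen.json", result.comparison)


def _occfit_dict(fit: OccupancyFit) -> dict:
    d = dataclasses.asdict(fit)
    d["residuals"] = np.asarray(d["residuals"]).tolist()
    return d
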