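"""Plain-text readers and writers for the pipeline's file formats.

TACs and blood series travel as TSV with fixed column names; fitted models,
metadata and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import BloodSeries
from .frames import TAC, FrameSchedule

TAC_COLUMNS = ["frame_start_min", "frame_duration_min", "activity_kBq_per_mL"]
BLOOD_COLUMNS = ["time_min", "wholeblood_kBq_per_mL", "plasma_over_blood", "parent_fraction"]
CONTINUOUS_COLUMNS = ["time_min", "wholeblood_kBq_per_mL"]


def write_tac_tsv(path, tac: TAC) -> None:
    df = pd.DataFrame(
        {
            TAC_COLUMNS[0]: tac.schedule.frame_start,
            TAC_COLUMNS[1]: tac.schedule.frame_duration,
            TAC_COLUMNS[2]: tac.activity,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tac_tsv(path, region: str = "", condition: str = "") -> TAC:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TAC columns {missing}")
    sched = FrameSchedule(df[TAC_COLUMNS[0]].to_numpy(), df[TAC_COLUMNS[1]].to_numpy())
    return TAC(sched, df[TAC_COLUMNS[2]].to_numpy(), region=region, condition=condition)


def write_blood_tsv(path, blood: BloodSeries) -> None:
    pd.DataFrame(
        {
            BLOOD_COLUMNS[0]: blood.times,
            BLOOD_COLUMNS[1]: blood.wholeblood,
            BLOOD_COLUMNS[2]: blood.pob,
            BLOOD_COLUMNS[3]: blood.ppf,
        }
    ).to_csv(path, sep="\t", index=False)


def read_blood_tsv(path) -> BloodSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOOD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing blood columns {missing}")
    return BloodSeries(*(df[c].to_numpy() for c in BLOOD_COLUMNS))


def write_continuous_tsv(path, times, values) -> None:
    pd.DataFrame({CONTINUOUS_COLUMNS[0]: times, CONTINUOUS_COLUMNS[1]: values}).to_csv(
        path, sep="\t", index=False
    )


def read_continuous_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return df[CONTINUOUS_COLUMNS[0]].to_numpy(), df[CONTINUOUS_COLUMNS[1]].to_numpy()


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
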