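"""Readers and writers for subject records.

On-disk layout per subject: a waveform CSV (``<stem>.csv``, columns ``time_s,
area_cm2, flow_ml_s``; comma separator, '.' decimal, UTF-8, mandatory header)
and a JSON metadata sidecar (``<stem>.json``) carrying identity, group, body
size and brachial pressures. Round-trip preserves every numeric field to 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .waveforms import AorticCycle, BrachialBP, SubjectRecord

WAVEFORM_COLUMNS = ("time_s", "area_cm2", "flow_ml_s")

_OPTIONAL_KEYS = {
    "lvm_g": "lvm",
    "diam_transverse_mm": "diam_transverse",
    "diam_isthmus_mm": "diam_isthmus",
    "diam_descending_mm": "diam_descending",
}


def read_subject_csv(path: str | Path) -> SubjectRecord:
    """Read one subject from a waveform CSV plus its JSON sidecar.

    ``path`` may point at either file; the sibling with the other extension is
    located automatically. Each invariant violation raises a
    :class:`~coawave.errors.ValidationError` naming the offending field.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    meta_path = path.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)

    table = pd.read_csv(csv_path)
    for col in WAVEFORM_COLUMNS:
        if col not in table.columns:
            raise ValidationError(col, f"missing column in {csv_path.name}")
    meta = json.loads(meta_path.read_text())
    for key in ("id", "group", "bsa_m2", "sbp_mmHg", "dbp_mmHg", "mbp_mmHg"):
        if key not in meta:
            raise ValidationError(key, f"missing metadata key in {meta_path.name}")

    cycle = AorticCycle(
        time=table["time_s"].to_numpy(float),
        area=table["area_cm2"].to_numpy(float),
        flow=table["flow_ml_s"].to_numpy(float),
        period=float(meta.get("period_s", 0.0)),
    )
    bp = BrachialBP(
        sbp=float(meta["sbp_mmHg"]), dbp=float(meta["dbp_mmHg"]), mbp=float(meta["mbp_mmHg"])
    )
    kwargs = {}
    for key, attr in _OPTIONAL_KEYS.items():
        if meta.get(key) is not None:
            kwargs[attr] = float(meta[key])
    return SubjectRecord(
        id=str(meta["id"]),
        group=str(meta["group"]),
        bsa=float(meta["bsa_m2"]),
        bp=bp,
        cycle=cycle,
        sex=str(meta.get("sex", "M")),
        age=float(meta.get("age_years", 0.0)),
        **kwargs,
    )


def write_subject_csv(record: SubjectRecord, path: str | Path) -> None:
    """Write ``record`` as waveform CSV + JSON sidecar at ``path`` (any suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cycle = record.cycle
    table = pd.DataFrame(
        {
            "time_s": cycle.time,
            "area_cm2": cycle.area,
            "flow_ml_s": cycle.flow,
        }
    )
    table.to_csv(path.with_suffix(".csv"), index=False, float_format="%.12g")
    meta = {
        "id": record.id,
        "group": record.group,
        "sex": record.sex,
        "age_years": record.age,
        "bsa_m2": record.bsa,
        "sbp_mmHg": record.bp.sbp,
        "dbp_mmHg": record.bp.dbp,
        "mbp_mmHg": record.bp.mbp,
        "period_s": cycle.period,
    }
    for key, attr in _OPTIONAL_KEYS.items():
        v = getattr(record, attr)
        if v is not None:
            meta[key] = v
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Read every ``*.csv``/``*.json`` subject pair in a directory (sorted by id)."""
    directory = Path(directory)
    records = []
    for csv_path in sorted(directory.glob("*.csv")):
        if csv_path.stem == "manifest":
            continue
        if csv_path.with_suffix(".json").exists():
            records.append(read_subject_csv(csv_path))
    return records
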