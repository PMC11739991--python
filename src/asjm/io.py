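"""Cohort file schemas, validation, configuration and run provenance.

Long-format cohorts are exchanged as two CSV files:

``patients.csv``
    patient_id, age_at_diagnosis, status (event|censored), observed_time_y
``observations.csv``
    patient_id, time_y, channel (psa|volume|mri_lesion|biopsy_gg), value

All times are decimal years since diagnosis (0 at diagnosis); PSA is in
ng/mL (numerically identical in ug/L), prostate volume in mL.  A
simulated cohort additionally carries a ``ground_truth.yaml`` sidecar
with the generating parameters and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._core import RAW_CHANNELS, PatientRecord

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_config",
    "write_provenance",
    "CohortValidationError",
]

PATIENT_COLUMNS = ["patient_id", "age_at_diagnosis", "status", "observed_time_y"]
OBSERVATION_COLUMNS = ["patient_id", "time_y", "channel", "value"]


class CohortValidationError(ValueError):
    """Raised after a full scan, carrying every row-level problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"cohort validation failed with {len(errors)} error(s):\n{preview}{more}")


def read_cohort(patients_path, observations_path) -> list[PatientRecord]:
    """Read and validate a two-file cohort; row errors cite line numbers.

    The full files are scanned before failing so every problem is
    reported at once.
    """
    pat = pd.read_csv(patients_path, float_precision="round_trip")
    obs = pd.read_csv(observations_path, float_precision="round_trip")
    errors: list[str] = []
    for cols, df, name in (
        (PATIENT_COLUMNS, pat, "patients"),
        (OBSERVATION_COLUMNS, obs, "observations"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError(
                [f"{name} file is missing column(s): {', '.join(missing)}"]
            )

    records: dict[str, PatientRecord] = {}
    for i, row in enumerate(pat.itertuples(index=False), start=2):  # header = line 1
        pid = str(row.patient_id)
        if pid in records:
            errors.append(f"patients line {i}: duplicate patient_id {pid}")
            continue
        if row.status not in ("event", "censored"):
            errors.append(f"patients line {i}: status must be event|censored, got {row.status!r}")
            continue
        t = float(row.observed_time_y)
        if not np.isfinite(t) or t < 0:
            errors.append(f"patients line {i}: invalid observed_time_y {row.observed_time_y}")
            continue
        records[pid] = PatientRecord(
            patient_id=pid,
            age_at_diagnosis=float(row.age_at_diagnosis),
            event_time_y=t if row.status == "event" else None,
            censor_time_y=t if row.status == "censored" else None,
        )

    for i, row in enumerate(obs.itertuples(index=False), start=2):
        pid = str(row.patient_id)
        if pid not in records:
            errors.append(f"observations line {i}: unknown patient_id {pid}")
            continue
        if row.channel not in RAW_CHANNELS:
            errors.append(f"observations line {i}: unknown channel {row.channel!r}")
            continue
        t = float(row.time_y)
        v = float(row.value)
        if not np.isfinite(t) or t < 0:
            errors.append(f"observations line {i}: negative or invalid time {row.time_y}")
            continue
        if row.channel in ("psa", "volume") and not v > 0:
            errors.append(f"observations line {i}: nonpositive {row.channel} value {v}")
            continue
        if row.channel == "mri_lesion" and v not in (0.0, 1.0):
            errors.append(f"observations line {i}: mri_lesion value {v} not in {{0,1}}")
            continue
        if row.channel == "biopsy_gg" and (v < 0 or v != int(v)):
            errors.append(f"observations line {i}: biopsy_gg value {v} not an integer >= 0")
            continue
        records[pid].observations.append((t, str(row.channel), v))

    out = []
    for pid, rec in records.items():
        rec.observations.sort(key=lambda o: (o[0], o[1]))
        errors.extend(rec.validate())
        out.append(rec)
    if errors:
        raise CohortValidationError(errors)
    return out


def write_cohort(
    records: list[PatientRecord],
    outdir,
    truth: dict | None = None,
) -> tuple[Path, Path]:
    """Write patients.csv / observations.csv (+ ground_truth.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pat = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age_at_diagnosis": [r.age_at_diagnosis for r in records],
            "status": [r.status for r in records],
            "observed_time_y": [r.observed_time_y for r in records],
        }
    )
    rows = []
    for r in records:
        for t, ch, v in r.observations:
            rows.append({"patient_id": r.patient_id, "time_y": t, "channel": ch, "value": v})
    obs = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    ppath = outdir / "patients.csv"
    opath = outdir / "observations.csv"
    pat.to_csv(ppath, index=False)
    obs.to_csv(opath, index=False)
    if truth is not None:
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
    return ppath, opath


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def write_provenance(outdir, command: str, args: dict, seed: int | None,
                     started: float) -> Path:
    """Drop a provenance JSON next to a command's outputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(args, sort_keys=True, default=str)
    payload = {
        "command": command,
        "args": args,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "wall_time_s": round(time.time() - started, 3),
    }
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
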