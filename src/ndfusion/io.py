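"""Cohort persistence: clinical CSV, NIfTI / array-container volumes, YAML.

On-disk layout produced by :func:`save_cohort` (and the ``simulate`` CLI):

    <dir>/clinical.csv          one row per patient (schema below)
    <dir>/volumes/<id>.nii.gz   one NIfTI per patient        (fmt="nifti")
    <dir>/volumes.npz           single container keyed by id (fmt="npz")

CSV schema: patient_id,gender,age,lohs,thrombolysis,nihss_admission,
nihss_max,nihss_discharge,vas,nd_label
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import ClinicalRecord

__all__ = ["save_cohort", "load_cohort", "write_clinical_csv",
           "read_clinical_csv", "load_yaml_config", "write_predictions_csv"]

CSV_COLUMNS = ["patient_id", "gender", "age", "lohs", "thrombolysis",
               "nihss_admission", "nihss_max", "nihss_discharge", "vas", "nd_label"]


def write_clinical_csv(records: list[ClinicalRecord], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    # %.17g keeps float64 exact through the text roundtrip
    df.loc[:, CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_clinical_csv(path) -> list[ClinicalRecord]:
    # round_trip parsing: the default fast parser is off by an ulp, which can
    # flip the deterioration rule for scores sitting exactly on the threshold
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns: {sorted(missing)}")
    return [ClinicalRecord(**{k: row[k] for k in CSV_COLUMNS})
            for _, row in df.iterrows()]


def save_cohort(records, volumes: np.ndarray | None, out_dir, fmt: str = "npz") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_clinical_csv(records, out / "clinical.csv")
    if volumes is None:
        return
    if fmt == "npz":
        np.savez_compressed(out / "volumes.npz",
                            **{r.patient_id: volumes[i] for i, r in enumerate(records)})
    elif fmt == "nifti":
        vdir = out / "volumes"
        vdir.mkdir(exist_ok=True)
        for i, r in enumerate(records):
            img = nib.Nifti1Image(np.asarray(volumes[i], dtype=np.float32), np.eye(4))
            nib.save(img, vdir / f"{r.patient_id}.nii.gz")
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def load_cohort(in_dir) -> tuple[list[ClinicalRecord], np.ndarray | None, np.ndarray]:
    src = Path(in_dir)
    records = read_clinical_csv(src / "clinical.csv")
    labels = np.array([r.nd_label for r in records], dtype=int)
    volumes = None
    if (src / "volumes.npz").exists():
        with np.load(src / "volumes.npz") as npz:
            volumes = np.stack([npz[r.patient_id] for r in records])
    elif (src / "volumes").is_dir():
        vols = [np.asarray(nib.load(src / "volumes" / f"{r.patient_id}.nii.gz").dataobj)
                for r in records]
        volumes = np.stack(vols)
    return records, volumes, labels


def write_predictions_csv(records, scores: np.ndarray, labels: np.ndarray, path,
                          threshold: float = 0.5) -> None:
    pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "score": scores,
        "pred": (np.asarray(scores) >= threshold).astype(int),
        "label": np.asarray(labels).astype(int),
    }).to_csv(path, index=False)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
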