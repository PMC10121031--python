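"""Readers and writers for the study tables.

Record, deployment and covariate tables are consumed from CSV or XLSX with
an optional column-name mapping (a dict or a YAML file mapping the file's
column names onto the canonical ones).  Detection histories are written as
one wide CSV per species plus an effort matrix and a JSON sidecar of site
labels, so downstream tools need no custom binary format.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .detections import DetectionData


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _read_table(path, mapping=None) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if mapping:
        if isinstance(mapping, (str, Path)):
            mapping = load_yaml(mapping)
        df = df.rename(columns=mapping)
    return df


def read_records(path, mapping=None) -> pd.DataFrame:
    """Photo-event table with columns station_id, species, timestamp."""
    return _read_table(path, mapping)


def read_deployments(path, mapping=None) -> pd.DataFrame:
    """Camera active intervals with columns station_id, start, end."""
    return _read_table(path, mapping)


def read_covariates(path, mapping=None) -> pd.DataFrame:
    """Station covariate table keyed by station_id."""
    return _read_table(path, mapping)


def write_detection_data(data: DetectionData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [f"{st}|survey{sv}" for st, sv in data.sites]
    occ_cols = [f"occ{j + 1}" for j in range(data.n_occasions)]
    for sp, mat in data.y.items():
        pd.DataFrame(mat, index=labels, columns=occ_cols).to_csv(outdir / f"history_{sp}.csv")
    pd.DataFrame(data.effort, index=labels, columns=occ_cols).to_csv(outdir / "effort.csv")
    sidecar = {
        "sites": [{"station_id": st, "survey": int(sv)} for st, sv in data.sites],
        "species_pair": list(data.species_pair),
        "study_start": data.design.study_start.isoformat(),
        "survey_days": data.design.survey_days,
        "n_occasions": data.design.n_occasions,
        "occasion_days": data.design.occasion_days,
    }
    (outdir / "sites.json").write_text(json.dumps(sidecar, indent=2))
    if data.site_covariates is not None:
        data.site_covariates.to_csv(outdir / "site_covariates.csv", index=False)


def write_study(study, outdir) -> None:
    """Write a simulated study's observable tables and a truth summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.records.to_csv(outdir / "records.csv", index=False)
    study.deployments.to_csv(outdir / "deployments.csv", index=False)
    study.covariates.to_csv(outdir / "covariates.csv", index=False)
    truth = {
        "seed": study.config.seed,
        "species_pair": list(study.config.species_pair),
        "f1": study.config.f1,
        "f2": study.config.f2,
        "f12": study.config.f12,
        "p1": study.config.p1,
        "p2": study.config.p2,
        "n_sites": study.detection_data.n_sites,
        "latent_occupancy": {
            sp: float(z.mean()) for sp, z in study.truth["z"].items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
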