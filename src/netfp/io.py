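"""Readers and writers for cohort artifacts.

Formats (all plain text):

* TAC table — TSV, long format, columns
  ``scan_id, roi, frame_index, activity_kBq_per_mL``.
* Manifest — JSON: per-scan metadata, covariates, frame schedule
  (start/end minute arrays) and the relative path of the IDIF file.
* IDIF — TSV, columns ``time_min, concentration_kBq_per_mL``.
* Similarity matrix — TSV with an ROI-name header row and a leading
  ROI-name column.
* Edge table — TSV, rows are scans, columns are ``roi_i|roi_j`` edges in
  canonical upper-triangle order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FrameSchedule, InputFunction, ScanRecord, TimeActivityCurve
from .registry import RoiRegistry, build_default_registry

__all__ = [
    "write_cohort",
    "load_cohort",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_edge_table",
    "read_edge_table",
    "covariate_frame",
]

_MANIFEST_NAME = "manifest.json"
_TAC_TABLE_NAME = "tacs.tsv"

_COVARIATE_KEYS = (
    "subject_id",
    "tracer",
    "batch",
    "dose_mbq",
    "weight_kg",
    "age",
    "sex",
    "genotype",
    "diagnosis",
    "session",
)


def write_cohort(scans: Sequence[ScanRecord], out_dir: str | Path) -> Path:
    """Write a cohort (manifest + TAC table + per-scan IDIF files).

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idif_dir = out_dir / "idif"
    idif_dir.mkdir(exist_ok=True)

    rows = []
    manifest_scans = []
    for scan in scans:
        if scan.schedule is None or scan.idif is None:
            raise ValueError(f"scan {scan.scan_id!r} lacks a schedule or IDIF")
        idif_path = idif_dir / f"{scan.scan_id}.tsv"
        pd.DataFrame(
            {
                "time_min": scan.idif.times,
                "concentration_kBq_per_mL": scan.idif.concentrations,
            }
        ).to_csv(idif_path, sep="\t", index=False, float_format="%.12g")
        for roi, tac in scan.tacs.items():
            for k, v in enumerate(tac.values):
                rows.append((scan.scan_id, roi, k, v))
        entry = {"scan_id": scan.scan_id}
        entry.update({k: getattr(scan, k) for k in _COVARIATE_KEYS})
        entry["frame_start_min"] = scan.schedule.frame_start.tolist()
        entry["frame_end_min"] = scan.schedule.frame_end.tolist()
        entry["idif_path"] = str(idif_path.relative_to(out_dir))
        manifest_scans.append(entry)

    tac_df = pd.DataFrame(rows, columns=["scan_id", "roi", "frame_index", "activity_kBq_per_mL"])
    tac_df.to_csv(out_dir / _TAC_TABLE_NAME, sep="\t", index=False, float_format="%.12g")

    manifest = {
        "format_version": 1,
        "tac_table": _TAC_TABLE_NAME,
        "units": {"time": "minutes", "activity": "kBq/mL", "dose": "MBq", "weight": "kg"},
        "scans": manifest_scans,
    }
    manifest_path = out_dir / _MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def load_cohort(
    manifest_path: str | Path,
    tac_dir: str | Path | None = None,
    registry: RoiRegistry | None = None,
) -> list[ScanRecord]:
    """Load and validate a cohort written by :func:`write_cohort`.

    ``tac_dir`` defaults to the manifest's directory.  Every registry ROI
    must have exactly one TAC per scan.
    """
    manifest_path = Path(manifest_path)
    base = Path(tac_dir) if tac_dir is not None else manifest_path.parent
    registry = registry or build_default_registry()
    manifest = json.loads(manifest_path.read_text())

    tac_path = base / manifest["tac_table"]
    if not tac_path.exists():
        raise FileNotFoundError(f"TAC table not found: {tac_path}")
    tac_df = pd.read_csv(tac_path, sep="\t")
    required_cols = {"scan_id", "roi", "frame_index", "activity_kBq_per_mL"}
    if not required_cols.issubset(tac_df.columns):
        raise ValueError(f"TAC table missing columns {sorted(required_cols - set(tac_df.columns))}")
    grouped = {sid: g for sid, g in tac_df.groupby("scan_id", sort=False)}

    scans: list[ScanRecord] = []
    for entry in manifest["scans"]:
        scan_id = entry["scan_id"]
        try:
            schedule = FrameSchedule(
                np.asarray(entry["frame_start_min"], dtype=float),
                np.asarray(entry["frame_end_min"], dtype=float),
            )
        except ValueError as exc:
            raise ValueError(f"scan {scan_id!r}: malformed schedule: {exc}") from exc
        if scan_id not in grouped:
            raise ValueError(f"scan {scan_id!r}: no TAC rows found in {tac_path}")
        g = grouped[scan_id]
        tacs: dict[str, TimeActivityCurve] = {}
        for roi, rg in g.groupby("roi", sort=False):
            rg = rg.sort_values("frame_index")
            if not np.array_equal(rg["frame_index"].to_numpy(), np.arange(schedule.n_frames)):
                raise ValueError(
                    f"scan {scan_id!r}, ROI {roi!r}: frame indices do not cover "
                    f"0..{schedule.n_frames - 1}"
                )
            tacs[str(roi)] = TimeActivityCurve(str(roi), rg["activity_kBq_per_mL"].to_numpy())
        idif_path = base / entry["idif_path"]
        if not idif_path.exists():
            raise FileNotFoundError(f"scan {scan_id!r}: IDIF file not found: {idif_path}")
        idif_df = pd.read_csv(idif_path, sep="\t")
        idif = InputFunction(
            idif_df["time_min"].to_numpy(), idif_df["concentration_kBq_per_mL"].to_numpy()
        )
        scan = ScanRecord(
            scan_id=scan_id,
            subject_id=str(entry["subject_id"]),
            tracer=str(entry["tracer"]),
            batch=str(entry["batch"]),
            dose_mbq=float(entry["dose_mbq"]),
            weight_kg=float(entry["weight_kg"]),
            age=float(entry["age"]),
            sex=str(entry["sex"]),
            genotype=str(entry["genotype"]),
            diagnosis=str(entry["diagnosis"]),
            session=str(entry["session"]),
            tacs=tacs,
            schedule=schedule,
            idif=idif,
        )
        scan.validate_against_registry(registry)
        scans.append(scan)
    return scans


def covariate_frame(scans: Sequence[ScanRecord]) -> pd.DataFrame:
    """Covariate table indexed by scan_id (adds the dose/weight column)."""
    df = pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "subject_id": s.subject_id,
                "tracer": s.tracer,
                "batch": s.batch,
                "sex": s.sex,
                "genotype": s.genotype,
                "age": s.age,
                "dose_mbq": s.dose_mbq,
                "weight_kg": s.weight_kg,
                "dw": s.dose_over_weight,
                "diagnosis": s.diagnosis,
                "session": s.session,
            }
            for s in scans
        ]
    ).set_index("scan_id")
    return df


def write_similarity_matrix(matrix, path: str | Path) -> Path:
    """Write a :class:`~netfp.network.SimilarityMatrix` as labelled TSV."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.roi_names, columns=matrix.roi_names)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="roi")
    return path


def read_similarity_matrix(path: str | Path, registry: RoiRegistry | None = None):
    """Read a similarity matrix; validate dimension/order against a registry."""
    from .network import SimilarityMatrix  # local import: avoid cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if registry is not None:
        if list(df.index) != registry.names or list(df.columns) != registry.names:
            raise ValueError(
                f"similarity matrix in {path} does not match the registry "
                f"({df.shape[0]} rows vs {len(registry)} ROIs, or name/order mismatch)"
            )
    scan_id = path.stem
    return SimilarityMatrix(scan_id=scan_id, roi_names=list(df.index), values=df.to_numpy())


def write_edge_table(edge_df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    edge_df.to_csv(path, sep="\t", float_format="%.17g", index_label="scan_id")
    return path


def read_edge_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="scan_id")
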