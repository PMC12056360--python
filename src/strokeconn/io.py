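"""File formats and pipeline configuration.

Everything desk-scale and diff-able: time series and clinical tables as
CSV, result tables as TSV, masks as NIfTI, manifests and provenance as
JSON.  Every manifest embeds a hash of the configuration that produced
it, so a rerun with the same config and inputs is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RoiTimeSeriesPanel, SubjectTimeSeries


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the published analysis settings."""

    # preprocessing
    fd_threshold_mm: float = 0.9
    gs_sd_threshold: float = 5.0
    band_low_hz: float = 0.008
    band_high_hz: float = 0.09
    # graph thresholds
    tau_min: float = 0.15
    tau_max: float = 0.50
    tau_step: float = 0.01
    # elastic net
    mixing_range: tuple[float, float] = (0.05, 1.0)
    penalty_range: tuple[float, float] = (0.0002, 0.36)
    n_candidates: int = 100
    n_folds: int = 5
    n_repeats: int = 20
    freq_threshold: float = 0.9
    # inference
    fdr_alpha: float = 0.05
    # lesion load
    lesion_weight: str = "max_over_area"
    # randomness
    seed: int = 0

    def tau_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.tau_min, self.tau_max + self.tau_step / 2, self.tau_step), 10
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "mixing_range" in raw:
            raw["mixing_range"] = tuple(raw["mixing_range"])
        if "penalty_range" in raw:
            raw["penalty_range"] = tuple(raw["penalty_range"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_panel(panel: RoiTimeSeriesPanel, out_dir: str | Path,
                config: PipelineConfig | None = None, seed: int | None = None) -> None:
    """One CSV per subject (rows = ROIs, columns = timepoints) plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in panel.subjects:
        frame = pd.DataFrame(s.data, index=panel.roi_labels)
        frame.to_csv(out / f"{s.subject_id}_bold.csv")
        if s.fd is not None:
            pd.DataFrame({"fd_mm": s.fd}).to_csv(out / f"{s.subject_id}_fd.csv", index=False)
        if s.confounds is not None:
            pd.DataFrame(s.confounds).to_csv(out / f"{s.subject_id}_confounds.csv", index=False)
    manifest = {
        "tr_seconds": panel.tr_seconds,
        "roi_labels": panel.roi_labels,
        "subjects": [s.subject_id for s in panel.subjects],
        "usable": {s.subject_id: bool(s.usable) for s in panel.subjects},
    }
    if seed is not None:
        manifest["seed"] = seed
    if config is not None:
        manifest["config_hash"] = config.hash()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_panel(panel_dir: str | Path) -> RoiTimeSeriesPanel:
    """Read a panel written by :func:`write_panel`."""
    d = Path(panel_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    subjects = []
    for sid in manifest["subjects"]:
        bold = pd.read_csv(d / f"{sid}_bold.csv", index_col=0)
        fd_path = d / f"{sid}_fd.csv"
        fd = pd.read_csv(fd_path)["fd_mm"].to_numpy() if fd_path.exists() else None
        conf_path = d / f"{sid}_confounds.csv"
        confounds = pd.read_csv(conf_path).to_numpy() if conf_path.exists() else None
        subjects.append(SubjectTimeSeries(
            subject_id=sid, data=bold.to_numpy(dtype=float), fd=fd,
            confounds=confounds,
            usable=manifest.get("usable", {}).get(sid, True),
        ))
    return RoiTimeSeriesPanel(subjects, manifest["roi_labels"], manifest["tr_seconds"])


def read_clinical(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "subject_id" not in table.columns:
        raise ValueError(f"{path}: clinical table must have a 'subject_id' column")
    return table.set_index("subject_id")
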