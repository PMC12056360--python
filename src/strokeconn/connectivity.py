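"""ROI sets and per-subject ROI-to-ROI connectivity matrices.

Connectivity is the sample Pearson correlation between the denoised BOLD
time series of every ROI pair, Fisher z-transformed (atanh) to stabilize
the variance for downstream linear models.  ROIs carry a hemisphere tag —
Ip (ipsilesional) or C (contralesional) — and subjects whose lesion is in
the left hemisphere are standardized by swapping each ROI with its
homologue, which at the matrix level is a row/column permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CORTICAL_SMN_REGIONS = [
    "M1",
    "SMA",
    "premotor",
    "S1",
    "superior_parietal",
    "precuneus",
]
_SUBCORTICAL_SMN_REGIONS = [
    "VL_thalamus",
    "VA_thalamus",
    "VP_thalamus",
    "post_putamen",
    "cerebellum_I_V",
    "cerebellum_VIII",
]
_DMN_REGIONS = [
    "medial_orbitofrontal",
    "angular_gyrus",
    "precuneus_cingulate",
    "middle_temporal",
    "parahippocampal_gyrus",
    "ant_thalamus",
    "crus",
]

HEMISPHERES = ("Ip", "C")


def _bilateral(regions: list[str]) -> list[str]:
    return [f"{h}_{r}" for r in regions for h in HEMISPHERES]


@dataclass
class RoiSet:
    """A named network: bilateral ROI labels with homologue pairing.

    Every label is ``<hemi>_<region>`` with hemi in {Ip, C}; the homologue
    of an ROI is the same region in the opposite hemisphere.
    """

    name: str
    roi_labels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        for lbl in self.roi_labels:
            if self.homologue(lbl) not in self.roi_labels:
                raise ValueError(f"ROI {lbl!r} has no homologue in the set")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @staticmethod
    def homologue(label: str) -> str:
        hemi, _, region = label.partition("_")
        if hemi not in HEMISPHERES:
            raise ValueError(f"label {label!r} lacks an Ip/C hemisphere tag")
        other = "C" if hemi == "Ip" else "Ip"
        return f"{other}_{region}"

    def homologue_permutation(self) -> np.ndarray:
        """Index permutation mapping each ROI to its homologue."""
        index = {lbl: i for i, lbl in enumerate(self.roi_labels)}
        return np.array([index[self.homologue(lbl)] for lbl in self.roi_labels])


def cortical_smn() -> RoiSet:
    """12-ROI cortical sensorimotor network."""
    return RoiSet("cortical_SMN", _bilateral(_CORTICAL_SMN_REGIONS))


def smn() -> RoiSet:
    """24-ROI sensorimotor network (cortical plus subcortical/cerebellar)."""
    return RoiSet("SMN", _bilateral(_CORTICAL_SMN_REGIONS + _SUBCORTICAL_SMN_REGIONS))


def dmn() -> RoiSet:
    """14-ROI default mode network."""
    return RoiSet("DMN", _bilateral(_DMN_REGIONS))


ROI_SETS = {"cortical_SMN": cortical_smn, "SMN": smn, "DMN": dmn}


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson r and Fisher z matrices for one subject."""

    subject_id: str
    roi_set: RoiSet
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (self.roi_set.n_rois, self.roi_set.n_rois):
            raise ValueError("r matrix shape does not match the ROI set")
        if not np.allclose(r, r.T, atol=1e-12, equal_nan=True):
            raise ValueError("r matrix must be symmetric")
        finite = r[np.isfinite(r)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.r = r

    @property
    def z(self) -> np.ndarray:
        """Fisher z off-diagonal; diagonal masked as NaN."""
        z = fisher_z(self.r)
        np.fill_diagonal(z, np.nan)
        return z

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.roi_set.roi_labels,
                            columns=self.roi_set.roi_labels)


def pearson_matrix(
    data: np.ndarray,
    roi_set: RoiSet,
    subject_id: str = "",
    keep_frames: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """Sample Pearson correlation between every ROI pair.

    ``data`` is (n_rois, n_timepoints); ``keep_frames`` optionally selects
    the unscrubbed frames.  A zero-variance ROI yields NaN entries (with a
    warning) that downstream analyses exclude.
    """
    X = np.asarray(data, dtype=float)
    if keep_frames is not None:
        X = X[:, np.asarray(keep_frames)]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 usable frames to correlate")
    sd = X.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            f"zero-variance ROI(s) at index {degenerate.tolist()}; "
            "their correlations are set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(subject_id=subject_id, roi_set=roi_set, r=r)


def fisher_z(r: np.ndarray | float) -> np.ndarray:
    """Variance-stabilizing Fisher transform z = atanh(r), clipped at |r| = 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    return np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))


def flip_hemispheres(matrix: np.ndarray, roi_set: RoiSet) -> np.ndarray:
    """Swap each ROI with its contralateral homologue (an involution)."""
    perm = roi_set.homologue_permutation()
    M = np.asarray(matrix)
    return M[np.ix_(perm, perm)]
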