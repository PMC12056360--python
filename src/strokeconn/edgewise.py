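"""Edgewise association of connectivity with clinical measures.

For every ROI pair in a network, a simple linear model relates the
cohort's Fisher-z connectivity at that edge to one clinical measure; the
slope t-score and its two-sided p-value are reported, and the p-values of
all edges in the network are adjusted with the Benjamini-Hochberg
step-up false-discovery-rate procedure (family = one network x one
measure, significance at adjusted p < 0.05).

Because some measures improve downward (GAIT coordination, Timed Up and
Go), displayed t-scores are sign-adjusted so a positive value always
means "better function goes with higher connectivity".

The analysis is exposed both as plain functions (:func:`fit_edgewise`,
:func:`bh_fdr`) and as the :class:`EdgewiseConnectivityModel` /
:class:`EdgewiseResults` pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, RoiSet

logger = logging.getLogger(__name__)

#: Default direction flags: True when a higher score means better function.
DEFAULT_HIGHER_IS_BETTER = {
    "FM": True,
    "fGS": True,
    "pGS": True,
    "GAIT": False,   # lower = better coordination
    "TUG": False,    # lower = faster
    "FGA": True,
    "proprioception": True,
    "monofilament": True,
    "vibration": True,
    "lesion_load": False,
}

MIN_COMPLETE_CASES = 4


@dataclass
class ClinicalTable:
    """Per-subject clinical measures plus per-measure direction flags."""

    data: pd.DataFrame  # index = subject_id, columns = measures
    higher_is_better: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flags = dict(DEFAULT_HIGHER_IS_BETTER)
        flags.update(self.higher_is_better)
        missing = [c for c in self.data.columns if c not in flags]
        if missing:
            raise ValueError(
                f"no higher_is_better flag for measure(s) {missing}; "
                "pass them explicitly"
            )
        self.higher_is_better = {c: flags[c] for c in self.data.columns}
        for col in ("proprioception", "monofilament", "vibration"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if len(vals) and (vals.abs() > 1 + 1e-9).any():
                    raise ValueError(f"asymmetry index {col} must lie in [-1, 1]")

    @property
    def measures(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, measure: str) -> np.ndarray:
        return self.data[measure].to_numpy(dtype=float)


def asymmetry_index(unaffected: float, affected: float) -> float:
    """Interlimb sensory asymmetry: (unaffected - affected) / (unaffected + affected).

    Negative values indicate greater impairment of the affected limb.
    Returns NaN (with a warning) when the denominator is zero.
    """
    total = unaffected + affected
    if total == 0:
        warnings.warn("asymmetry index undefined: limb scores sum to zero", stacklevel=2)
        return float("nan")
    return (unaffected - affected) / total


def stack_edges(
    matrices: list[ConnectivityMatrix],
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Stack upper-triangle Fisher-z values across subjects.

    Returns (n_subjects, n_edges) array and the (roi_i, roi_j) labels.
    """
    if not matrices:
        raise ValueError("no connectivity matrices given")
    roi_set = matrices[0].roi_set
    labels = roi_set.roi_labels
    iu = np.triu_indices(roi_set.n_rois, k=1)
    Z = np.stack([m.z[iu] for m in matrices])
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return Z, pairs


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sign_adjust(t: np.ndarray | float, higher_is_better: bool) -> np.ndarray | float:
    """Flip t so positive always means better function with higher connectivity."""
    return t if higher_is_better else -t


def fit_edgewise(
    z: np.ndarray,
    pairs: list[tuple[str, str]],
    measure_values: np.ndarray,
    measure_name: str = "score",
    higher_is_better: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Slope t-tests of Fisher-z on one clinical measure, edge by edge.

    ``z`` is (n_subjects, n_edges).  Complete cases only; edges with fewer
    than four complete observations are skipped (logged).  The slope
    t-score of the simple regression of z on the measure equals the
    correlation t, so it is invariant to which variable is the response.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(measure_values, dtype=float)
    if z.shape[0] != y.size:
        raise ValueError("z and measure must cover the same subjects")
    y_ok = np.isfinite(y)
    rows = []
    for e, (roi_i, roi_j) in enumerate(pairs):
        mask = y_ok & np.isfinite(z[:, e])
        n = int(mask.sum())
        if n < MIN_COMPLETE_CASES:
            logger.info("edge (%s, %s): %d complete cases, skipped", roi_i, roi_j, n)
            continue
        ze, ye = z[mask, e], y[mask]
        if ye.std() == 0:
            raise ValueError(f"measure {measure_name!r} has zero variance")
        if ze.std() == 0:
            logger.info("edge (%s, %s): constant connectivity, skipped", roi_i, roi_j)
            continue
        r = float(np.corrcoef(ze, ye)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        df = n - 2
        denom = max(1.0 - r * r, 1e-300)
        t = r * np.sqrt(df) / np.sqrt(denom)
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((roi_i, roi_j, measure_name, n, t, p))
    table = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "measure", "n", "t", "p_raw"]
    )
    if len(table):
        table["p_fdr"] = bh_fdr(table["p_raw"].to_numpy())
        table["significant"] = table["p_fdr"] < alpha
        table["t_signed"] = sign_adjust(table["t"].to_numpy(), higher_is_better)
    else:
        table["p_fdr"] = []
        table["significant"] = []
        table["t_signed"] = []
    return table


class EdgewiseConnectivityModel:
    """Edgewise linear association of a network's connectivity with clinical measures.

    Parameters
    ----------
    matrices
        Per-subject connectivity matrices over one ROI set, in the same
        order as the rows of ``clinical.data``.
    clinical
        Clinical measure table with direction flags.
    """

    def __init__(self, matrices: list[ConnectivityMatrix], clinical: ClinicalTable):
        if len(matrices) != len(clinical.data):
            raise ValueError("one connectivity matrix per clinical row required")
        self.matrices = matrices
        self.clinical = clinical
        self.roi_set = matrices[0].roi_set
        self.z, self.pairs = stack_edges(matrices)

    @classmethod
    def from_dataframe(
        cls,
        z_frame: pd.DataFrame,
        roi_set: RoiSet,
        clinical: ClinicalTable,
    ) -> "EdgewiseConnectivityModel":
        """Build from a subjects x edges Fisher-z DataFrame.

        Columns must be "roi_i|roi_j" edge names over ``roi_set``.
        """
        pairs = [tuple(c.split("|")) for c in z_frame.columns]
        model = cls.__new__(cls)
        model.matrices = []
        model.clinical = clinical
        model.roi_set = roi_set
        model.z = z_frame.to_numpy(dtype=float)
        model.pairs = pairs
        return model

    def fit(self, measures: list[str] | None = None, alpha: float = 0.05) -> "EdgewiseResults":
        """Fit every edge against every requested measure (FDR per measure)."""
        measures = self.clinical.measures if measures is None else measures
        tables = []
        for m in measures:
            tables.append(
                fit_edgewise(
                    self.z,
                    self.pairs,
                    self.clinical.values_for(m),
                    measure_name=m,
                    higher_is_better=self.clinical.higher_is_better[m],
                    alpha=alpha,
                )
            )
        return EdgewiseResults(
            table=pd.concat(tables, ignore_index=True),
            network=self.roi_set.name,
            alpha=alpha,
        )


@dataclass
class EdgewiseResults:
    """Edge association table with FDR-adjusted p and sign-adjusted t."""

    table: pd.DataFrame
    network: str
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        """Text table of FDR-significant edges, largest |t| first."""
        sig = self.significant.sort_values("p_fdr")
        lines = [
            f"Edgewise connectivity associations — network {self.network}",
            f"{len(self.table)} edge-measure tests, "
            f"{len(sig)} significant at FDR {self.alpha:g}",
            "",
            f"{'Measure':<16}{'ROI-1':<26}{'ROI-2':<26}{'FDR p':>8}{'T score':>9}",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"{row['measure']:<16}{row['roi_i']:<26}{row['roi_j']:<26}"
                f"{row['p_fdr']:>8.3f}{row['t_signed']:>9.3f}"
            )
        return "\n".join(lines)
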