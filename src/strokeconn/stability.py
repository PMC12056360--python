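"""Repeated cross-validated elastic-net stability selection.

This implements the regression procedure used to relate nodal graph-metric
AUC values (features: one column per ROI of a network) to a clinical
outcome:

1. normality gate — each outcome is Shapiro-Wilk tested; outcomes with
   p < 0.05 are Box-Cox transformed (maximum-likelihood lambda, with a
   recorded shift when the data are not strictly positive);
2. elastic net with five-fold cross-validation over a grid of 100
   candidates: 10 mixing values alpha in [0.05, 1] crossed with 10
   penalty strengths lambda log-spaced in [0.0002, 0.36]; the candidate
   with the lowest cross-validated RMSE is refitted on the full data;
3. stability loop — the whole CV fit is repeated 20 times with
   re-drawn fold assignments; an ROI whose coefficient is nonzero in at
   least 90% of repeats has a *strong association* with the outcome;
4. ranking — mean coefficients (over the repeats where selected) of the
   strong set are expressed as a percentage of the largest magnitude
   (largest = 100%), with the direction of each relationship taken from
   the simple Pearson correlation of the raw feature with the raw outcome.

Features are standardized internally; coefficients are reported on the
standardized scale, so the rank percentages compare like with like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

N_MIXING = 10
N_PENALTY = 10
MIXING_RANGE = (0.05, 1.0)
PENALTY_RANGE = (0.0002, 0.36)
N_FOLDS = 5
N_REPEATS = 20
FREQ_THRESHOLD = 0.9


@dataclass
class TransformRecord:
    """Outcome normality check and the transform applied (if any)."""

    measure: str
    shapiro_w: float
    shapiro_p: float
    transformed: bool
    boxcox_lambda: float | None = None
    shift: float = 0.0


@dataclass
class ElasticNetCVFit:
    """One cross-validated elastic-net fit at the best (alpha, lambda)."""

    mixing_alpha: float      # L1 share of the penalty
    penalty_lambda: float    # overall penalty strength
    beta: np.ndarray         # coefficients on the standardized-feature scale
    cv_rmse: float
    seed: int


@dataclass
class StabilitySelectionResult:
    """Selection frequencies and strong-association set over the repeats."""

    outcome: str
    metric: str
    feature_names: list[str]
    selection_count: np.ndarray     # per feature, of `repeats`
    repeats: int
    mean_beta: np.ndarray           # mean over repeats where selected (NaN if never)
    strong_set: list[str]
    rank_percent: dict[str, float]  # strong features only; largest = 100
    direction: dict[str, int]       # sign of Pearson r(feature, outcome)
    per_repeat: pd.DataFrame        # chosen alpha/lambda and CV RMSE per repeat
    n_complete_cases: int
    transform: TransformRecord | None = None


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p; rejects constant input and n outside [3, 5000]."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000 finite values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def boxcox_transform(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Maximum-likelihood Box-Cox transform; shifts non-positive data first.

    Returns (transformed, lambda, shift) with y' = ((y + shift)^lambda - 1)/lambda
    (log(y + shift) at lambda = 0).
    """
    y = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("Box-Cox requires finite values")
    if np.ptp(y) == 0:
        raise ValueError("Box-Cox undefined for constant input")
    shift = 0.0
    if y.min() <= 0:
        shift = -float(y.min()) + 1e-6 * max(float(np.ptp(y)), 1.0)
    transformed, lam = stats.boxcox(y + shift)
    return transformed, float(lam), shift


def normality_gate(values: np.ndarray, measure: str = "") -> tuple[np.ndarray, TransformRecord]:
    """Box-Cox transform the outcome iff Shapiro-Wilk rejects normality at 0.05."""
    y = np.asarray(values, dtype=float)
    w, p = shapiro_wilk(y)
    if p >= 0.05:
        return y, TransformRecord(measure, w, p, transformed=False)
    yt, lam, shift = boxcox_transform(y)
    return yt, TransformRecord(measure, w, p, transformed=True,
                               boxcox_lambda=lam, shift=shift)


def _candidate_grid() -> tuple[np.ndarray, np.ndarray]:
    mixing = np.linspace(*MIXING_RANGE, N_MIXING)
    # descending penalties, as coordinate-descent paths expect
    penalty = np.logspace(np.log10(PENALTY_RANGE[1]), np.log10(PENALTY_RANGE[0]), N_PENALTY)
    return mixing, penalty


def fit_elastic_net_cv(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = N_FOLDS,
) -> ElasticNetCVFit:
    """Elastic net over the 100-candidate grid, scored by 5-fold CV RMSE.

    Features and the outcome are standardized on the full data, so the
    shared penalty range is meaningful across outcomes of different units;
    coefficients are returned on that standardized scale.  Within each
    fold the training means are used as intercepts.  Ties in CV RMSE
    resolve to the first candidate in grid order, which is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if n < 2 * n_folds:
        new_folds = max(2, n // 2)
        warnings.warn(
            f"only {n} cases; reducing CV folds {n_folds} -> {new_folds}",
            stacklevel=2,
        )
        n_folds = new_folds
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("outcome has zero variance")
    y = y / y_sd
    mixing, penalty = _candidate_grid()
    sq_err = np.zeros((N_MIXING, penalty.size))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # near-zero penalties at small n stop at the iteration cap; the
        # remaining duality gap is far below the CV noise floor
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in kf.split(Xs):
            Xtr, ytr = Xs[train], y[train]
            xm, ym = Xtr.mean(axis=0), ytr.mean()
            Xte_c = Xs[test] - xm
            for a_idx, l1 in enumerate(mixing):
                _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=l1, alphas=penalty)
                pred = Xte_c @ coefs + ym
                sq_err[a_idx] += ((pred - y[test, None]) ** 2).sum(axis=0)
        cv_rmse = np.sqrt(sq_err / n)
        a_idx, l_idx = np.unravel_index(np.argmin(cv_rmse), cv_rmse.shape)
        best_l1, best_lam = float(mixing[a_idx]), float(penalty[l_idx])
        xm, ym = Xs.mean(axis=0), y.mean()
        _, coefs, _ = enet_path(Xs - xm, y - ym, l1_ratio=best_l1, alphas=penalty)
        beta = coefs[:, l_idx]
    return ElasticNetCVFit(
        mixing_alpha=best_l1,
        penalty_lambda=best_lam,
        beta=beta,
        cv_rmse=float(cv_rmse[a_idx, l_idx]),
        seed=seed,
    )


def rank_coefficients(mean_beta: dict[str, float]) -> dict[str, float]:
    """Proportional magnitude ranking: the largest |beta| is 100%."""
    if not mean_beta:
        return {}
    top = max(abs(b) for b in mean_beta.values())
    if top == 0:
        return {k: 0.0 for k in mean_beta}
    return {k: 100.0 * abs(b) / top for k, b in mean_beta.items()}


def stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    repeats: int = N_REPEATS,
    freq_threshold: float = FREQ_THRESHOLD,
    base_seed: int = 0,
    outcome: str = "score",
    metric: str = "",
    transform: TransformRecord | None = None,
    y_raw: np.ndarray | None = None,
) -> StabilitySelectionResult:
    """Repeat the CV elastic net with re-drawn folds; report stable features.

    ``y`` is the (possibly Box-Cox transformed) outcome entering the
    penalized fits; ``y_raw`` (default: ``y``) is the untransformed outcome
    used for the Pearson-based direction of each relationship.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = [f"x{j}" for j in range(p)] if feature_names is None else list(feature_names)
    y_dir = y if y_raw is None else np.asarray(y_raw, dtype=float)
    counts = np.zeros(p, dtype=int)
    beta_sum = np.zeros(p)
    rows = []
    for rep in range(repeats):
        fit = fit_elastic_net_cv(X, y, seed=base_seed + rep)
        nonzero = fit.beta != 0
        counts += nonzero
        beta_sum += np.where(nonzero, fit.beta, 0.0)
        rows.append((rep, fit.mixing_alpha, fit.penalty_lambda, fit.cv_rmse,
                     int(nonzero.sum())))
    with np.errstate(invalid="ignore"):
        mean_beta = np.where(counts > 0, beta_sum / np.maximum(counts, 1), np.nan)
    need = int(np.ceil(freq_threshold * repeats))
    strong_idx = np.flatnonzero(counts >= need)
    strong = [names[j] for j in strong_idx]
    ranks = rank_coefficients({names[j]: float(mean_beta[j]) for j in strong_idx})
    direction = {
        names[j]: int(np.sign(np.corrcoef(X[:, j], y_dir)[0, 1]))
        if np.std(X[:, j]) > 0 else 0
        for j in strong_idx
    }
    per_repeat = pd.DataFrame(
        rows, columns=["repeat", "mixing_alpha", "penalty_lambda", "cv_rmse", "n_selected"]
    )
    return StabilitySelectionResult(
        outcome=outcome,
        metric=metric,
        feature_names=names,
        selection_count=counts,
        repeats=repeats,
        mean_beta=mean_beta,
        strong_set=strong,
        rank_percent=ranks,
        direction=direction,
        per_repeat=per_repeat,
        n_complete_cases=n,
        transform=transform,
    )


class StabilityElasticNet:
    """Stability-selection elastic net of nodal AUC features on one outcome.

    Parameters
    ----------
    X
        (subjects x ROIs) graph-metric AUC features for one metric.
    y
        Clinical outcome (raw scale; the normality gate is applied at fit
        time unless ``gate_normality=False``).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        feature_names: list[str] | None = None,
        outcome: str = "score",
        metric: str = "",
        gate_normality: bool = True,
    ):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n_subjects, n_features) matching y")
        complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("%s/%s: dropped %d incomplete case(s)", outcome, metric, dropped)
        self.X = X[complete]
        self.y_raw = y[complete]
        self.feature_names = feature_names
        self.outcome = outcome
        self.metric = metric
        self.gate_normality = gate_normality

    @classmethod
    def from_dataframe(
        cls,
        auc_frame: pd.DataFrame,
        outcome_values: pd.Series | np.ndarray,
        outcome: str = "score",
        metric: str = "",
        **kwargs,
    ) -> "StabilityElasticNet":
        """Build from an AUC DataFrame (index subjects, columns ROIs)."""
        y = np.asarray(outcome_values, dtype=float)
        return cls(y, auc_frame.to_numpy(dtype=float),
                   feature_names=list(auc_frame.columns),
                   outcome=outcome, metric=metric, **kwargs)

    def fit(self, repeats: int = N_REPEATS, base_seed: int = 0,
            freq_threshold: float = FREQ_THRESHOLD) -> "StabilityResults":
        if self.gate_normality:
            y_fit, record = normality_gate(self.y_raw, self.outcome)
        else:
            y_fit, record = self.y_raw, None
        res = stability_selection(
            self.X, y_fit,
            feature_names=self.feature_names,
            repeats=repeats,
            freq_threshold=freq_threshold,
            base_seed=base_seed,
            outcome=self.outcome,
            metric=self.metric,
            transform=record,
            y_raw=self.y_raw,
        )
        return StabilityResults(res)


@dataclass
class StabilityResults:
    """Results wrapper with a ranked-strong-set summary table."""

    result: StabilitySelectionResult

    @property
    def strong_set(self) -> list[str]:
        return self.result.strong_set

    @property
    def selection_frequency(self) -> pd.Series:
        r = self.result
        return pd.Series(r.selection_count / r.repeats, index=r.feature_names)

    def to_frame(self) -> pd.DataFrame:
        """Strong-set table: rank percent, direction, selection count."""
        r = self.result
        rows = [
            {
                "outcome": r.outcome,
                "metric": r.metric,
                "roi": name,
                "rank_percent": r.rank_percent[name],
                "direction": r.direction[name],
                "selection_count": int(r.selection_count[r.feature_names.index(name)]),
            }
            for name in r.strong_set
        ]
        frame = pd.DataFrame(
            rows, columns=["outcome", "metric", "roi", "rank_percent",
                           "direction", "selection_count"]
        )
        return frame.sort_values("rank_percent", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Stability elastic net — outcome {r.outcome}"
            + (f", metric {r.metric}" if r.metric else ""),
            f"{r.n_complete_cases} complete cases, {r.repeats} repeats, "
            f"strong set = nonzero in >= {int(np.ceil(FREQ_THRESHOLD * r.repeats))} repeats",
        ]
        if r.transform is not None:
            t = r.transform
            if t.transformed:
                lines.append(
                    f"outcome Box-Cox transformed (Shapiro-Wilk p = {t.shapiro_p:.3g}, "
                    f"lambda = {t.boxcox_lambda:.3f})"
                )
            else:
                lines.append(f"outcome kept raw (Shapiro-Wilk p = {t.shapiro_p:.3g})")
        lines.append("")
        lines.append(f"{'ROI':<28}{'rank %':>8}{'dir':>5}{'count':>7}")
        for _, row in self.to_frame().iterrows():
            sign = "(-)" if row["direction"] < 0 else ""
            lines.append(
                f"{row['roi']:<28}{row['rank_percent']:>8.0f}{sign:>5}"
                f"{row['selection_count']:>7d}"
            )
        if not r.strong_set:
            lines.append("(strong set empty)")
        return "\n".join(lines)
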