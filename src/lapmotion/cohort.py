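"""Cohort comparison: nonparametric group tests, robust Z scaling, gated PCA.

The per-participant metric table (one row per participant x task x instrument
x metric, mirroring the study-report layout) is compared across experience
groups with the Kruskal-Wallis test; where the three groups differ
(p < 0.05), pairwise Mann-Whitney U tests follow. Significant metrics are
normalized by a robust Z-score,

    z_i = (X_i - X_m) / NIQR,

where X_m is the cohort median and NIQR the normalized interquartile range
(IQR x 0.7413, the scaling that makes NIQR estimate one standard deviation
under normality), and fed to a principal component analysis whose first
component acts as a one-dimensional competency score.

The scaling and PCA steps are sklearn-compatible estimators
(:class:`RobustZScaler`, :class:`SignificanceGatedPCA`) so they compose with
``sklearn.pipeline`` and model selection; the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    ConstantMetricError,
    InsufficientInputError,
    IntegrityError,
    TrackValidationError,
)

__all__ = [
    "NIQR_FACTOR",
    "RobustScaleParams",
    "CohortResult",
    "assemble_metric_table",
    "kruskal_wallis",
    "mann_whitney_pairwise",
    "robust_z_normalize",
    "RobustZScaler",
    "SignificanceGatedPCA",
    "select_and_project",
]

#: IQR -> standard-deviation-equivalent scale factor (1/1.349) under normality
NIQR_FACTOR = 0.7413

GROUP_ORDER = ("novice", "intermediate", "expert")


@dataclass(frozen=True)
class RobustScaleParams:
    metric_name: str
    median: float
    niqr: float


def assemble_metric_table(records: list[dict]) -> pd.DataFrame:
    """Build the long-format metric table.

    ``records`` are dicts with keys ``participant_id, task, instrument,
    metric, value``; an undefined metric is an explicit ``None``/NaN value,
    never a silent omission or a zero. Duplicate (participant, task,
    instrument, metric) keys raise :class:`IntegrityError`.
    """
    df = pd.DataFrame.from_records(
        records, columns=["participant_id", "task", "instrument", "metric", "value"]
    )
    key = ["participant_id", "task", "instrument", "metric"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise IntegrityError(f"duplicate metric row {first}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def metric_table_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to participants x 'instrument:metric' columns."""
    t = table.copy()
    t["column"] = t["instrument"].astype(str) + ":" + t["metric"].astype(str)
    return t.pivot(index="participant_id", columns="column", values="value")


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Requires >= 2 groups, each nonempty; the chi-square approximation with
    k-1 degrees of freedom needs a total sample of at least 5.
    """
    if len(groups) < 2:
        raise TrackValidationError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise TrackValidationError(f"group {i} is empty")
    if sum(g.size for g in arrays) < 5:
        raise TrackValidationError("total sample too small for chi-square approximation")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all ties: no evidence against the null
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney_pairwise(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the combined sample is small
    (n_a + n_b <= ``exact_max_n``) and there are no ties, the tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise TrackValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    small = a.size + b.size <= exact_max_n and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if small else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def robust_z_normalize(
    values: np.ndarray, metric_name: str = ""
) -> tuple[np.ndarray, RobustScaleParams]:
    """Robust Z-score: (X - median) / NIQR.

    Needs at least 4 finite values (two quartiles must be estimable) and a
    strictly positive NIQR. Returns the z-scores and the fitted location/scale
    for reuse on new participants.
    """
    x = np.asarray(values, float)
    finite = x[np.isfinite(x)]
    if finite.size < 4:
        raise TrackValidationError(
            f"robust Z needs >= 4 values, got {finite.size} for {metric_name!r}"
        )
    med = float(np.median(finite))
    q1, q3 = np.percentile(finite, [25, 75])  # linear-interpolation quartiles
    niqr = float((q3 - q1) * NIQR_FACTOR)
    if niqr <= 0:
        raise ConstantMetricError(f"metric {metric_name!r} has zero NIQR")
    return (x - med) / niqr, RobustScaleParams(metric_name, med, niqr)


class RobustZScaler(BaseEstimator, TransformerMixin):
    """Columnwise robust Z-score transformer: (X - median) / NIQR.

    Drop-in analogue of ``sklearn.preprocessing.RobustScaler`` with the NIQR
    convention fixed to IQR x 0.7413 so that scaled features have unit
    standard deviation under normality.
    """

    def fit(self, X, y=None):
        X = self._to_frame(X)
        params = []
        for col in X.columns:
            _, p = robust_z_normalize(X[col].to_numpy(), str(col))
            params.append(p)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.center_ = np.array([p.median for p in params])
        self.scale_ = np.array([p.niqr for p in params])
        self.params_ = params
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = self._to_frame(X)
        return (X.to_numpy(float) - self.center_) / self.scale_

    def inverse_transform(self, Z):
        check_is_fitted(self, "scale_")
        return np.asarray(Z, float) * self.scale_ + self.center_

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.atleast_2d(np.asarray(X, float)))


@dataclass
class CohortResult:
    """Outputs of the cohort-comparison layer."""

    kw_p: pd.Series  # per-metric Kruskal-Wallis p
    pairwise_p: pd.DataFrame  # significant metrics x {N-E, I-E, N-I}
    selected_metrics: list[str]
    scale_params: list[RobustScaleParams]
    loadings: pd.DataFrame  # metric x PC weights, orthonormal columns
    scores: pd.DataFrame  # participant x PC
    var_explained: np.ndarray  # fraction per component, sums to 1


class SignificanceGatedPCA(BaseEstimator, TransformerMixin):
    """PCA restricted to metrics that separate the experience groups.

    ``fit(X, y)`` takes a participants x metrics frame and group labels,
    keeps the metrics whose Kruskal-Wallis p-value across groups is below
    ``alpha`` (minus explicit ``exclusions``, e.g. metrics with a non-monotone
    group trend), robust-Z-normalizes them, and eigendecomposes the covariance
    of the normalized matrix. Component signs are fixed so the mean expert
    score on PC1 is nonnegative (experts plot to the right).

    Fitted attributes: ``kw_pvalues_``, ``selected_metrics_``, ``scaler_``,
    ``loadings_`` (orthonormal columns), ``explained_variance_ratio_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        exclusions: tuple[str, ...] = (),
        group_order: tuple[str, ...] = GROUP_ORDER,
    ):
        self.alpha = alpha
        self.exclusions = exclusions
        self.group_order = group_order

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise TrackValidationError("group labels are required to gate the PCA")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != X.shape[0]:
            raise TrackValidationError("labels and rows misaligned")
        self.kw_pvalues_ = pd.Series(
            {
                col: kruskal_wallis(
                    *[
                        X.loc[y == g, col].dropna().to_numpy()
                        for g in self.group_order
                    ]
                )[1]
                for col in X.columns
            }
        )
        selected = [
            c
            for c in X.columns
            if self.kw_pvalues_[c] < self.alpha and c not in self.exclusions
        ]
        dropped = []
        for c in list(selected):
            col = X[c]
            if not np.isfinite(col.to_numpy(float)).all():
                raise TrackValidationError(f"metric {c!r} has missing values")
            try:
                robust_z_normalize(col.to_numpy(float), str(c))
            except ConstantMetricError:
                warnings.warn(f"dropping constant metric {c!r} (zero NIQR)")
                dropped.append(c)
                selected.remove(c)
        if len(selected) < 2:
            raise InsufficientInputError(
                f"only {len(selected)} metrics significant at alpha={self.alpha}"
            )
        self.selected_metrics_ = selected
        self.scaler_ = RobustZScaler().fit(X[selected])
        Z = self.scaler_.transform(X[selected])
        cov = np.cov(Z, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
        scores = Z @ evecs
        # sign convention: experts score nonnegative on each component mean>=0 for PC1
        expert = y == self.group_order[-1]
        if expert.any():
            flip = np.where(scores[expert].mean(axis=0) < 0, -1.0, 1.0)
        else:
            flip = np.where(evecs[0] < 0, -1.0, 1.0)
        evecs = evecs * flip
        self.loadings_ = pd.DataFrame(
            evecs,
            index=selected,
            columns=[f"PC{i + 1}" for i in range(evecs.shape[1])],
        )
        total = evals.sum()
        self.explained_variance_ = evals
        self.explained_variance_ratio_ = evals / total if total > 0 else evals
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.selected_metrics_]
        return self.scaler_.transform(X) @ self.loadings_.to_numpy()


def select_and_project(
    wide: pd.DataFrame,
    groups: pd.Series | dict,
    alpha: float = 0.05,
    exclusions: tuple[str, ...] = (),
) -> CohortResult:
    """Run the full cohort-comparison layer on a wide metric matrix.

    Parameters
    ----------
    wide:
        Participants x metrics frame (index = participant_id).
    groups:
        Participant -> group label (novice/intermediate/expert).
    alpha:
        Kruskal-Wallis significance gate for both pairwise testing and PCA.
    exclusions:
        Metrics withheld from the PCA despite significance (e.g. a metric with
        a V-shaped, non-monotone trend across groups).
    """
    groups = pd.Series(groups).reindex(wide.index)
    if groups.isna().any():
        raise TrackValidationError("every participant needs a group label")
    y = groups.to_numpy(dtype=object)

    pca = SignificanceGatedPCA(alpha=alpha, exclusions=exclusions).fit(wide, y)
    kw_p = pca.kw_pvalues_

    # pairwise tests are gated on KW significance
    pair_labels = {"N-E": ("novice", "expert"), "I-E": ("intermediate", "expert"),
                   "N-I": ("novice", "intermediate")}
    rows = {}
    for metric in kw_p.index[kw_p < alpha]:
        row = {}
        for lab, (ga, gb) in pair_labels.items():
            a = wide.loc[y == ga, metric].dropna().to_numpy()
            b = wide.loc[y == gb, metric].dropna().to_numpy()
            row[lab] = mann_whitney_pairwise(a, b)[1]
        rows[metric] = row
    pairwise = pd.DataFrame.from_dict(rows, orient="index", columns=list(pair_labels))

    scores = pd.DataFrame(
        pca.transform(wide),
        index=wide.index,
        columns=pca.loadings_.columns,
    )
    return CohortResult(
        kw_p=kw_p,
        pairwise_p=pairwise,
        selected_metrics=list(pca.selected_metrics_),
        scale_params=list(pca.scaler_.params_),
        loadings=pca.loadings_,
        scores=scores,
        var_explained=pca.explained_variance_ratio_,
    )
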