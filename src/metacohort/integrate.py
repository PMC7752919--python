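"""Standardization of datasets to a reference cohort and merging.

A designated reference dataset anchors the meta-cohort.  Every other dataset
D is brought onto the reference scale in three steps:

1. quantile normalization of each sample to the reference quantile profile;
2. gene-wise robust standardization: ``x' = (x - m_D) / s_D * s_ref + m_ref``
   where ``m_D``/``s_D`` are the weighted median and weighted MAD of D, and
   ``m_ref``/``s_ref`` the unweighted reference median and raw MAD.  The
   weights are inverse-probability weights from a logistic dataset-affiliation
   model (forward stepwise selection by AIC over gender, age, site, MSI and
   stage), computed as Pd/Pr and truncated at five so no single sample
   dominates;
3. truncation of every value to the min/max observed in the reference.

Datasets are then column-concatenated on their shared gene space, dropping
samples with unknown tumor stage.

RNA-seq datasets enter this stage as ``log2(x + offset)``-transformed,
within-dataset quantile-normalized gene matrices (:func:`prepare_rnaseq`);
microarray datasets arrive already corrected and gene-summarized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import median_abs_deviation
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "weighted_median",
    "weighted_mad",
    "prepare_rnaseq",
    "ReferenceQuantileNormalizer",
    "quantile_normalize_to_reference",
    "StepwiseAffiliationModel",
    "fit_affiliation_model",
    "compute_ipw_weights",
    "ReferenceStandardizer",
    "standardize_to_reference",
    "truncate_to_reference",
    "merge_cohorts",
    "HarmonizedCohort",
]

DEFAULT_WEIGHT_CAP = 5.0
_CANDIDATES = ("gender", "age", "site", "msi", "stage")


# --------------------------------------------------------------- robust stats
def weighted_median(x, w) -> float:
    """Weighted median by the cumulative-weight rule.

    The estimate is the smallest value whose cumulative weight reaches half
    the total; when the cumulative weight hits exactly half, the midpoint
    between that value and the next is returned.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("x and w must be 1-D and aligned")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    half = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, half, side="left"))
    if i + 1 < len(xs) and np.isclose(cw[i], half, rtol=1e-12, atol=0.0):
        return 0.5 * (xs[i] + xs[i + 1])
    return float(xs[i])


def weighted_mad(x, w, center: float | None = None) -> float:
    """Weighted median absolute deviation (no consistency constant)."""
    x = np.asarray(x, dtype=float)
    if center is None:
        center = weighted_median(x, w)
    return weighted_median(np.abs(x - center), w)


# ------------------------------------------------------- quantile normalization
def _map_to_quantiles(x: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Replace a vector's values by reference quantiles at their ranks.

    Tied input values receive the mean of the reference quantiles spanning
    their rank range.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    uniq, inverse, counts = np.unique(xs, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=ref_sorted)
    mapped_sorted = (sums / counts)[inverse]
    out = np.empty_like(x, dtype=float)
    out[order] = mapped_sorted
    return out


class ReferenceQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile-normalize samples to a reference quantile profile.

    ``fit`` learns the reference quantiles as the mean of the sorted
    per-sample value vectors of the reference matrix (samples x features);
    alternatively an explicit quantile vector can be given.  ``transform``
    maps each sample so that its sorted values equal the reference quantiles,
    averaging over ties.  A feature-count mismatch is linearly interpolated
    when ``interpolate=True``, otherwise an error.
    """

    def __init__(self, reference_quantiles=None, interpolate: bool = False):
        self.reference_quantiles = reference_quantiles
        self.interpolate = interpolate

    def fit(self, X: pd.DataFrame | None = None, y=None):
        if self.reference_quantiles is not None:
            q = np.asarray(self.reference_quantiles, dtype=float)
        else:
            if X is None:
                raise ValueError("either X or reference_quantiles is required")
            arr = np.asarray(X, dtype=float)
            q = np.sort(arr, axis=1).mean(axis=0)
        if not np.all(np.isfinite(q)):
            raise ValueError("reference quantiles must be finite")
        self.reference_quantiles_ = np.sort(q)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_quantiles_")
        arr = np.asarray(X, dtype=float)
        q = self.reference_quantiles_
        if arr.shape[1] != len(q):
            if not self.interpolate:
                raise ValueError(
                    f"feature count {arr.shape[1]} does not match reference "
                    f"quantile length {len(q)}; enable interpolate"
                )
            grid_ref = np.linspace(0.0, 1.0, len(q))
            grid_new = np.linspace(0.0, 1.0, arr.shape[1])
            q = np.interp(grid_new, grid_ref, q)
        out = np.vstack([_map_to_quantiles(row, q) for row in arr])
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def quantile_normalize_to_reference(
    matrix: pd.DataFrame,
    reference_quantiles,
    interpolate: bool = False,
) -> pd.DataFrame:
    """Quantile-normalize a feature x sample matrix to a reference profile."""
    est = ReferenceQuantileNormalizer(
        reference_quantiles=reference_quantiles, interpolate=interpolate
    )
    return est.fit().transform(matrix.T).T


def prepare_rnaseq(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2-transform non-negative expression estimates and quantile-normalize
    within the dataset (feature x sample orientation)."""
    arr = matrix.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression estimates must be non-negative")
    logged = np.log2(arr + offset)
    ref = np.sort(logged, axis=0).mean(axis=1)
    out = np.column_stack(
        [_map_to_quantiles(logged[:, j], ref) for j in range(logged.shape[1])]
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# --------------------------------------------------------- affiliation weights
class StepwiseAffiliationModel(BaseEstimator):
    """Logistic dataset-affiliation model with forward stepwise AIC selection.

    Fit on the pooled samples of a dataset D and the reference, with the
    binary label ``y = 1`` for membership in D.  Starting from the
    intercept-only model, the candidate covariate whose addition lowers the
    AIC the most is added, until no addition improves it.  Candidates hit by
    complete separation are skipped with a warning.
    """

    def __init__(self, candidates: tuple[str, ...] = _CANDIDATES):
        self.candidates = candidates

    def _blocks(self, clin: pd.DataFrame) -> dict[str, pd.DataFrame]:
        blocks = {}
        for cand in self.candidates:
            if cand not in clin.columns:
                raise ValueError(f"candidate covariate {cand!r} missing")
            col = clin[cand]
            if pd.api.types.is_numeric_dtype(col):
                blocks[cand] = col.to_frame(cand).astype(float)
            else:
                blocks[cand] = pd.get_dummies(
                    col.astype(str), prefix=cand, drop_first=True, dtype=float
                )
        return blocks

    def fit(self, clin: pd.DataFrame, y) -> "StepwiseAffiliationModel":
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary dataset-affiliation labels")
        blocks = self._blocks(clin)
        self._fit_columns_: dict[str, list[str]] = {
            k: list(v.columns) for k, v in blocks.items()
        }

        def _fit_logit(cols: list[str]):
            Xd = (
                pd.concat([blocks[c] for c in cols], axis=1)
                if cols
                else pd.DataFrame(index=clin.index)
            )
            Xd = sm.add_constant(Xd.to_numpy(dtype=float), has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise np.linalg.LinAlgError("non-finite estimates")
            return res

        selected: list[str] = []
        skipped: list[str] = []
        current = _fit_logit(selected)
        trace = [{"step": 0, "added": None, "aic": float(current.aic)}]
        remaining = list(self.candidates)
        step = 0
        while remaining:
            best = None
            for cand in list(remaining):
                try:
                    res = _fit_logit(selected + [cand])
                except Exception:
                    warnings.warn(
                        f"covariate {cand!r} dropped from stepwise selection "
                        "(separation or singular fit)",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    remaining.remove(cand)
                    skipped.append(cand)
                    continue
                if best is None or res.aic < best[1].aic:
                    best = (cand, res)
            if best is None or best[1].aic >= current.aic:
                break
            step += 1
            selected.append(best[0])
            remaining.remove(best[0])
            current = best[1]
            trace.append({"step": step, "added": best[0], "aic": float(current.aic)})

        self.selected_covariates_ = selected
        self.skipped_covariates_ = skipped
        self.trace_ = trace
        self.result_ = current
        self._train_index_ = clin.index
        return self

    def predict_proba(self, clin: pd.DataFrame) -> np.ndarray:
        """Probability of affiliation to dataset D (label 1) per sample."""
        check_is_fitted(self, "result_")
        blocks = self._blocks(clin)
        if self.selected_covariates_:
            parts = []
            for c in self.selected_covariates_:
                b = blocks[c].reindex(columns=self._fit_columns_[c], fill_value=0.0)
                parts.append(b)
            Xd = pd.concat(parts, axis=1).to_numpy(dtype=float)
        else:
            Xd = np.empty((len(clin), 0))
        Xd = sm.add_constant(Xd, has_constant="add")
        return np.asarray(self.result_.predict(Xd), dtype=float)


def fit_affiliation_model(
    clin_D: pd.DataFrame,
    clin_ref: pd.DataFrame,
    candidates: tuple[str, ...] = _CANDIDATES,
) -> StepwiseAffiliationModel:
    """Fit the affiliation model for dataset D vs the reference cohort."""
    pooled = pd.concat([clin_D, clin_ref])
    y = np.concatenate([np.ones(len(clin_D)), np.zeros(len(clin_ref))])
    return StepwiseAffiliationModel(candidates=candidates).fit(pooled, y)


def compute_ipw_weights(
    model: StepwiseAffiliationModel,
    clin_D: pd.DataFrame,
    w_max: float = DEFAULT_WEIGHT_CAP,
    direction: str = "pd_over_pr",
) -> pd.Series:
    """Per-sample inverse-probability weights, truncated at ``w_max``.

    ``direction="pd_over_pr"`` follows the ratio of the modeled probability
    of belonging to D over that of belonging to the reference;
    ``"pr_over_pd"`` is the conventional reweighting toward the reference
    composition.  The truncation count is stored in ``weights.attrs``.
    """
    pd_prob = model.predict_proba(clin_D)
    pr_prob = 1.0 - pd_prob
    if direction == "pd_over_pr":
        num, den = pd_prob, pr_prob
    elif direction == "pr_over_pd":
        num, den = pr_prob, pd_prob
    else:
        raise ValueError(f"unknown direction {direction!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, np.inf)
    n_den_zero = int(np.sum(den <= 0))
    if n_den_zero:
        logger.warning(
            "%d samples had a numerically zero denominator probability; "
            "weights set to the cap",
            n_den_zero,
        )
    weights = np.minimum(raw, w_max)
    n_truncated = int(np.sum(raw > w_max))
    out = pd.Series(weights, index=clin_D.index, name="ipw_weight")
    out.attrs["n_truncated"] = n_truncated
    out.attrs["w_max"] = w_max
    return out


# ---------------------------------------------------------- standardization
class ReferenceStandardizer(BaseEstimator, TransformerMixin):
    """Gene-wise median/MAD standardization onto a reference cohort.

    ``fit`` records the unweighted median and raw MAD (no consistency
    constant) of every gene in the reference (samples x genes).
    ``transform`` maps dataset D's values gene by gene as
    ``(x - m_D) / s_D * s_ref + m_ref`` where ``m_D``/``s_D`` are the
    weighted median/MAD of D under the supplied sample weights.  Genes with
    zero weighted MAD get a location-only shift (logged).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ReferenceStandardizer":
        arr = np.asarray(X, dtype=float)
        self.ref_median_ = pd.Series(np.median(arr, axis=0), index=X.columns)
        self.ref_mad_ = pd.Series(
            median_abs_deviation(arr, axis=0, scale=1.0), index=X.columns
        )
        return self

    def transform(
        self, X: pd.DataFrame, sample_weight: pd.Series | np.ndarray | None = None
    ) -> pd.DataFrame:
        check_is_fitted(self, "ref_median_")
        genes = X.columns
        missing = genes.difference(self.ref_median_.index)
        if len(missing):
            raise ValueError(f"genes absent from reference: {list(missing[:5])}")
        if sample_weight is None:
            w = np.ones(len(X))
        elif isinstance(sample_weight, pd.Series):
            w = sample_weight.reindex(X.index).to_numpy(dtype=float)
        else:
            w = np.asarray(sample_weight, dtype=float)
        arr = X.to_numpy(dtype=float)
        out = np.empty_like(arr)
        n_degenerate = 0
        for j, g in enumerate(genes):
            x = arr[:, j]
            m_d = weighted_median(x, w)
            s_d = weighted_mad(x, w, center=m_d)
            m_r = float(self.ref_median_[g])
            s_r = float(self.ref_mad_[g])
            if s_d == 0:
                n_degenerate += 1
                out[:, j] = x - m_d + m_r
            else:
                out[:, j] = (x - m_d) / s_d * s_r + m_r
        if n_degenerate:
            logger.warning(
                "%d genes had zero weighted MAD; location-only shift applied",
                n_degenerate,
            )
        return pd.DataFrame(out, index=X.index, columns=genes)


def standardize_to_reference(
    matrix_D: pd.DataFrame,
    weights: pd.Series | np.ndarray | None,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-wise weighted median/MAD standardization (feature x sample)."""
    est = ReferenceStandardizer().fit(reference.T)
    return est.transform(matrix_D.T, sample_weight=weights).T


def truncate_to_reference(
    matrix: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Clip every gene's values to the min/max observed in the reference."""
    missing = matrix.index.difference(reference.index)
    if len(missing):
        raise KeyError(f"genes absent from reference: {list(missing[:5])}")
    ref = reference.loc[matrix.index]
    lo = ref.min(axis=1)
    hi = ref.max(axis=1)
    return matrix.clip(lower=lo, upper=hi, axis=0)


# -------------------------------------------------------------------- merging
@dataclass
class HarmonizedCohort:
    """A merged, reference-standardized gene x sample meta-cohort."""

    matrix: pd.DataFrame  # genes x samples, gene intersection of all datasets
    clinical: pd.DataFrame  # retained samples only
    reference_id: str
    flags: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)

    @property
    def sample_datasets(self) -> pd.Series:
        return self.clinical["dataset_id"]


def merge_cohorts(
    matrices: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    reference_id: str,
    flags: dict | None = None,
) -> HarmonizedCohort:
    """Column-concatenate standardized datasets on their shared gene space.

    Samples with unknown tumor stage are excluded; per-dataset retained and
    dropped counts are logged and kept in ``stage_log``.
    """
    if len(matrices) < 2:
        raise ValueError("merging requires at least two datasets")
    if reference_id not in matrices:
        raise ValueError(f"reference dataset {reference_id!r} not among inputs")

    shared = matrices[reference_id].index
    for ds, mat in matrices.items():
        shared = shared.intersection(mat.index)
    if len(shared) == 0:
        raise ValueError("gene intersection across datasets is empty")
    shared = matrices[reference_id].index[matrices[reference_id].index.isin(shared)]

    all_samples = np.concatenate([m.columns.to_numpy() for m in matrices.values()])
    dup = pd.Index(all_samples).duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate sample ids across datasets: {list(pd.Index(all_samples)[dup][:5])}"
        )

    pieces = []
    log = []
    for ds, mat in matrices.items():
        clin = clinical.loc[mat.columns]
        known = ~(clin["stage"].isna() | (clin["stage"].astype(str) == "unknown"))
        kept = mat.loc[shared, known.to_numpy()]
        log.append(
            {"dataset": ds, "retained": int(known.sum()), "dropped": int((~known).sum())}
        )
        logger.info(
            "dataset %s: %d samples retained, %d with unknown stage dropped",
            ds, int(known.sum()), int((~known).sum()),
        )
        pieces.append(kept)
    merged = pd.concat(pieces, axis=1)
    return HarmonizedCohort(
        matrix=merged,
        clinical=clinical.loc[merged.columns],
        reference_id=reference_id,
        flags=dict(flags or {}),
        stage_log=log,
    )
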