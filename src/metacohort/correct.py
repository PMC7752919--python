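"""Per-feature mixed-effects removal of technical effects.

Each feature (probeset or gene) is modeled separately within a dataset:

* microarray design: fixed effects for center of origin, MSI status and the
  three array-quality metrics (PM.IQR, RMA.IQR, RNA.DEG, mean-centered);
  random intercept for scan batch (scanning day);
* RNA-seq design: fixed effect for center, random intercept for sequencing
  plate.

Variance components are estimated by REML.  If a feature's random-effect fit
fails to converge, the batch variance hits the zero boundary, or there is a
single batch level, the fit falls back to ordinary least squares without the
batch term (flagged per feature).

Correction subtracts the estimated technical component — center effect,
shrunken (BLUP-style) batch prediction and metric slopes times the
mean-centered metrics — after centering that component across samples, so
the grand mean of every feature is preserved exactly.  Biological covariates
(MSI) are estimated to keep them out of the technical terms but are retained
in the corrected values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "MixedEffectsCorrector",
    "FeatureModelFit",
    "fit_feature_models",
    "remove_technical_effects",
]

_METRICS = ["pm_iqr", "rma_iqr", "rna_deg"]


@dataclass
class FeatureModelFit:
    """Estimates for one feature's technical model."""

    feature_id: str
    fixed_effects: dict[str, float]
    random_effects: dict[str, float]  # per batch level, shrunken predictions
    residual_var: float
    batch_var: float
    converged: bool
    fallback: bool  # True when the mixed fit was replaced by OLS


def _sum_coded(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Sum-to-zero (deviation) coding: k-1 columns, last level = -sum of others."""
    levels = sorted(values.astype(str).unique())
    if len(levels) < 2:
        return np.empty((len(values), 0)), [], levels
    cols = np.zeros((len(values), len(levels) - 1))
    arr = values.astype(str).to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (arr == lev).astype(float)
    cols[arr == levels[-1], :] = -1.0
    names = [f"{prefix}[{lev}]" for lev in levels[:-1]]
    return cols, names, levels


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that do not increase the design rank."""
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


class MixedEffectsCorrector(BaseEstimator, TransformerMixin):
    """Estimate and remove technical effects feature by feature.

    Parameters
    ----------
    design : {"microarray", "rnaseq"}
        Which covariate set to use (see module docstring).
    batch_as_fixed : bool
        Model the batch as a fixed effect instead of a random intercept.
    reml : bool
        REML (default) vs ML estimation of the variance components.

    `X` is samples x features (scikit-learn orientation); the clinical table
    is passed to :meth:`fit` aligned on the sample index.
    """

    def __init__(
        self,
        design: str = "microarray",
        batch_as_fixed: bool = False,
        reml: bool = True,
    ):
        self.design = design
        self.batch_as_fixed = batch_as_fixed
        self.reml = reml

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, clinical: pd.DataFrame) -> "MixedEffectsCorrector":
        if self.design not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown design {self.design!r}")
        missing = X.index.difference(clinical.index)
        if len(missing):
            raise ValueError(
                f"clinical rows missing for samples: {', '.join(map(str, missing[:5]))}"
            )
        clin = clinical.loc[X.index]

        batch_col = "scan_batch" if self.design == "microarray" else "plate"
        if batch_col not in clin.columns and "scan_batch" in clin.columns:
            batch_col = "scan_batch"  # simulated RNA-seq reuses the batch column
        design_parts: list[np.ndarray] = [np.ones((len(clin), 1))]
        names: list[str] = ["intercept"]
        tech_cols: list[str] = []  # names whose effects get subtracted

        c_cols, c_names, self.center_levels_ = _sum_coded(clin["center"], "center")
        if c_cols.shape[1] == 0:
            logger.info("single center level; center term dropped")
        design_parts.append(c_cols)
        names += c_names
        tech_cols += c_names

        if self.design == "microarray":
            m_cols, m_names, self.msi_levels_ = _sum_coded(clin["msi"], "msi")
            design_parts.append(m_cols)
            names += m_names  # biological: estimated but NOT subtracted
            metric_means = clin[_METRICS].mean()
            metrics_centered = (clin[_METRICS] - metric_means).to_numpy(dtype=float)
            design_parts.append(metrics_centered)
            names += _METRICS
            tech_cols += _METRICS
            self.metric_means_ = metric_means

        batch = clin[batch_col].astype(str)
        self.batch_levels_ = sorted(batch.unique())
        if self.batch_as_fixed:
            b_cols, b_names, _ = _sum_coded(batch, "batch")
            design_parts.append(b_cols)
            names += b_names
            tech_cols += b_names

        Xd = np.hstack(design_parts)
        Xd, names, dropped = _drop_aliased(Xd, names)
        if dropped:
            logger.info("dropped aliased design columns: %s", dropped)
        tech_cols = [n for n in tech_cols if n in names]

        self.design_matrix_ = Xd
        self.design_names_ = names
        self.tech_names_ = tech_cols
        self.batch_ = batch
        use_random = not self.batch_as_fixed and len(self.batch_levels_) > 1

        Y = X.to_numpy(dtype=float)
        fits: list[FeatureModelFit] = []
        n_fallback = 0
        for j, fid in enumerate(X.columns):
            fit = self._fit_one(str(fid), Y[:, j], Xd, names, batch, use_random)
            n_fallback += fit.fallback
            fits.append(fit)
        if n_fallback:
            logger.info("OLS fallback used for %d/%d features", n_fallback, len(fits))
        self.fits_ = fits
        self.n_fallback_ = n_fallback
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def _fit_one(
        self,
        fid: str,
        y: np.ndarray,
        Xd: np.ndarray,
        names: list[str],
        batch: pd.Series,
        use_random: bool,
    ) -> FeatureModelFit:
        if use_random:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = sm.MixedLM(y, Xd, groups=batch.to_numpy())
                    res = md.fit(reml=self.reml)
                batch_var = float(np.asarray(res.cov_re)[0, 0])
                if np.isfinite(batch_var) and batch_var > 1e-10 and res.converged:
                    ranef = {
                        str(k): float(np.asarray(v)[0])
                        for k, v in res.random_effects.items()
                    }
                    return FeatureModelFit(
                        feature_id=fid,
                        fixed_effects=dict(zip(names, map(float, res.fe_params))),
                        random_effects=ranef,
                        residual_var=float(res.scale),
                        batch_var=batch_var,
                        converged=bool(res.converged),
                        fallback=False,
                    )
            except (np.linalg.LinAlgError, ValueError):
                pass
        # OLS fallback (or fixed-batch / single-batch design)
        res = sm.OLS(y, Xd).fit()
        return FeatureModelFit(
            feature_id=fid,
            fixed_effects=dict(zip(names, map(float, res.params))),
            random_effects={lev: 0.0 for lev in self.batch_levels_},
            residual_var=float(res.scale),
            batch_var=0.0,
            converged=True,
            fallback=use_random,
        )

    # ------------------------------------------------------------ transform
    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Subtract each feature's estimated technical component.

        Only valid for the samples seen at fit time (batch predictions and
        the design are sample-specific).
        """
        check_is_fitted(self, "fits_")
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("features differ from those seen at fit time")
        if not X.index.equals(self.batch_.index):
            raise ValueError("samples differ from those seen at fit time")

        names = self.design_names_
        tech_idx = [names.index(n) for n in self.tech_names_]
        Xd_tech = self.design_matrix_[:, tech_idx]
        batch_codes = self.batch_.to_numpy()

        out = X.to_numpy(dtype=float).copy()
        for j, fit in enumerate(self.fits_):
            beta_tech = np.array([fit.fixed_effects[n] for n in self.tech_names_])
            tech = Xd_tech @ beta_tech
            tech = tech + np.array([fit.random_effects.get(b, 0.0) for b in batch_codes])
            tech = tech - tech.mean()  # grand mean per feature preserved exactly
            out[:, j] -= tech
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def fit_summary(self) -> pd.DataFrame:
        """Per-feature fixed effects, variances and flags as one table."""
        check_is_fitted(self, "fits_")
        rows = []
        for f in self.fits_:
            row = {"feature_id": f.feature_id, **f.fixed_effects}
            row.update(
                residual_var=f.residual_var,
                batch_var=f.batch_var,
                converged=f.converged,
                fallback=f.fallback,
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("feature_id")


def fit_feature_models(
    expr: pd.DataFrame,
    clin: pd.DataFrame,
    design: str = "microarray",
    **kwargs,
) -> MixedEffectsCorrector:
    """Fit per-feature technical models on a feature x sample matrix."""
    est = MixedEffectsCorrector(design=design, **kwargs)
    return est.fit(expr.T, clin)


def remove_technical_effects(
    expr: pd.DataFrame,
    fits: MixedEffectsCorrector,
    clin: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Return the corrected feature x sample matrix."""
    return fits.transform(expr.T).T
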