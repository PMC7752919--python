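"""Probeset-to-gene collapsing by the first principal component.

Multiple microarray probesets can measure the same gene.  Rather than
averaging them, each gene's expression is summarized by the first principal
component of its probesets across samples.  The raw PC score is on an
arbitrary scale and with an arbitrary sign, so two conventions make it
comparable to a plain intensity:

* the score is re-centered and re-scaled to the loading-weighted mean of the
  probesets' means and standard deviations (weights = |first-eigenvector
  loadings| by default);
* the sign is flipped, if needed, so the score correlates positively with
  the probeset contributing most to the component.

Single-probeset genes pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = ["FirstPCGeneSummarizer", "summarize_first_pc"]


def _loading_weights(loadings: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "absolute":
        return np.abs(loadings)
    if weighting == "squared":
        return loadings**2
    if weighting == "signed":
        return loadings
    raise ValueError(f"unknown weighting {weighting!r}")


class FirstPCGeneSummarizer(BaseEstimator, TransformerMixin):
    """Collapse a probeset-level matrix to gene level via first-PC scores.

    Parameters
    ----------
    annotation : DataFrame with columns ``probeset_id`` and ``gene_id``
        Many-to-one mapping; probesets absent from the mapping are dropped
        (a count is logged).
    weighting : {"absolute", "squared", "signed"}
        How eigenvector loadings enter the re-centering/re-scaling weights.
        ``absolute`` is the default; ``signed`` can produce negative weights
        and is provided for sensitivity analyses only.
    use_correlation : bool
        Compute the PC on the correlation matrix (probesets standardized)
        instead of the covariance matrix of mean-centered probesets.

    The estimator follows scikit-learn conventions: `X` is samples x
    probesets; :meth:`transform` returns samples x genes.  ``fit`` learns the
    per-gene eigenvector, the target mean/SD and the canonical sign from the
    training data; ``transform`` projects (new) samples onto them.
    """

    def __init__(
        self,
        annotation: pd.DataFrame | None = None,
        weighting: str = "absolute",
        use_correlation: bool = False,
    ):
        self.annotation = annotation
        self.weighting = weighting
        self.use_correlation = use_correlation

    def fit(self, X: pd.DataFrame, y=None) -> "FirstPCGeneSummarizer":
        if self.annotation is None:
            raise ValueError("annotation mapping is required")
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ValueError("at least 2 samples are required for PCA summarization")

        annot = self.annotation
        if annot["probeset_id"].duplicated().any():
            raise ValueError("a probeset maps to more than one gene")
        mapping = annot.set_index("probeset_id")["gene_id"]
        mapped = [p for p in X.columns if p in mapping.index]
        n_unmapped = X.shape[1] - len(mapped)
        if n_unmapped:
            logger.info("dropping %d unmapped probesets", n_unmapped)
        if not mapped:
            raise ValueError("no probeset in the expression matrix is annotated")

        groups: dict[str, list[str]] = {}
        for p in mapped:  # annotation order fixes tie-breaks
            groups.setdefault(mapping[p], []).append(p)

        self.gene_ids_ = list(groups)
        self.components_: dict[str, dict] = {}
        self.degenerate_genes_: list[str] = []
        for gid, probes in groups.items():
            self.components_[gid] = self._fit_gene(gid, X[probes])
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def _fit_gene(self, gid: str, block: pd.DataFrame) -> dict:
        probes = list(block.columns)
        if len(probes) == 1:
            return {"probes": probes, "passthrough": True}

        vals = block.to_numpy(dtype=float)  # n_samples x p
        means = vals.mean(axis=0)
        sds = vals.std(axis=0, ddof=1)
        centered = vals - means
        if self.use_correlation:
            proj_scale = 1.0 / np.where(sds > 0, sds, 1.0)
        else:
            proj_scale = np.ones_like(sds)
        centered = centered * proj_scale
        cov = np.cov(centered.T, ddof=1)

        if not np.any(np.diag(np.atleast_2d(cov)) > 0):
            # all probesets constant: weighted mean row with equal weights
            self.degenerate_genes_.append(gid)
            warnings.warn(
                f"gene {gid}: probesets have zero total variance; "
                "returning the constant weighted-mean row",
                RuntimeWarning,
                stacklevel=2,
            )
            return {"probes": probes, "degenerate": True, "value": float(means.mean())}

        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        v = evecs[:, -1]  # leading eigenvector
        w = _loading_weights(v, self.weighting)
        wsum = w.sum()
        if wsum == 0:
            w = np.ones_like(w)
            wsum = w.sum()
        target_mean = float(np.dot(w, means) / wsum)
        target_sd = float(np.dot(w, sds) / wsum)

        scores = centered @ v
        top = int(np.argmax(np.abs(v)))  # first probeset wins ties (argmax rule)
        sign = np.sign(np.dot(scores, centered[:, top]))
        if sign < 0:
            v = -v
            scores = -scores
        score_sd = scores.std(ddof=1)
        scale = target_sd / score_sd if score_sd > 0 else 0.0
        return {
            "probes": probes,
            "eigvec": v,
            "probe_means": means,
            "proj_scale": proj_scale,
            "scale": scale,
            "target_mean": target_mean,
            "target_sd": target_sd,
        }

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "components_")
        X = self._validate(X)
        out = {}
        for gid in self.gene_ids_:
            comp = self.components_[gid]
            block = X[comp["probes"]]
            if comp.get("passthrough"):
                out[gid] = block.iloc[:, 0].to_numpy(dtype=float)
            elif comp.get("degenerate"):
                out[gid] = np.full(len(X), comp["value"])
            else:
                centered = (
                    block.to_numpy(dtype=float) - comp["probe_means"]
                ) * comp["proj_scale"]
                scores = centered @ comp["eigvec"]
                out[gid] = scores * comp["scale"] + comp["target_mean"]
        return pd.DataFrame(out, index=X.index)

    @staticmethod
    def _validate(X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame (samples x probesets)")
        if X.isna().any().any() or not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError(
                "expression matrix contains missing or non-finite values; "
                "impute or filter before summarization"
            )
        return X


def summarize_first_pc(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    weighting: str = "absolute",
    use_correlation: bool = False,
) -> pd.DataFrame:
    """Collapse a probeset x sample matrix to gene x sample.

    Thin wrapper over :class:`FirstPCGeneSummarizer` using the field's
    features-in-rows orientation.
    """
    est = FirstPCGeneSummarizer(
        annotation=annot, weighting=weighting, use_correlation=use_correlation
    )
    gene_by_sample = est.fit_transform(expr.T).T
    gene_by_sample.index.name = "gene_id"
    return gene_by_sample
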