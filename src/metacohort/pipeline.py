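"""End-to-end harmonization: correct -> summarize -> normalize -> standardize
-> truncate -> merge.

The fixed stage order for microarray-style datasets is

1. per-feature mixed-effects technical correction,
2. first-PC probeset-to-gene summarization,
3. quantile normalization of every non-reference dataset to the reference
   quantile profile,
4. IPW-weighted gene-wise median/MAD standardization to the reference,
5. truncation to the reference per-gene range,
6. column-wise merging on the shared gene space (unknown-stage samples
   dropped).

Count-based (RNA-seq) datasets replace stages 1-2 by
``log2 + within-dataset quantile normalization`` (:func:`prepare_rnaseq`)
followed by the same correction model at gene level; in the synthetic runs
all datasets are microarray-style.  Per-stage sample/feature counts are
logged and collected into the returned cohort's ``stage_log``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from metacohort.correct import MixedEffectsCorrector
from metacohort.integrate import (
    HarmonizedCohort,
    compute_ipw_weights,
    fit_affiliation_model,
    merge_cohorts,
    quantile_normalize_to_reference,
    standardize_to_reference,
    truncate_to_reference,
)
from metacohort.summarize import summarize_first_pc

logger = logging.getLogger(__name__)

__all__ = ["harmonize"]


def harmonize(
    expression: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_id: str,
    design: str = "microarray",
    weight_direction: str = "pd_over_pr",
    correct: bool = True,
) -> HarmonizedCohort:
    """Run the full harmonization pipeline on per-dataset probeset matrices.

    Returns a :class:`HarmonizedCohort` whose ``stage_log`` records per-stage
    counts and the per-dataset IPW selection traces.
    """
    if reference_id not in expression:
        raise ValueError(f"reference dataset {reference_id!r} not among inputs")

    stage_log: list[dict] = []
    gene_level: dict[str, pd.DataFrame] = {}
    for ds_id, mat in expression.items():
        clin = clinical.loc[mat.columns]
        if correct:
            corrector = MixedEffectsCorrector(design=design).fit(mat.T, clin)
            corrected = corrector.transform(mat.T).T
            n_fb = corrector.n_fallback_
        else:
            corrected, n_fb = mat, 0
        genes = summarize_first_pc(corrected, annotation)
        stage_log.append(
            {
                "stage": "correct+summarize",
                "dataset": ds_id,
                "n_samples": mat.shape[1],
                "n_probesets": mat.shape[0],
                "n_genes": genes.shape[0],
                "n_ols_fallback": n_fb,
            }
        )
        logger.info(
            "dataset %s: corrected %d probesets, summarized to %d genes "
            "(%d OLS fallbacks)",
            ds_id, mat.shape[0], genes.shape[0], n_fb,
        )
        gene_level[ds_id] = genes

    reference = gene_level[reference_id]
    # reference quantile profile: mean of the sorted per-sample gene vectors
    ref_profile = np.sort(reference.to_numpy().T, axis=1).mean(axis=0)

    standardized: dict[str, pd.DataFrame] = {reference_id: reference}
    ref_clin = clinical.loc[reference.columns]
    for ds_id, genes in gene_level.items():
        if ds_id == reference_id:
            continue
        genes = genes.loc[reference.index.intersection(genes.index)]
        qn = quantile_normalize_to_reference(genes, ref_profile)
        clin_d = clinical.loc[qn.columns]
        model = fit_affiliation_model(clin_d, ref_clin)
        weights = compute_ipw_weights(model, clin_d, direction=weight_direction)
        std = standardize_to_reference(qn, weights, reference.loc[qn.index])
        trunc = truncate_to_reference(std, reference.loc[qn.index])
        standardized[ds_id] = trunc
        stage_log.append(
            {
                "stage": "integrate",
                "dataset": ds_id,
                "n_samples": qn.shape[1],
                "selected_covariates": model.selected_covariates_,
                "aic_trace": model.trace_,
                "n_weights_truncated": weights.attrs["n_truncated"],
            }
        )
        logger.info(
            "dataset %s: standardized to %s with covariates %s "
            "(%d weights truncated)",
            ds_id, reference_id, model.selected_covariates_,
            weights.attrs["n_truncated"],
        )

    cohort = merge_cohorts(
        standardized,
        clinical,
        reference_id,
        flags={
            "corrected": correct,
            "quantile_normalized": True,
            "standardized": True,
            "truncated": True,
            "weight_direction": weight_direction,
        },
    )
    cohort.stage_log = stage_log + cohort.stage_log
    return cohort
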