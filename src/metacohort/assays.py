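"""Relative-quantification calculators for qRT-PCR and ChIP-qPCR.

Both assume perfect amplification efficiency (one cycle = a factor of two).

* delta-delta-Ct: per sample, the target gene's Ct is referenced to an
  endogenous control (``dCt = Ct_target - Ct_reference``) in the treated and
  control conditions; the fold change is ``2^-(dCt_treated - dCt_control)``.
  Duplicate wells are averaged in Ct space before any differencing.
* percent input: ChIP enrichment relative to the input chromatin,
  ``%input = 100 * 2^((Ct_input - log2(1/f)) - Ct_IP)`` where ``f`` is the
  fraction of chromatin the input aliquot represents (the ``-log2(1/f)``
  term corrects the input Ct for its dilution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ddct_fold_change", "chip_percent_input"]

_CT_COLUMNS = {"sample", "gene", "condition", "ct"}


def _mean_ct(ct: pd.DataFrame, sample, gene, condition) -> float:
    rows = ct[
        (ct["sample"] == sample) & (ct["gene"] == gene) & (ct["condition"] == condition)
    ]
    if rows.empty:
        raise ValueError(
            f"no Ct wells for sample={sample!r}, gene={gene!r}, condition={condition!r}"
        )
    vals = rows["ct"].astype(float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite Ct for sample={sample!r}, gene={gene!r}")
    return float(vals.mean())


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    treated: str,
    control: str,
) -> pd.Series:
    """Per-sample fold change of the target gene by the delta-delta-Ct method.

    ``ct`` is a long-format well table with columns ``sample``, ``gene``,
    ``condition``, ``ct`` (and optionally ``replicate``); duplicate wells of
    the same (sample, gene, condition) are averaged before differencing.
    """
    missing = _CT_COLUMNS - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    folds = {}
    for sample in pd.unique(ct["sample"]):
        dct_treated = _mean_ct(ct, sample, target_gene, treated) - _mean_ct(
            ct, sample, reference_gene, treated
        )
        dct_control = _mean_ct(ct, sample, target_gene, control) - _mean_ct(
            ct, sample, reference_gene, control
        )
        folds[sample] = 2.0 ** -(dct_treated - dct_control)
    return pd.Series(folds, name="fold_change")


def chip_percent_input(ct_ip, ct_input, input_fraction: float) -> float | np.ndarray:
    """ChIP-qPCR enrichment as percent of (dilution-adjusted) input.

    ``input_fraction`` is the fraction of total chromatin the input aliquot
    represents (e.g. 0.1 for a 10% input); the input Ct is shifted down by
    ``log2(1/input_fraction)`` to the scale of the full chromatin amount.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    adjusted_input = ct_input - np.log2(1.0 / input_fraction)
    result = 100.0 * 2.0 ** (adjusted_input - ct_ip)
    if result.ndim == 0:
        return float(result)
    return result
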