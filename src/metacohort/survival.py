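"""Expression-tertile association with survival endpoints and tumor stage.

Samples are split at the tertiles of a gene's expression distribution into
low / medium / high groups (low = reference).  Association is then measured
endpoint by endpoint:

* relapse and overall survival: Cox proportional-hazards model on the two
  group indicators, overall significance by likelihood-ratio test against
  the null model, pairwise Wald tests, hazard ratios with 95% Wald CIs, and
  Kaplan-Meier curves per group for visualization;
* tumor stage: a linear model of expression on the stage factor with an
  overall F-test, per-stage adjusted means with 95% CIs and pairwise Wald
  comparisons.

Endpoint-specific sample selection: time-to-relapse analyses use only
patients diagnosed at stage I-III; overall survival is analyzed separately
in pre-metastatic (I-III) and metastatic (IV) strata; samples with unknown
stage are excluded; rectum samples of designated datasets can be excluded
from outcome analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "EmptyCohortError",
    "DegenerateDistributionError",
    "TertileGroups",
    "AssociationResult",
    "select_endpoint_samples",
    "tertile_groups",
    "CoxTertileAssociation",
    "StageLinearAssociation",
    "cox_tertile_association",
    "stage_linear_association",
    "km_estimate",
]

_LEVELS = ["low", "medium", "high"]
ENDPOINTS = ("relapse", "os_premet", "os_met", "stage")


class EmptyCohortError(ValueError):
    """Raised when endpoint-specific filtering leaves no samples."""


class DegenerateDistributionError(ValueError):
    """Raised when expression values cannot be split into tertiles."""


@dataclass
class TertileGroups:
    """Low/medium/high assignment by expression tertiles."""

    labels: pd.Series  # categorical with levels low < medium < high
    cuts: tuple[float, float]  # 33.3% and 66.7% quantiles

    @property
    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(_LEVELS, fill_value=0)


@dataclass
class AssociationResult:
    """Association estimates for one endpoint."""

    endpoint: str
    n_per_group: dict[str, int]
    overall_stat: float
    overall_p: float
    hazard_ratios: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pairwise_p: dict[str, float] = field(default_factory=dict)
    adjusted_means: pd.DataFrame | None = None
    km: dict[str, pd.DataFrame] | None = None
    warnings: list[str] = field(default_factory=list)


def select_endpoint_samples(
    clin: pd.DataFrame,
    endpoint: str,
    exclude_rectum_datasets: tuple[str, ...] = (),
) -> pd.Index:
    """Return the sample ids eligible for an endpoint-specific analysis."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    stage = clin["stage"].astype(str)
    known = ~clin["stage"].isna() & (stage != "unknown")
    if endpoint in ("relapse", "os_premet"):
        mask = known & stage.isin(["I", "II", "III"])
    elif endpoint == "os_met":
        mask = known & (stage == "IV")
    else:
        mask = known
    if endpoint == "relapse":
        mask &= clin["relapse_time"].notna() & clin["relapse_event"].notna()
    elif endpoint in ("os_premet", "os_met"):
        mask &= clin["os_time"].notna() & clin["os_event"].notna()
    if exclude_rectum_datasets and endpoint != "stage":
        rectum = (clin["site"].astype(str) == "rectum") & clin["dataset_id"].isin(
            exclude_rectum_datasets
        )
        mask &= ~rectum
    selected = clin.index[mask]
    if len(selected) == 0:
        raise EmptyCohortError(f"no samples eligible for endpoint {endpoint!r}")
    return selected


def tertile_groups(values: pd.Series | np.ndarray) -> TertileGroups:
    """Split expression values into low/medium/high tertile groups.

    Assignment is rank-based; ties spanning a cut point are all assigned to
    the lower group (minimum-rank rule), so tied samples never straddle a
    boundary.
    """
    vals = pd.Series(values).astype(float)
    if vals.isna().any():
        raise ValueError("expression values contain missing entries")
    if vals.nunique() < 3:
        raise DegenerateDistributionError(
            "need at least 3 distinct expression values to form tertiles"
        )
    n = len(vals)
    ranks = stats.rankdata(vals.to_numpy(), method="min")
    labels = np.where(ranks <= n / 3, "low", np.where(ranks <= 2 * n / 3, "medium", "high"))
    cat = pd.Series(
        pd.Categorical(labels, categories=_LEVELS, ordered=True), index=vals.index
    )
    cuts = tuple(np.quantile(vals.to_numpy(), [1 / 3, 2 / 3]))
    return TertileGroups(labels=cat, cuts=cuts)


def _group_labels(groups) -> pd.Series:
    if isinstance(groups, TertileGroups):
        return groups.labels
    return pd.Series(groups)


class CoxTertileAssociation(BaseEstimator):
    """Cox proportional-hazards association of tertile groups with survival.

    Fits a partial-likelihood model with indicators for the medium and high
    groups (low = reference).  Ties are handled by the Breslow approximation
    by default (``ties="efron"`` available).  Overall significance is a
    likelihood-ratio test of the two-indicator model against the null;
    pairwise group contrasts use Wald z-tests.
    """

    def __init__(self, ties: str = "breslow", alpha: float = 0.05):
        self.ties = ties
        self.alpha = alpha

    def fit(self, time, event, groups) -> "CoxTertileAssociation":
        labels = _group_labels(groups)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if np.sum(event) < 1:
            raise ValueError("no events observed; Cox model cannot be fitted")
        if not (labels == "low").any():
            raise ValueError("reference (low) group is empty")

        exog = np.column_stack(
            [(labels == "medium").astype(float), (labels == "high").astype(float)]
        )
        model = PHReg(time, exog, status=event, ties=self.ties)
        res = model.fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.diag(cov))

        ll_full = float(model.loglike(params))
        ll_null = float(model.loglike(np.zeros_like(params)))
        lrt = 2.0 * (ll_full - ll_null)
        self.lrt_statistic_ = lrt
        self.lrt_pvalue_ = float(stats.chi2.sf(lrt, df=2))

        z = stats.norm.ppf(1 - self.alpha / 2)
        self.params_ = params
        self.cov_ = cov
        self.hazard_ratios_ = {
            "medium_vs_low": (
                float(np.exp(params[0])),
                float(np.exp(params[0] - z * se[0])),
                float(np.exp(params[0] + z * se[0])),
            ),
            "high_vs_low": (
                float(np.exp(params[1])),
                float(np.exp(params[1] - z * se[1])),
                float(np.exp(params[1] + z * se[1])),
            ),
        }
        se_hm = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        self.wald_pvalues_ = {
            "medium_vs_low": float(2 * stats.norm.sf(abs(params[0] / se[0]))),
            "high_vs_low": float(2 * stats.norm.sf(abs(params[1] / se[1]))),
            "high_vs_medium": float(
                2 * stats.norm.sf(abs((params[1] - params[0]) / se_hm))
            ),
        }

        notes = []
        ev = pd.Series(event).groupby(labels.to_numpy(), observed=False).agg(["sum", "count"])
        for lev in _LEVELS:
            if lev in ev.index and ev.loc[lev, "count"] > 0:
                s, c = ev.loc[lev, "sum"], ev.loc[lev, "count"]
                if s == 0 or s == c:
                    msg = (
                        f"group {lev!r} has {'no' if s == 0 else 'only'} events; "
                        "monotone partial likelihood, estimates unreliable"
                    )
                    notes.append(msg)
                    warnings.warn(msg, RuntimeWarning, stacklevel=2)
        self.warnings_ = notes
        self.n_per_group_ = {
            lev: int((labels == lev).sum()) for lev in _LEVELS
        }
        return self

    def to_result(self, endpoint: str, km: dict | None = None) -> AssociationResult:
        check_is_fitted(self, "params_")
        return AssociationResult(
            endpoint=endpoint,
            n_per_group=self.n_per_group_,
            overall_stat=self.lrt_statistic_,
            overall_p=self.lrt_pvalue_,
            hazard_ratios=self.hazard_ratios_,
            pairwise_p=self.wald_pvalues_,
            km=km,
            warnings=list(self.warnings_),
        )


class StageLinearAssociation(BaseEstimator):
    """Linear model of expression across tumor stages.

    OLS of expression on the stage factor; overall F-test; per-stage
    adjusted means with 95% CIs (equal to the sample means when no further
    covariates are modeled) and pairwise Wald comparisons.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, expression, stage) -> "StageLinearAssociation":
        import statsmodels.api as sm

        y = np.asarray(expression, dtype=float)
        stage = pd.Series(stage).astype(str).to_numpy()
        levels = [s for s in ["I", "II", "III", "IV"] if s in set(stage)]
        if not levels:
            levels = sorted(set(stage))
        if len(levels) < 2:
            raise ValueError("at least two stage levels are required")
        counts = pd.Series(stage).value_counts()
        if (counts.reindex(levels) < 2).any():
            raise ValueError("each stage level needs at least 2 samples")

        dummies = np.column_stack([(stage == lev).astype(float) for lev in levels[1:]])
        X = sm.add_constant(dummies, has_constant="add")
        res = sm.OLS(y, X).fit()
        self.result_ = res
        if np.ptp(y) == 0:  # constant expression: no between- or within-group SS
            self.f_statistic_, self.f_pvalue_ = 0.0, 1.0
        else:
            self.f_statistic_ = float(res.fvalue)
            self.f_pvalue_ = float(res.f_pvalue)
        self.stage_levels_ = levels

        rows = []
        k = len(levels)
        for i, lev in enumerate(levels):
            L = np.zeros(k)
            L[0] = 1.0
            if i > 0:
                L[i] = 1.0
            t = res.t_test(L)
            lo, hi = np.ravel(t.conf_int(alpha=self.alpha))
            rows.append(
                {"stage": lev, "mean": float(np.ravel(t.effect)[0]),
                 "ci_low": float(lo), "ci_high": float(hi),
                 "n": int(counts[lev])}
            )
        self.adjusted_means_ = pd.DataFrame(rows).set_index("stage")

        pairwise = {}
        for i in range(k):
            for j in range(i + 1, k):
                L = np.zeros(k)
                if i > 0:
                    L[i] = -1.0
                if j > 0:
                    L[j] = 1.0
                if i == 0:
                    pass  # reference level: contrast is just the j-th dummy
                t = res.t_test(L)
                pairwise[f"{levels[j]}_vs_{levels[i]}"] = float(np.ravel(t.pvalue)[0])
        self.pairwise_pvalues_ = pairwise
        return self

    def to_result(self) -> AssociationResult:
        check_is_fitted(self, "result_")
        return AssociationResult(
            endpoint="stage",
            n_per_group=self.adjusted_means_["n"].to_dict(),
            overall_stat=self.f_statistic_,
            overall_p=self.f_pvalue_,
            adjusted_means=self.adjusted_means_,
            pairwise_p=self.pairwise_pvalues_,
        )


def cox_tertile_association(
    time, event, groups, ties: str = "breslow", endpoint: str = "survival"
) -> AssociationResult:
    """Fit the tertile Cox model and return the association summary
    (including per-group Kaplan-Meier curves)."""
    est = CoxTertileAssociation(ties=ties).fit(time, event, groups)
    km = km_estimate(time, event, groups)
    return est.to_result(endpoint, km=km)


def stage_linear_association(expression, stage) -> AssociationResult:
    """Fit the stage linear model and return the association summary."""
    return StageLinearAssociation().fit(expression, stage).to_result()


def km_estimate(time, event, groups) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group.

    Returns, per non-empty group, a table of event/censoring times with the
    number at risk, observed events and the survival estimate.  S(0) = 1 and
    the curve is non-increasing; right-censored subjects leave the risk set
    without an event.
    """
    labels = _group_labels(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    out: dict[str, pd.DataFrame] = {}
    if isinstance(labels.dtype, pd.CategoricalDtype):
        expected = list(labels.cat.categories)
    else:
        expected = list(pd.unique(labels))
    present = [lev for lev in expected if (labels == lev).any()]
    for lev in set(expected) - set(present):
        warnings.warn(f"group {lev!r} is empty; omitted", RuntimeWarning, stacklevel=2)
    for lev in present:
        mask = (labels == lev).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        table = kmf.event_table.copy()
        surv = kmf.survival_function_["KM_estimate"]
        out[str(lev)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
                "events": table["observed"].to_numpy(dtype=int),
                "censored": table["censored"].to_numpy(dtype=int),
                "survival": surv.reindex(table.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out
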