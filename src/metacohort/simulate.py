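"""Synthetic multi-dataset expression cohorts with known ground truth.

Emulates the structure of a real expression meta-cohort: several datasets
measured at probeset level, each with its own centers of origin, scan
batches, array-quality metrics, clinical composition and survival follow-up.
Every nuisance effect is drawn from a known distribution and returned in a
:class:`GroundTruth` object so that downstream correction, summarization and
association stages can be validated against the truth.

Generative model per probeset ``p`` (mapping to gene ``g``) and sample ``i``::

    y_pi = intercept_p + loading_p * signal_gi + center_offset[c(i)]
           + batch_offset[b(i)] + slopes_p . metrics_i + eps_pi

with ``signal_gi = mu_g + N(0, gene_signal_sd) (+ msi_effect_size if sample
is MSI and g is an MSI-responsive gene)`` and ``eps ~ N(0, noise_sd)``.

Survival times follow an exponential hazard
``baseline_hazard * exp(cox_log_hr * z_i)`` where ``z_i`` is the target
gene's signal standardized by its true mean and SD, with administrative
(type-I) censoring at ``censor_time``.  The event probability for a constant
hazard ``h`` is therefore ``1 - exp(-h * censor_time)`` in closed form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "generate_meta_cohort",
    "default_covariate_shift",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent simulation settings."""


def default_covariate_shift(n_datasets: int) -> list[dict]:
    """Per-dataset clinical composition tables with mild, deterministic shifts.

    Dataset 0 (the designated reference in synthetic runs) gets a balanced
    composition; later datasets drift in gender/site/MSI prevalence, stage mix
    and mean age, so that the affiliation model has real signal to select.
    """
    shifts = []
    for d in range(n_datasets):
        t = d / max(n_datasets - 1, 1)
        p_m = min(0.45 + 0.25 * t, 0.9)
        p_rectum = min(0.20 + 0.25 * t, 0.9)
        p_msi = min(0.12 + 0.18 * t, 0.9)
        # ordinal stage I-IV plus a small unknown fraction
        stage_w = np.array([0.18 + 0.1 * t, 0.32, 0.30 - 0.05 * t, 0.15 - 0.05 * t])
        stage_w = stage_w / stage_w.sum() * 0.95
        shifts.append(
            {
                "gender": {"M": p_m, "F": 1.0 - p_m},
                "site": {"colon": 1.0 - p_rectum, "rectum": p_rectum},
                "msi": {"MSI": p_msi, "MSS": 1.0 - p_msi},
                "stage": {
                    "I": stage_w[0],
                    "II": stage_w[1],
                    "III": stage_w[2],
                    "IV": stage_w[3],
                    "unknown": 0.05,
                },
                "age_mean": 66.0 + 4.0 * t,
                "age_sd": 10.0,
            }
        )
    return shifts


@dataclass
class SimulationConfig:
    """Parameters of the synthetic meta-cohort generator.

    Scales are log2 expression units unless noted.  Hazards are per month.
    """

    n_datasets: int = 4
    samples_per_dataset: int = 120
    n_genes: int = 400
    probesets_per_gene: tuple[int, int] = (1, 4)
    loading_range: tuple[float, float] = (0.5, 1.5)
    probeset_intercept_sd: float = 0.5
    gene_signal_sd: float = 1.0
    center_effect_sd: float = 0.5
    batch_effect_sd: float = 1.0
    n_centers_per_dataset: int = 2
    # ~12 arrays per scanning day for a 120-sample dataset; a coarser batch
    # structure leaves too few levels to estimate the variance component
    n_batches_per_dataset: int = 10
    metric_slope_sd: float = 0.1
    noise_sd: float = 0.3
    msi_effect_genes: float = 0.1
    msi_effect_size: float = 1.0
    target_gene_id: str = "G0001"
    cox_log_hr: float = float(np.log(2.0))
    baseline_hazard: float = 0.02
    censor_time: float = 60.0
    covariate_shift: list[dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_datasets": self.n_datasets,
            "samples_per_dataset": self.samples_per_dataset,
            "n_genes": self.n_genes,
            "n_centers_per_dataset": self.n_centers_per_dataset,
            "n_batches_per_dataset": self.n_batches_per_dataset,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        lo, hi = self.probesets_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"probesets_per_gene must be a valid count range, got {self.probesets_per_gene}"
            )
        for name in ("center_effect_sd", "batch_effect_sd", "metric_slope_sd",
                     "noise_sd", "gene_signal_sd", "probeset_intercept_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.censor_time <= 0:
            raise ConfigurationError("censor_time must be > 0")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be >= 0")
        if not 0.0 <= self.msi_effect_genes <= 1.0:
            raise ConfigurationError("msi_effect_genes must be a fraction in [0, 1]")
        if self.covariate_shift is not None:
            if len(self.covariate_shift) != self.n_datasets:
                raise ConfigurationError(
                    "covariate_shift must provide one table per dataset"
                )
            for d, tab in enumerate(self.covariate_shift):
                for key in ("gender", "site", "msi", "stage"):
                    probs = tab[key]
                    if abs(sum(probs.values()) - 1.0) > 1e-8:
                        raise ConfigurationError(
                            f"covariate_shift[{d}][{key!r}] probabilities must sum to 1"
                        )


@dataclass
class GroundTruth:
    """The nuisance and signal parameters used to generate a cohort."""

    gene_signal: pd.DataFrame  # gene x sample, technical-effect-free
    probeset_loadings: pd.Series  # per probeset
    probeset_intercepts: pd.Series
    center_offsets: dict[str, float]  # per center level, log2 units
    batch_offsets: dict[str, float]  # per batch level, log2 units
    metric_slopes: pd.DataFrame  # probeset x metric
    msi_genes: list[str]
    true_log_hr: float

    def to_json(self) -> str:
        payload = {
            "probeset_loadings": self.probeset_loadings.to_dict(),
            "probeset_intercepts": self.probeset_intercepts.to_dict(),
            "center_offsets": self.center_offsets,
            "batch_offsets": self.batch_offsets,
            "metric_slopes": {
                k: v.to_dict() for k, v in self.metric_slopes.items()
            },
            "msi_genes": self.msi_genes,
            "true_log_hr": self.true_log_hr,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


_METRICS = ["pm_iqr", "rma_iqr", "rna_deg"]
# mild positive correlation between the three array-quality metrics
_METRIC_COV = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.3], [0.3, 0.3, 1.0]])


def _draw_categorical(rng: np.random.Generator, table: dict, n: int) -> np.ndarray:
    levels = list(table.keys())
    probs = np.array([table[k] for k in levels], dtype=float)
    return rng.choice(levels, size=n, p=probs / probs.sum())


def generate_meta_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a multi-dataset probeset-level meta-cohort.

    Returns
    -------
    expression : dict of dataset_id -> DataFrame (probesets x samples), log2 scale
    clinical : DataFrame indexed by sample_id (all datasets stacked)
    annotation : DataFrame with columns probeset_id, gene_id
    truth : GroundTruth

    Draw order is fixed: one root ``SeedSequence`` is spawned into a
    structure stream (gene/probeset architecture, shared across datasets)
    plus one independent stream per dataset, so appending a dataset leaves
    earlier datasets byte-identical (for a fixed ``covariate_shift``; the
    default composition tables themselves depend on ``n_datasets``).
    """
    cfg = config
    shifts = cfg.covariate_shift or default_covariate_shift(cfg.n_datasets)

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_datasets + 1)
    rng_struct = np.random.default_rng(children[0])

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    if cfg.target_gene_id not in gene_ids:
        raise ConfigurationError(
            f"target_gene_id {cfg.target_gene_id!r} not among generated genes"
        )

    # --- shared architecture (structure stream) ---
    lo, hi = cfg.probesets_per_gene
    n_ps_per_gene = rng_struct.integers(lo, hi + 1, size=cfg.n_genes)
    gene_means = rng_struct.uniform(6.0, 12.0, size=cfg.n_genes)

    probeset_ids: list[str] = []
    probeset_gene: list[str] = []
    for g, gid in enumerate(gene_ids):
        for k in range(n_ps_per_gene[g]):
            probeset_ids.append(f"{gid}_ps{k + 1}")
            probeset_gene.append(gid)
    n_ps = len(probeset_ids)
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    ps_gene_idx = np.array([gene_index[g] for g in probeset_gene])

    loadings = rng_struct.uniform(*cfg.loading_range, size=n_ps)
    intercepts = rng_struct.normal(0.0, cfg.probeset_intercept_sd, size=n_ps)
    slopes = rng_struct.normal(0.0, cfg.metric_slope_sd, size=(n_ps, 3))

    n_msi_genes = int(round(cfg.msi_effect_genes * cfg.n_genes))
    eligible = [g for g in gene_ids if g != cfg.target_gene_id]
    msi_genes = list(
        rng_struct.choice(eligible, size=min(n_msi_genes, len(eligible)), replace=False)
    )
    msi_mask = np.isin(gene_ids, msi_genes)

    annotation = pd.DataFrame({"probeset_id": probeset_ids, "gene_id": probeset_gene})

    expression: dict[str, pd.DataFrame] = {}
    clin_frames: list[pd.DataFrame] = []
    signal_frames: list[pd.DataFrame] = []
    center_offsets: dict[str, float] = {}
    batch_offsets: dict[str, float] = {}

    target_mu = gene_means[gene_index[cfg.target_gene_id]]

    for d in range(cfg.n_datasets):
        ds_id = f"DS{d + 1}"
        rng = np.random.default_rng(children[d + 1])
        n = cfg.samples_per_dataset
        sample_ids = [f"{ds_id}_S{i + 1:04d}" for i in range(n)]
        tab = shifts[d]

        # clinical composition (draw order fixed: gender, age, site, msi, stage)
        gender = _draw_categorical(rng, tab["gender"], n)
        age = rng.normal(tab["age_mean"], tab.get("age_sd", 10.0), size=n)
        site = _draw_categorical(rng, tab["site"], n)
        msi = _draw_categorical(rng, tab["msi"], n)
        stage = _draw_categorical(rng, tab["stage"], n)

        centers = [f"{ds_id}_C{j + 1}" for j in range(cfg.n_centers_per_dataset)]
        batches = [f"{ds_id}_B{j + 1}" for j in range(cfg.n_batches_per_dataset)]
        center = rng.choice(centers, size=n)
        batch = rng.choice(batches, size=n)
        c_off = rng.normal(0.0, cfg.center_effect_sd, size=len(centers))
        b_off = rng.normal(0.0, cfg.batch_effect_sd, size=len(batches))
        center_offsets.update(dict(zip(centers, c_off)))
        batch_offsets.update(dict(zip(batches, b_off)))

        metrics = rng.multivariate_normal(np.zeros(3), _METRIC_COV, size=n)

        # biology: gene signal with optional MSI shift
        signal = gene_means[:, None] + rng.normal(
            0.0, cfg.gene_signal_sd, size=(cfg.n_genes, n)
        )
        is_msi = msi == "MSI"
        if is_msi.any() and msi_mask.any():
            signal[np.ix_(msi_mask, is_msi)] += cfg.msi_effect_size

        # technical assembly at probeset level
        c_map = dict(zip(centers, c_off))
        b_map = dict(zip(batches, b_off))
        metric_term = metrics @ slopes.T  # n x n_ps
        base = intercepts[:, None] + loadings[:, None] * signal[ps_gene_idx, :]
        shared = np.array([c_map[c] for c in center]) + np.array(
            [b_map[b] for b in batch]
        )
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_ps, n))
        values = base + shared[None, :] + metric_term.T + noise

        # survival: exponential hazard tied to the target gene's true signal
        z = (signal[gene_index[cfg.target_gene_id], :] - target_mu) / cfg.gene_signal_sd
        rate = cfg.baseline_hazard * np.exp(cfg.cox_log_hr * z)
        with np.errstate(divide="ignore"):
            t_os = rng.exponential(1.0, size=n) / np.where(rate > 0, rate, np.nan)
            t_rel = rng.exponential(1.0, size=n) / np.where(rate > 0, rate, np.nan)
        t_os = np.where(np.isnan(t_os), np.inf, t_os)
        t_rel = np.where(np.isnan(t_rel), np.inf, t_rel)
        os_event = (t_os <= cfg.censor_time).astype(int)
        os_time = np.minimum(t_os, cfg.censor_time)
        rel_event = (t_rel <= cfg.censor_time).astype(float)
        rel_time = np.minimum(t_rel, cfg.censor_time)
        # relapse follow-up only exists for non-metastatic disease
        premet = np.isin(stage, ["I", "II", "III"])
        rel_event = np.where(premet, rel_event, np.nan)
        rel_time = np.where(premet, rel_time, np.nan)

        expression[ds_id] = pd.DataFrame(
            values, index=pd.Index(probeset_ids, name="probeset_id"), columns=sample_ids
        )
        signal_frames.append(
            pd.DataFrame(signal, index=pd.Index(gene_ids, name="gene_id"),
                         columns=sample_ids)
        )
        clin_frames.append(
            pd.DataFrame(
                {
                    "dataset_id": ds_id,
                    "center": center,
                    "scan_batch": batch,
                    "pm_iqr": metrics[:, 0],
                    "rma_iqr": metrics[:, 1],
                    "rna_deg": metrics[:, 2],
                    "gender": gender,
                    "age": age,
                    "site": site,
                    "msi": msi,
                    "stage": stage,
                    "relapse_time": rel_time,
                    "relapse_event": rel_event,
                    "os_time": os_time,
                    "os_event": os_event,
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )

    clinical = pd.concat(clin_frames)
    truth = GroundTruth(
        gene_signal=pd.concat(signal_frames, axis=1),
        probeset_loadings=pd.Series(loadings, index=probeset_ids),
        probeset_intercepts=pd.Series(intercepts, index=probeset_ids),
        center_offsets=center_offsets,
        batch_offsets=batch_offsets,
        metric_slopes=pd.DataFrame(slopes, index=probeset_ids, columns=_METRICS),
        msi_genes=msi_genes,
        true_log_hr=cfg.cox_log_hr,
    )
    return expression, clinical, annotation, truth


def write_cohort(
    out_dir: str | Path,
    expression: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write a generated cohort to disk (TSV/CSV/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds_id, mat in expression.items():
        mat.to_csv(out / f"expression_{ds_id}.tsv", sep="\t")
    clinical.to_csv(out / "clinical.csv")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
        truth.gene_signal.to_csv(out / "gene_signal.tsv", sep="\t")
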