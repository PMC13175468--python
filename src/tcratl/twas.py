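"""Two-step summary-statistic TWAS.

Step 1 trains, per gene, an elastic-net model of (residualized) expression
on cis-SNV dosages restricted to a prioritized SNV set:

    E_g ~ sum_i w_{i,g} X_i + eps

with the penalty strength chosen by cross-validation and models kept only
when the cross-validated R^2 exceeds 0.01. Step 2 combines the trained
weights with GWAS summary statistics into a gene-level Z score:

    Z_g = sum_{i in Model_g} w_{i,g} * (sigma_i / sigma_g) * beta_i / se(beta_i)

where sigma_i is the training-panel genotype SD of predictor i and
sigma_g = sqrt(w' Sigma w) is the SD of predicted expression under the
reference-panel LD matrix Sigma. Genes with Bonferroni-corrected P < 0.05
are reported as significant.

Variant QC (exclusion rules): MAF < 0.01, missingness > 10%, HWE P < 1e-6.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, cross_val_predict


@dataclasses.dataclass(frozen=True)
class QcConfig:
    maf_min: float = 0.01
    missing_max: float = 0.10
    hwe_p_min: float = 1e-6

    def __post_init__(self):
        for v in (self.maf_min, self.missing_max, self.hwe_p_min):
            if not 0 < v < 1:
                raise ValueError("QC thresholds must lie in (0, 1)")


@dataclasses.dataclass
class ExpressionModel:
    gene: str
    tss: int
    chrom: str
    weights: pd.Series  # nonzero elastic-net weights, indexed by variant id
    cv_r2: float
    sigma_i: pd.Series  # training genotype SDs for the weight index
    sigma_g: float  # SD of predicted expression under training LD
    alpha: float  # selected penalty strength


@dataclasses.dataclass
class TwasResult:
    gene: str
    z: float
    p: float
    n_predictors: int
    dropped: list[str]
    untestable: bool = False


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit P value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the observed allele frequency; no
    continuity correction. Monomorphic sites cannot depart from HWE and
    return P = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    genotypes: pd.DataFrame, cfg: QcConfig = QcConfig()
) -> tuple[list[str], pd.DataFrame]:
    """Apply MAF / missingness / HWE exclusion rules to a dosage matrix.

    ``genotypes`` is samples x variants with NaN marking missing calls.
    Returns (passing variant ids, exclusion log); the log records every rule
    each excluded variant violated. Idempotent by construction.
    """
    passing, log_rows = [], []
    n = len(genotypes)
    for vid in genotypes.columns:
        g = genotypes[vid]
        missing = float(g.isna().mean())
        obs = g.dropna()
        reasons = []
        if missing > cfg.missing_max:
            reasons.append("missingness")
        if len(obs):
            freq = float(obs.mean() / 2)
            maf = min(freq, 1 - freq)
            if maf < cfg.maf_min:
                reasons.append("maf")
            counts = obs.round().astype(int).value_counts()
            p_hwe = hwe_test(int(counts.get(2, 0)), int(counts.get(1, 0)), int(counts.get(0, 0)))
            if p_hwe < cfg.hwe_p_min:
                reasons.append("hwe")
        else:
            reasons.append("maf")
        if reasons:
            log_rows.append((vid, ",".join(reasons)))
        else:
            passing.append(vid)
    return passing, pd.DataFrame(log_rows, columns=["variant", "reasons"])


def cis_predictors(
    gene_chrom: str,
    gene_tss: int,
    variants: pd.DataFrame,
    prioritized_set: set[str] | None,
    window: float = 1e6,
) -> list[str]:
    """Variants within +/- ``window`` bp of the TSS (closed bounds, same
    chromosome) that are members of the prioritized set.

    ``prioritized_set=None`` is the baseline mode: no prioritization filter,
    i.e. the full-panel TWAS.
    """
    sel = variants[
        (variants["chrom"] == gene_chrom)
        & ((variants["pos"] - gene_tss).abs() <= window)
    ]
    ids = list(sel["id"])
    if prioritized_set is not None:
        ids = [i for i in ids if i in prioritized_set]
    return ids


def residualize_expression(expr: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of expression on covariates + intercept.

    Stands in for factor-based expression normalization: removes known
    covariate effects before elastic-net fitting. Accepts (n,) or (n, g)
    expression.
    """
    expr = np.asarray(expr, dtype=np.float64)
    n = expr.shape[0]
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        covariates = np.asarray(covariates, dtype=np.float64)
        X = np.hstack([X, covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, expr, rcond=None)
    return expr - X @ beta


def train_expression_model(
    genotypes: pd.DataFrame,
    residual_expr: np.ndarray,
    predictor_ids: Sequence[str],
    gene: str,
    gene_chrom: str = "",
    gene_tss: int = 0,
    en_l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
) -> ExpressionModel:
    """Cross-validated elastic-net expression model for one gene.

    Penalty strength is chosen by ``n_folds``-fold CV (seeded fold
    assignment); ``cv_r2`` is the squared Pearson correlation between
    out-of-fold predictions (at the selected penalty) and the residualized
    expression. An all-zero-weight solution is retained with cv_r2 = 0.
    """
    if len(predictor_ids) < 2:
        raise ValueError("need at least 2 predictors after QC")
    y = np.asarray(residual_expr, dtype=np.float64)
    if len(y) <= n_folds:
        raise ValueError("need more samples than folds")
    X = genotypes[list(predictor_ids)].to_numpy(dtype=np.float64)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny folds
        enet = ElasticNetCV(l1_ratio=en_l1_ratio, cv=cv, alphas=50, max_iter=5000)
        enet.fit(X, y)
        oof = cross_val_predict(
            ElasticNet(alpha=enet.alpha_, l1_ratio=en_l1_ratio, max_iter=5000), X, y, cv=cv
        )
    w = pd.Series(enet.coef_, index=list(predictor_ids))
    nz = w[w != 0]
    if len(nz) == 0 or np.std(oof) == 0:
        cv_r2 = 0.0
    else:
        cv_r2 = float(np.corrcoef(oof, y)[0, 1] ** 2)
    sigma_i = genotypes[list(nz.index)].std(ddof=1) if len(nz) else pd.Series(dtype=float)
    sigma_g = _sigma_g(nz, genotypes) if len(nz) else 0.0
    return ExpressionModel(
        gene=gene, tss=gene_tss, chrom=gene_chrom, weights=nz, cv_r2=cv_r2,
        sigma_i=sigma_i, sigma_g=sigma_g, alpha=float(enet.alpha_),
    )


def _sigma_g(weights: pd.Series, reference_genotypes: pd.DataFrame) -> float:
    """sqrt(w' Sigma w) with Sigma the reference genotype covariance."""
    G = reference_genotypes[list(weights.index)].to_numpy(dtype=np.float64)
    Sigma = np.cov(G, rowvar=False, ddof=1).reshape(len(weights), len(weights))
    w = weights.to_numpy()
    return float(np.sqrt(max(w @ Sigma @ w, 0.0)))


def filter_models(models: Sequence[ExpressionModel], r2_min: float = 0.01) -> list[ExpressionModel]:
    """Keep genetically well-predicted models: cv_r2 strictly > r2_min."""
    return [m for m in models if m.cv_r2 > r2_min]


def twas_z(
    model: ExpressionModel,
    summary_stats: pd.DataFrame,
    reference_genotypes: pd.DataFrame | None = None,
) -> TwasResult:
    """Gene-level association Z from trained weights + GWAS summary stats.

    Predictors absent from the summary statistics are dropped with a warning
    (and sigma_g recomputed over the remaining predictors when a reference
    panel is supplied). A model with no usable predictors, or sigma_g = 0,
    is flagged untestable.
    """
    ss = summary_stats.set_index("id")
    present = [v for v in model.weights.index if v in ss.index]
    dropped = [v for v in model.weights.index if v not in ss.index]
    if dropped:
        warnings.warn(
            f"{model.gene}: {len(dropped)} predictor(s) missing from summary stats "
            "dropped; Z computed over the remainder"
        )
    w = model.weights[present]
    if len(w) == 0:
        return TwasResult(model.gene, np.nan, np.nan, 0, dropped, untestable=True)
    if reference_genotypes is not None:
        sigma_g = _sigma_g(w, reference_genotypes)
    elif not dropped:
        sigma_g = model.sigma_g
    else:
        raise ValueError("reference genotypes required when predictors were dropped")
    if sigma_g == 0:
        return TwasResult(model.gene, np.nan, np.nan, len(w), dropped, untestable=True)
    beta = ss.loc[present, "beta"].to_numpy(dtype=float)
    se = ss.loc[present, "se"].to_numpy(dtype=float)
    sigma_i = model.sigma_i[present].to_numpy(dtype=float)
    z = float(np.sum(w.to_numpy() * (sigma_i / sigma_g) * beta / se))
    p = float(2 * stats.norm.sf(abs(z)))
    return TwasResult(model.gene, z, p, len(w), dropped)


def bonferroni_report(results: Sequence[TwasResult], alpha: float = 0.05) -> pd.DataFrame:
    """Flag genes with P < alpha / m over the m tested genes."""
    testable = [r for r in results if not r.untestable]
    m = len(testable)
    if m == 0:
        raise ValueError("no testable genes")
    thr = alpha / m
    rows = [
        (r.gene, r.z, r.p, r.n_predictors, (not r.untestable) and r.p < thr)
        for r in results
    ]
    return pd.DataFrame(rows, columns=["gene", "Z", "P", "n_predictors", "significant"])


def run_twas(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: np.ndarray | None,
    variants: pd.DataFrame,
    gene_defs: Sequence,
    summary_stats: pd.DataFrame,
    prioritized_set: set[str] | None,
    qc: QcConfig = QcConfig(),
    window: float = 1e6,
    r2_min: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ExpressionModel], pd.DataFrame]:
    """End-to-end two-step TWAS over a gene set.

    ``gene_defs`` supplies (gene, chrom, tss) per gene (extra fields are
    ignored); ``prioritized_set=None`` runs the baseline (unrestricted)
    analysis. Returns (results table, retained models, QC exclusion log).
    """
    passing, qc_log = qc_filter(genotypes, qc)
    passing_set = set(passing)
    resid = residualize_expression(expression.to_numpy(dtype=float), covariates)
    resid = pd.DataFrame(resid, index=expression.index, columns=expression.columns)
    models = []
    for gd in gene_defs:
        preds = cis_predictors(gd.chrom, gd.tss, variants, prioritized_set, window)
        preds = [p for p in preds if p in passing_set]
        if len(preds) < 2:
            continue
        models.append(
            train_expression_model(
                genotypes, resid[gd.gene].to_numpy(), preds, gd.gene,
                gene_chrom=gd.chrom, gene_tss=gd.tss, seed=seed,
            )
        )
    kept = filter_models(models, r2_min)
    results = [twas_z(m, summary_stats, reference_genotypes=genotypes) for m in kept]
    table = bonferroni_report(results) if results else pd.DataFrame(
        columns=["gene", "Z", "P", "n_predictors", "significant"]
    )
    return table, kept, qc_log
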