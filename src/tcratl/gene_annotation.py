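"""Annotation of TWAS-significant genes.

Joins gene lists against CRISPR-dependency (CERES) scores, drug-target
tables, and disease-gene tables, and computes the three summary quantities:
essential genes (median CERES < -0.5 across cell lines), druggable rate
(genes with an approved or phase II/III drug), and disease-listed rate.

Gene identifiers are case- and whitespace-normalized before joining.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import pandas as pd

CERES_ESSENTIAL_CUTOFF = -0.5
ACTIONABLE_STATUSES = frozenset({"approved", "phase II", "phase III"})
DRUG_STATUSES = frozenset({"approved", "phase II", "phase III", "other"})


def _norm(g) -> str:
    return str(g).strip().upper()


def essential_genes(genes: Sequence[str], ceres: pd.DataFrame) -> pd.DataFrame:
    """Flag genes whose median CERES score across cell lines is < -0.5.

    The cutoff is strict: a median of exactly -0.5 is not essential. Genes
    absent from the table are reported unflagged with a notice.
    """
    t = ceres.assign(gene=ceres["gene"].map(_norm))
    medians = t.groupby("gene")["score"].median()
    rows = []
    missing = []
    for g in genes:
        key = _norm(g)
        if key in medians.index:
            med = float(medians[key])
            rows.append((g, med, med < CERES_ESSENTIAL_CUTOFF))
        else:
            missing.append(g)
            rows.append((g, float("nan"), False))
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from the CERES table: {missing}")
    return pd.DataFrame(rows, columns=["gene", "median_ceres", "essential"])


@dataclasses.dataclass
class DruggableReport:
    count: int
    rate_percent: float
    gene_drugs: pd.DataFrame  # gene, drug, status rows for counted genes


def druggable_rate(genes: Sequence[str], drug_targets: pd.DataFrame) -> DruggableReport:
    """Genes with at least one approved / phase II / phase III drug.

    Rate is count / |genes| * 100. Rows with other statuses never qualify a
    gene.
    """
    if not len(genes):
        raise ValueError("empty gene list")
    t = drug_targets.assign(gene=drug_targets["gene"].map(_norm))
    bad = set(t["status"]) - DRUG_STATUSES
    if bad:
        raise ValueError(f"unknown drug statuses: {sorted(bad)}")
    actionable = t[t["status"].isin(ACTIONABLE_STATUSES)]
    keys = {_norm(g) for g in genes}
    hits = actionable[actionable["gene"].isin(keys)]
    n = hits["gene"].nunique()
    return DruggableReport(
        count=n,
        rate_percent=100.0 * n / len(genes),
        gene_drugs=hits.reset_index(drop=True),
    )


def disease_rate(
    genes: Sequence[str],
    disease_genes: pd.DataFrame,
    disease_filter: Sequence[str] | None = None,
) -> float:
    """Percentage of genes with at least one disease-table entry.

    ``disease_filter`` restricts which diseases count (default: any).
    """
    if not len(genes):
        raise ValueError("empty gene list")
    t = disease_genes.assign(gene=disease_genes["gene"].map(_norm))
    if disease_filter is not None:
        t = t[t["disease"].isin(set(disease_filter))]
    listed = set(t["gene"])
    n = sum(_norm(g) in listed for g in genes)
    return 100.0 * n / len(genes)


def annotate_genes(
    genes: Sequence[str],
    ceres: pd.DataFrame,
    drug_targets: pd.DataFrame,
    disease_genes: pd.DataFrame,
) -> pd.DataFrame:
    """Combined per-gene report: essentiality, druggability, disease listing."""
    ess = essential_genes(genes, ceres).set_index("gene")
    drug = druggable_rate(genes, drug_targets)
    druggable = set(drug.gene_drugs["gene"])
    t = disease_genes.assign(gene=disease_genes["gene"].map(_norm))
    listed = set(t["gene"])
    return pd.DataFrame(
        {
            "gene": list(genes),
            "median_ceres": [ess.loc[g, "median_ceres"] for g in genes],
            "essential": [bool(ess.loc[g, "essential"]) for g in genes],
            "druggable": [_norm(g) in druggable for g in genes],
            "disease_listed": [_norm(g) in listed for g in genes],
        }
    )
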