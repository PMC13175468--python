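"""Functional evaluation of prioritized SNV subsets.

Overlap of SNV positions with enhancer chromatin states (15-state
segmentation), tissue vs unrelated cell-line contrasts, counts of
genome-wide-significant GWAS variants (P < 5e-8), overlap with
pathogenic/germline variant tables, and pairwise subset overlaps.

SNV positions are 1-based and converted to 0-based points; chromatin-state
intervals are half-open BED intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .synthetic_data import CHROMHMM_15_STATES, ENHANCER_STATES
from .tcra import Variant

GWAS_SIGNIFICANCE = 5e-8


@dataclasses.dataclass
class StateAnnotation:
    """One cell line's chromatin-state segmentation."""

    cell_line: str
    intervals: pd.DataFrame  # chrom, start, end, state (half-open)
    enhancer_states: tuple[str, ...] = ENHANCER_STATES

    def __post_init__(self):
        bad = set(self.intervals["state"]) - set(CHROMHMM_15_STATES)
        if bad:
            raise ValueError(f"unknown chromatin states: {sorted(bad)}")
        if (self.intervals["start"] < 0).any() or (
            self.intervals["end"] <= self.intervals["start"]
        ).any():
            raise ValueError("intervals must be nonempty half-open with start >= 0")
        self._trees: dict[str, IntervalTree] | None = None

    def _enhancer_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            self._trees = {}
            enh = self.intervals[self.intervals["state"].isin(self.enhancer_states)]
            for chrom, grp in enh.groupby("chrom"):
                self._trees[str(chrom)] = IntervalTree.from_tuples(
                    zip(grp["start"], grp["end"])
                )
        return self._trees

    def covers(self, chrom: str, pos: int) -> bool:
        """Is the 1-based position inside any enhancer-state interval?"""
        tree = self._enhancer_trees().get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))


def read_states_bed(path, cell_line: str,
                    enhancer_states: tuple[str, ...] = ENHANCER_STATES) -> StateAnnotation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "state"], comment="#")
    return StateAnnotation(cell_line, df, enhancer_states)


def overlap_proportion(snvs: Sequence[Variant], annotation: StateAnnotation) -> float:
    """Fraction of SNVs whose position falls in an enhancer-state interval."""
    if not snvs:
        raise ValueError("empty SNV set")
    hits = sum(annotation.covers(v.chrom, v.pos) for v in snvs)
    return hits / len(snvs)


@dataclasses.dataclass
class TissueContrast:
    per_cell_line: dict[str, float]
    tissue_mean: float
    other_mean: float
    tissue_range: tuple[float, float]
    other_range: tuple[float, float]


def tissue_contrast(
    snvs: Sequence[Variant],
    tissue_annotations: Sequence[StateAnnotation],
    other_annotations: Sequence[StateAnnotation],
) -> TissueContrast:
    """Enhancer-overlap proportions in tissue-relevant vs unrelated cell lines."""
    if not tissue_annotations or not other_annotations:
        raise ValueError("both annotation groups must be nonempty")
    per = {}
    tp = [overlap_proportion(snvs, a) for a in tissue_annotations]
    op = [overlap_proportion(snvs, a) for a in other_annotations]
    for a, p in zip(tissue_annotations, tp):
        per[a.cell_line] = p
    for a, p in zip(other_annotations, op):
        per[a.cell_line] = p
    return TissueContrast(
        per_cell_line=per,
        tissue_mean=sum(tp) / len(tp),
        other_mean=sum(op) / len(op),
        tissue_range=(min(tp), max(tp)),
        other_range=(min(op), max(op)),
    )


def gwas_significant_count(
    snv_subset: Iterable[str],
    summary_stats: pd.DataFrame,
    threshold: float = GWAS_SIGNIFICANCE,
) -> tuple[int, set[str], set[str]]:
    """Count subset members with GWAS P strictly below the threshold.

    ``summary_stats`` must carry ``id`` and ``p`` columns. Returns
    (count, significant ids, unmatched ids) — unmatched subset members are
    reported, never silently dropped.
    """
    subset = set(snv_subset)
    stats = summary_stats.set_index("id")["p"]
    matched = subset & set(stats.index)
    unmatched = subset - matched
    sig = {vid for vid in matched if stats[vid] < threshold}
    return len(sig), sig, unmatched


def pathogenic_overlap(
    snv_subset: Sequence[Variant],
    pathogenic_table: pd.DataFrame,
) -> int:
    """Count subset variants matching pathogenic + germline table rows.

    Matching is by (chrom, pos, ref, alt); the table is first filtered to
    rows whose clinical significance is 'pathogenic' and origin 'germline'.
    """
    t = pathogenic_table
    keep = t[
        (t["clinical_significance"].str.lower() == "pathogenic")
        & (t["origin"].str.lower() == "germline")
    ]
    keys = set(zip(keep["chrom"], keep["pos"], keep["ref"], keep["alt"]))
    return sum(v.key in keys for v in snv_subset)


def subset_overlap(a: Iterable[str], b: Iterable[str]) -> tuple[int, int, int]:
    """(|A∩B|, |A\\B|, |B\\A|) for two id sets."""
    sa, sb = set(a), set(b)
    return len(sa & sb), len(sa - sb), len(sb - sa)


@dataclasses.dataclass
class EnrichmentReport:
    per_cell_line: dict[str, float]
    tissue_contrast: TissueContrast | None
    gwas_significant: int
    pathogenic: int
    subset_size: int

    def frame(self) -> pd.DataFrame:
        rows = [("cell_line_overlap:" + c, p) for c, p in self.per_cell_line.items()]
        rows += [
            ("gwas_significant", self.gwas_significant),
            ("pathogenic_germline", self.pathogenic),
            ("subset_size", self.subset_size),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def evaluate_subset(
    variants: Sequence[Variant],
    tissue_annotations: Sequence[StateAnnotation],
    other_annotations: Sequence[StateAnnotation],
    summary_stats: pd.DataFrame,
    pathogenic_table: pd.DataFrame,
    gwas_threshold: float = GWAS_SIGNIFICANCE,
) -> EnrichmentReport:
    """Full functional evaluation of one prioritized subset."""
    contrast = tissue_contrast(variants, tissue_annotations, other_annotations)
    n_sig, _, _ = gwas_significant_count(
        [v.id for v in variants], summary_stats, gwas_threshold
    )
    n_path = pathogenic_overlap(variants, pathogenic_table)
    return EnrichmentReport(
        per_cell_line=contrast.per_cell_line,
        tissue_contrast=contrast,
        gwas_significant=n_sig,
        pathogenic=n_path,
        subset_size=len(variants),
    )
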