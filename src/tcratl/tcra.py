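"""Tissue-based cis-regulatory activity (tCRA) scoring of SNVs.

A variant's tCRA is the mean over k tissue tracks of the absolute difference
between the model's alt-allele and ref-allele predictions read out at the
center of the output window (the two middle 128-bp bins averaged; bins 448
and 449 at full-scale geometry). The variant is placed one base to the right
of the input-sequence midpoint, i.e. at 0-based offset L/2.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_prep import PrepConfig, SequenceWindow, one_hot_encode
from .io import GenomeLike

_BASES = set("ACGT")


@dataclasses.dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant; ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"{self.id or self.chrom}:{self.pos}: alleles must be single bases, "
                             f"got ref={self.ref!r} alt={self.alt!r} (indels rejected)")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref and alt are identical")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclasses.dataclass
class TcraRecord:
    variant: Variant
    per_track_effect: np.ndarray  # (k,), |Pred_alt - Pred_ref| at the center
    tcra: float

    def __post_init__(self):
        self.per_track_effect = np.asarray(self.per_track_effect, dtype=np.float64)
        if (self.per_track_effect < 0).any():
            raise ValueError("per-track effects must be nonnegative")


@dataclasses.dataclass
class PrioritizedSubsets:
    ranked_ids: list[str]  # all variant ids, best first
    sizes: list[int]

    def subset(self, size: int) -> list[str]:
        if size not in self.sizes:
            raise KeyError(f"size {size} not among {self.sizes}")
        return self.ranked_ids[:size]


def make_allele_windows(
    genome: GenomeLike, variant: Variant, L: int, pad: bool = False
) -> tuple[SequenceWindow, SequenceWindow]:
    """Build ref- and alt-allele windows with the SNV at 0-based offset L/2.

    The windows are identical except at that single offset. Raises if the
    genome base at the variant position does not equal the declared ref.
    """
    p0 = variant.pos - 1
    offset = L // 2
    start = p0 - offset
    n = genome.length(variant.chrom)
    if not pad and (start < 0 or start + L > n):
        raise IndexError(
            f"window for {variant.chrom}:{variant.pos} exceeds chromosome bounds; "
            "enable padding or use a larger margin"
        )
    lo, hi = max(start, 0), min(start + L, n)
    core = genome.fetch(variant.chrom, lo, hi)
    seq = "N" * (lo - start) + core + "N" * (start + L - hi)
    observed = seq[offset]
    if observed != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: genome has "
            f"{observed!r}, variant declares ref {variant.ref!r}"
        )
    alt_seq = seq[:offset] + variant.alt + seq[offset + 1 :]
    ref_w = SequenceWindow(variant.chrom, start, start + L, seq, one_hot_encode(seq))
    alt_w = SequenceWindow(variant.chrom, start, start + L, alt_seq, one_hot_encode(alt_seq))
    return ref_w, alt_w


def center_bin_value(pred: np.ndarray) -> np.ndarray:
    """Average the two central output bins (per track).

    For an even bin count n this is 1-based bins n/2 and n/2+1 (448 and 449
    at full-scale geometry). An odd bin count falls back to the single middle
    bin with a warning.
    """
    pred = np.atleast_2d(np.asarray(pred))
    n = pred.shape[0]
    if n % 2 == 0:
        return pred[n // 2 - 1 : n // 2 + 1].mean(axis=0)
    warnings.warn(f"odd bin count {n}: using the single middle bin")
    return pred[n // 2].copy()


def tcra_score(
    model,
    genome: GenomeLike,
    variant: Variant,
    cfg: PrepConfig,
    mode: str = "mean_abs",
    pad: bool = False,
) -> TcraRecord:
    """Score one SNV: per-track central effect and its mean (the tCRA).

    ``mode="mean_abs"`` (default) is the mean of absolute per-track
    differences; ``mode="abs_mean"`` is the absolute value of the mean
    difference, kept for sensitivity checks.
    """
    ref_w, alt_w = make_allele_windows(genome, variant, cfg.L, pad=pad)
    preds = model.predict_batch(np.stack([ref_w.one_hot, alt_w.one_hot]))
    ref_c = center_bin_value(preds[0])
    alt_c = center_bin_value(preds[1])
    return _record(variant, ref_c, alt_c, mode)


def _record(variant: Variant, ref_c: np.ndarray, alt_c: np.ndarray, mode: str) -> TcraRecord:
    diff = alt_c - ref_c
    if mode == "mean_abs":
        effects = np.abs(diff)
        score = float(effects.mean())
    elif mode == "abs_mean":
        effects = np.abs(diff)
        score = float(abs(diff.mean()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TcraRecord(variant, effects, score)


def tcra_score_batch(
    model,
    genome: GenomeLike,
    variants: Sequence[Variant],
    cfg: PrepConfig,
    mode: str = "mean_abs",
    batch_size: int = 16,
    pad: bool = False,
) -> list[TcraRecord]:
    """Score many SNVs, batching ref/alt pairs through the model."""
    records = []
    for i in range(0, len(variants), batch_size):
        chunk = variants[i : i + batch_size]
        windows = []
        for v in chunk:
            ref_w, alt_w = make_allele_windows(genome, v, cfg.L, pad=pad)
            windows.extend([ref_w.one_hot, alt_w.one_hot])
        preds = model.predict_batch(np.stack(windows))
        for j, v in enumerate(chunk):
            ref_c = center_bin_value(preds[2 * j])
            alt_c = center_bin_value(preds[2 * j + 1])
            records.append(_record(v, ref_c, alt_c, mode))
    return records


def prioritize(records: Iterable[TcraRecord], sizes: Sequence[int]) -> PrioritizedSubsets:
    """Rank variants by descending tCRA and emit nested top-N subsets.

    Ties are broken by (chrom, pos) ascending, so the ranking is stable and
    deterministic across runs. Sizes exceeding the record count are truncated
    with a warning.
    """
    recs = list(records)
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("subset sizes must be ascending")
    clipped = []
    for s in sizes:
        if s > len(recs):
            warnings.warn(f"subset size {s} exceeds record count {len(recs)}; truncated")
            s = len(recs)
        clipped.append(s)
    order = sorted(recs, key=lambda r: (-r.tcra, r.variant.chrom, r.variant.pos))
    return PrioritizedSubsets([r.variant.id for r in order], clipped)


def records_to_frame(records: Sequence[TcraRecord], per_track: bool = False) -> pd.DataFrame:
    """Tabulate records as a TSV-ready DataFrame."""
    rows = []
    for r in records:
        row = {
            "id": r.variant.id,
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "tcra": r.tcra,
        }
        if per_track:
            for j, e in enumerate(r.per_track_effect):
                row[f"effect_track{j}"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def variants_from_frame(df: pd.DataFrame) -> list[Variant]:
    """Build Variant objects from a (chrom, pos, id, ref, alt) table."""
    return [
        Variant(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.id))
        for r in df.itertuples(index=False)
    ]
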