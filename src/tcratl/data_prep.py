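"""Model-ready sample construction.

Turns a genome plus raw per-bp track signal into one-hot encoded sequence
inputs and cropped/clipped/scaled/binned targets, mirroring the standard
sequence-to-profile preprocessing: a 196,608-bp window is cropped by
40,960 bp at each end, the remaining signal is clipped at 32, scaled by 2 and
averaged over 128-bp bins, giving 896 target values per track.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeLike

# column order A, C, G, T; N encodes as an all-zero row
_ALPHABET = "ACGT"
_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(_ALPHABET):
    _LUT[ord(_b), _i] = 1.0
    _LUT[ord(_b.lower()), _i] = 1.0
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTNacgtn":
    _VALID[ord(_b)] = True


@dataclasses.dataclass(frozen=True)
class PrepConfig:
    """Geometry and normalization constants for sample preparation.

    Defaults are the full-scale geometry; :meth:`desk` returns the small
    geometry used throughout the test suite (4,096 bp -> 24 bins).
    """

    L: int = 196_608
    crop: int = 40_960
    bin_size: int = 128
    clip_max: float = 32.0
    scale: float = 2.0

    def __post_init__(self):
        if min(self.L, self.crop, self.bin_size) <= 0 or self.clip_max <= 0 or self.scale <= 0:
            raise ValueError("all PrepConfig fields must be positive")
        if (self.L - 2 * self.crop) % self.bin_size != 0:
            raise ValueError(
                f"(L - 2*crop) = {self.L - 2 * self.crop} not divisible by "
                f"bin_size = {self.bin_size}"
            )
        if self.L - 2 * self.crop <= 0:
            raise ValueError("crop leaves no sequence")

    @property
    def n_bins(self) -> int:
        return (self.L - 2 * self.crop) // self.bin_size

    @classmethod
    def desk(cls, **kw) -> "PrepConfig":
        """Small geometry (L=4096, crop=512, bin=128 -> 24 bins)."""
        args = dict(L=4096, crop=512, bin_size=128)
        args.update(kw)
        return cls(**args)


@dataclasses.dataclass
class SequenceWindow:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    seq: str
    one_hot: np.ndarray  # (L, 4)

    def __post_init__(self):
        if self.end - self.start != len(self.seq):
            raise ValueError("coordinates inconsistent with sequence length")


@dataclasses.dataclass
class BinnedTracks:
    values: np.ndarray  # (n_bins, k), nonnegative
    bin_size: int
    crop: int

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if (self.values < 0).any():
            raise ValueError("binned track values must be nonnegative")


@dataclasses.dataclass
class DatasetSplit:
    samples: list[tuple[SequenceWindow, BinnedTracks]]
    label: str

    def __len__(self) -> int:
        return len(self.samples)

    def inputs(self) -> np.ndarray:
        """Stacked one-hot inputs, (n, L, 4)."""
        return np.stack([w.one_hot for w, _ in self.samples])

    def targets(self) -> np.ndarray:
        """Stacked binned targets, (n, n_bins, k)."""
        return np.stack([t.values for _, t in self.samples])


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode a DNA string (A,C,G,T columns; N -> zero row).

    Raises ``ValueError`` naming the first offending position on any
    character outside {A,C,G,T,N} (case-insensitive).
    """
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = np.flatnonzero(~_VALID[codes])
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"illegal character {seq[i]!r} at position {i}")
    return _LUT[codes].copy()


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (zero rows decode to N)."""
    mat = np.asarray(mat)
    out = np.full(mat.shape[0], "N", dtype="<U1")
    nz = mat.sum(axis=1) > 0
    out[nz] = np.array(list(_ALPHABET))[mat[nz].argmax(axis=1)]
    return "".join(out)


def extract_window(
    genome: GenomeLike, chrom: str, start: int, L: int, pad: bool = False
) -> SequenceWindow:
    """Extract an L-bp window at ``start`` (0-based); optionally pad with N.

    With ``pad=True`` any overhang beyond either chromosome end is filled
    with N (which one-hot encodes to zero rows); otherwise overhang raises.
    """
    n = genome.length(chrom)
    if not pad:
        if start < 0 or start + L > n:
            raise IndexError(
                f"window [{start}, {start + L}) outside {chrom} (length {n})"
            )
        seq = genome.fetch(chrom, start, start + L)
    else:
        lo, hi = max(start, 0), min(start + L, n)
        core = genome.fetch(chrom, lo, hi) if hi > lo else ""
        seq = "N" * (lo - start) + core + "N" * (start + L - hi)
    return SequenceWindow(chrom, start, start + L, seq, one_hot_encode(seq))


def bin_targets(raw_signal: np.ndarray, cfg: PrepConfig) -> np.ndarray:
    """Crop, clip, scale and bin a per-bp signal.

    Pipeline order: crop ``cfg.crop`` bp from each end, clip at
    ``cfg.clip_max``, multiply by ``cfg.scale``, then average over
    consecutive ``cfg.bin_size``-bp windows. Accepts (L,) or (L, k) input
    and returns (n_bins,) or (n_bins, k) accordingly.
    """
    raw = np.asarray(raw_signal, dtype=np.float64)
    if raw.shape[0] != cfg.L:
        raise ValueError(f"signal length {raw.shape[0]} != configured L {cfg.L}")
    squeeze = raw.ndim == 1
    if squeeze:
        raw = raw[:, None]
    x = raw[cfg.crop : cfg.L - cfg.crop]
    x = np.clip(x, None, cfg.clip_max) * cfg.scale
    binned = x.reshape(cfg.n_bins, cfg.bin_size, x.shape[1]).mean(axis=1)
    return binned[:, 0] if squeeze else binned


def split_regions(
    regions: Sequence[tuple[str, int]],
    fractions: tuple[float, float, float],
    seed: int,
) -> dict[str, list[tuple[str, int]]]:
    """Deterministically shuffle regions and partition into train/valid/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(regions))
    n = len(regions)
    n_train = round(n * fractions[0])
    n_valid = round(n * (fractions[0] + fractions[1])) - n_train
    idx = {
        "train": order[:n_train],
        "valid": order[n_train : n_train + n_valid],
        "test": order[n_train + n_valid :],
    }
    return {lab: [regions[i] for i in ii] for lab, ii in idx.items()}


def build_dataset(
    genome: GenomeLike,
    tracks: Mapping[str, np.ndarray],
    regions: Sequence[tuple[str, int]],
    cfg: PrepConfig,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, DatasetSplit]:
    """Assemble train/valid/test splits of (window, binned target) samples.

    ``tracks`` maps chrom -> (L_chrom, k) raw per-bp signal; each region is a
    (chrom, start) window origin. Assignment to splits is deterministic under
    ``seed`` and regions are never shared between splits.
    """
    seen = set()
    for r in regions:
        if r in seen:
            raise ValueError(f"duplicate region {r}")
        seen.add(r)
    assignment = split_regions(list(regions), split_fractions, seed)
    out = {}
    for label, regs in assignment.items():
        samples = []
        for chrom, start in regs:
            window = extract_window(genome, chrom, start, cfg.L)
            raw = np.atleast_2d(np.asarray(tracks[chrom]).T).T[start : start + cfg.L]
            values = bin_targets(raw, cfg)
            samples.append(
                (window, BinnedTracks(values, bin_size=cfg.bin_size, crop=cfg.crop))
            )
        out[label] = DatasetSplit(samples, label)
    return out


def save_dataset(splits: Mapping[str, DatasetSplit], outdir) -> None:
    """Serialize splits as compressed tensors plus a TSV manifest.

    Writes ``<label>.npz`` (inputs, targets) per split and ``manifest.tsv``
    listing every sample's split, chrom, start and end.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for label, split in splits.items():
        np.savez_compressed(
            os.path.join(outdir, f"{label}.npz"),
            inputs=split.inputs().astype(np.float32),
            targets=split.targets(),
        )
        for w, t in split.samples:
            rows.append((label, w.chrom, w.start, w.end, t.bin_size, t.crop))
    pd.DataFrame(rows, columns=["split", "chrom", "start", "end", "bin_size", "crop"]).to_csv(
        os.path.join(outdir, "manifest.tsv"), sep="\t", index=False
    )


def load_dataset(outdir) -> dict[str, DatasetSplit]:
    """Inverse of :func:`save_dataset` (sequences restored from one-hot)."""
    import os

    manifest = pd.read_csv(os.path.join(outdir, "manifest.tsv"), sep="\t")
    out = {}
    for label, grp in manifest.groupby("split", sort=False):
        with np.load(os.path.join(outdir, f"{label}.npz")) as data:
            inputs, targets = data["inputs"], data["targets"]
        samples = []
        for i, row in enumerate(grp.itertuples(index=False)):
            seq = decode_one_hot(inputs[i])
            w = SequenceWindow(row.chrom, row.start, row.end, seq, inputs[i])
            samples.append((w, BinnedTracks(targets[i], bin_size=row.bin_size, crop=row.crop)))
        out[label] = DatasetSplit(samples, str(label))
    return out


def tiling_regions(genome: GenomeLike, cfg: PrepConfig, step: int | None = None) -> list[tuple[str, int]]:
    """Non-overlapping (or strided) window origins tiling each chromosome."""
    step = step or cfg.L
    regs = []
    for chrom in genome.chroms():
        n = genome.length(chrom)
        for start in range(0, n - cfg.L + 1, step):
            regs.append((chrom, start))
    return regs
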