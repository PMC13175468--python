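"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Genomes are exposed through a tiny fetch-based protocol so that in-memory
synthetic genomes and indexed FASTA files are interchangeable everywhere
downstream.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np
import pandas as pd


@runtime_checkable
class GenomeLike(Protocol):
    """Minimal random-access genome interface."""

    def chroms(self) -> list[str]: ...

    def length(self, chrom: str) -> int: ...

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence on [start, end), 0-based half-open."""
        ...


class DictGenome:
    """Genome backed by an in-memory ``{chrom: sequence}`` mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self._seqs[chrom]) or start > end:
            raise IndexError(
                f"interval [{start}, {end}) outside {chrom} "
                f"(length {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start:end]


class FastaGenome:
    """Indexed FASTA genome (via pyfaidx)."""

    def __init__(self, path: str | os.PathLike):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.length(chrom) or start > end:
            raise IndexError(f"interval [{start}, {end}) outside {chrom}")
        return str(self._fa[chrom][start:end])


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(
    values: Mapping[str, np.ndarray], path: str | os.PathLike, track_index: int = 0
) -> None:
    """Write one track of per-bp signal as run-length-encoded bedGraph.

    ``values`` maps chrom -> (L,) or (L, k) array; ``track_index`` selects the
    column when 2-D.
    """
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            v = np.asarray(arr)
            if v.ndim == 2:
                v = v[:, track_index]
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a bedGraph file into dense per-bp arrays (zeros where uncovered)."""
    out = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    for row in df.itertuples(index=False):
        if row.chrom in out:
            out[row.chrom][row.start : row.end] = row.value
    return out


def write_bigwig(
    values: Mapping[str, np.ndarray], path: str | os.PathLike, track_index: int = 0
) -> None:
    """Optional bigWig export (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    header = [(c, int(np.asarray(v).shape[0])) for c, v in values.items()]
    bw.addHeader(header)
    for chrom, arr in values.items():
        v = np.asarray(arr, dtype=np.float64)
        if v.ndim == 2:
            v = v[:, track_index]
        bw.addEntries(chrom, 0, values=v, span=1, step=1)
    bw.close()


def read_bigwig(path: str | os.PathLike, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    out = {}
    for chrom, n in chrom_lengths.items():
        vals = np.array(bw.values(chrom, 0, n), dtype=np.float64)
        out[chrom] = np.nan_to_num(vals)
    bw.close()
    return out


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name]) intervals as BED."""
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike, names: Iterable[str] = ("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(variants: pd.DataFrame, path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Minimal VCF v4.2 export of SNVs (chrom, pos, id, ref, alt columns)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for c, n in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\n")


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), f[2], f[3], f[4]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
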