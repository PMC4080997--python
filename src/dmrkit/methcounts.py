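"""Per-cytosine methylation count tables and conversion-efficiency estimation.

A whole-genome bisulfite library reduces, per cytosine, to two integers:
``n_meth`` (reads that still show C, i.e. the cytosine was methylated and
protected from conversion) and ``n_unmeth`` (reads showing T).  A
:class:`SampleMethylome` holds one library's records as a sorted DataFrame.

Table dialect: 6-column TSV -- chrom, pos (1-based), strand, context,
n_meth, n_unmeth -- with a ``#``-prefixed header line; optionally gzipped.
Positions are converted to 0-based in memory.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .genome import CONTEXTS, CytosineSite

logger = logging.getLogger(__name__)

_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


@dataclasses.dataclass(frozen=True)
class MethCountRecord:
    """One cytosine's methylated (a_i) and unmethylated (b_i) read counts."""

    site: CytosineSite
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclasses.dataclass
class SampleMethylome:
    """One bisulfite library: metadata plus a sorted per-cytosine count table.

    ``records`` columns: chrom (str), pos (int, 0-based), strand ('+'/'-'),
    context (CG/CHG/CHH), n_meth, n_unmeth.  At most one row per
    (chrom, pos, strand); sorted by (chrom, pos, strand).
    """

    sample_id: str
    genotype: str = ""
    replicate: str = ""
    records: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, self.sample_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMethylome):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.genotype == other.genotype
            and self.replicate == other.replicate
            and self.records.reset_index(drop=True).equals(
                other.records.reset_index(drop=True)
            )
        )


def _validate_records(df: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"methylome {sample_id}: missing columns {missing}")
    df = df[_COLUMNS]
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "n_meth", "n_unmeth"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    if (df[["n_meth", "n_unmeth"]] < 0).to_numpy().any():
        raise ValueError(f"methylome {sample_id}: negative counts")
    bad_ctx = set(df["context"].astype(str)) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"methylome {sample_id}: invalid contexts {sorted(bad_ctx)}")
    bad_strand = set(df["strand"].astype(str)) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"methylome {sample_id}: invalid strands {sorted(bad_strand)}")
    df["strand"] = df["strand"].astype(str)
    df["context"] = df["context"].astype(str)

    key = pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]])
    if key.has_duplicates:
        dup = df[key.duplicated()].iloc[0]
        raise ValueError(
            f"methylome {sample_id}: duplicate record at "
            f"{dup.chrom}:{dup.pos}({dup.strand})"
        )
    if not key.is_monotonic_increasing:
        logger.warning("methylome %s: records unsorted; sorting", sample_id)
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


def _open(path: str | Path, mode: str) -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_count_table(
    path: str | Path, sample_id: str = "", genotype: str = "", replicate: str = ""
) -> SampleMethylome:
    """Read a 6-column count table; returns a validated, sorted methylome.

    Malformed lines raise ``ValueError`` with the 1-based line number.
    """
    rows = []
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]) - 1,  # file is 1-based
                        parts[2],
                        parts[3],
                        int(parts[4]),
                        int(parts[5]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return SampleMethylome(
        sample_id=sample_id or Path(path).stem,
        genotype=genotype,
        replicate=replicate,
        records=df,
    )


def write_count_table(methylome: SampleMethylome, path: str | Path) -> None:
    """Write the 6-column dialect (positions 1-based on disk)."""
    with _open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tn_meth\tn_unmeth\n")
        df = methylome.records
        out = df.assign(pos=df["pos"] + 1)
        out.to_csv(fh, sep="\t", header=False, index=False)


def estimate_conversion_efficiency(
    methylome: SampleMethylome, control_chrom: str
) -> float:
    """Bisulfite conversion efficiency from an unmethylated control sequence.

    Every cytosine on the control (chloroplast or spike-in) is assumed
    unmethylated, so the fraction of its reads converted to T,
    sum(b_i) / sum(a_i + b_i), estimates the conversion rate.
    """
    ctl = methylome.records[methylome.records["chrom"] == control_chrom]
    total = int(ctl["n_meth"].sum() + ctl["n_unmeth"].sum())
    if total == 0:
        raise ValueError(
            f"no coverage on control chromosome {control_chrom!r} "
            f"in sample {methylome.sample_id}"
        )
    rate = float(ctl["n_unmeth"].sum()) / total
    logger.info(
        "sample %s: conversion efficiency %.4f (n=%d reads on %s)",
        methylome.sample_id,
        rate,
        total,
        control_chrom,
    )
    return rate
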