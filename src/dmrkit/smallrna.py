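"""Small-RNA window quantification and differential small-RNA regions (DSRs).

Mapped small-RNA reads (BED of genomic positions; alignment is upstream)
are assigned to 500-bp static windows by their 5' end and normalised to
RPM (reads per million mapped reads).  Two analyses are provided:

* DSR calling between a mutant and its wild type: windows reaching an RPM
  floor (default 10 RPM, in either sample) are tested with Fisher's exact
  test on (window count vs rest of library) and a fold-change cutoff; this
  combination of the RPM filter, Fisher test and BH-FDR is this package's
  documented procedure, written to output headers as such.
* a global abundance comparison: a two-sided Mann-Whitney U test on the
  RPM values of windows passing the floor in the wild-type sample,
  answering whether the small-RNA population is globally shifted.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import fdr_adjust, fisher_exact_batch, mann_whitney_u

logger = logging.getLogger(__name__)

REDUCED = "reduced"  # fewer small-RNA reads in the mutant
INCREASED = "increased"


@dataclasses.dataclass
class DsrConfig:
    window_size: int = 500
    rpm_min: float = 10.0        # RPM floor for a window to be testable
    rpm_min_scope: str = "either"  # "either" sample or "wt" only
    fc_min: float = 2.0          # fold-change cutoff (with pseudocount)
    pseudocount_rpm: float = 0.5
    q_max: float = 0.01
    min_read_length: int = 15
    max_read_length: int = 35

    def __post_init__(self) -> None:
        if self.rpm_min_scope not in {"either", "wt"}:
            raise ValueError("rpm_min_scope must be 'either' or 'wt'")
        if self.window_size <= 0 or self.rpm_min < 0 or self.fc_min < 1:
            raise ValueError("invalid DSR config")


def validate_reads(reads: pd.DataFrame, config: DsrConfig | None = None) -> pd.DataFrame:
    """Check read intervals and length bounds; returns the frame with a
    ``length`` column."""
    config = config or DsrConfig()
    reads = reads.copy()
    reads["start"] = reads["start"].astype(np.int64)
    reads["end"] = reads["end"].astype(np.int64)
    if (reads["start"] >= reads["end"]).any():
        raise ValueError("reads must have start < end")
    reads["length"] = reads["end"] - reads["start"]
    bad = (reads["length"] < config.min_read_length) | (
        reads["length"] > config.max_read_length
    )
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} reads outside the allowed length range "
            f"[{config.min_read_length}, {config.max_read_length}] nt"
        )
    return reads


def count_reads_in_windows(
    reads: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_size: int = 500,
    library_size: int | None = None,
) -> pd.DataFrame:
    """Count reads per static window and attach RPM values.

    A read belongs to exactly one window, chosen by its 5' end (start for
    '+' reads, end - 1 for '-' reads; start when no strand column is
    present).  ``library_size`` defaults to the number of input reads.
    Reads beyond the chromosome end raise ``ValueError``.
    """
    from .dmr import make_windows

    windows = make_windows(chrom_lengths, window_size)
    if "strand" in reads.columns:
        five_prime = np.where(
            reads["strand"].to_numpy() == "-",
            reads["end"].to_numpy() - 1,
            reads["start"].to_numpy(),
        )
    else:
        five_prime = reads["start"].to_numpy()
    lengths = reads["chrom"].map(chrom_lengths)
    if lengths.isna().any():
        bad = reads.loc[lengths.isna(), "chrom"].iloc[0]
        raise ValueError(f"read on unknown chromosome {bad!r}")
    if (reads["end"].to_numpy() > lengths.to_numpy()).any() or (five_prime < 0).any():
        raise ValueError("read extends beyond chromosome end")
    lib = library_size if library_size is not None else len(reads)
    if lib <= 0:
        raise ValueError("library size must be positive")
    counts = (
        pd.DataFrame({"chrom": reads["chrom"], "widx": five_prime // window_size})
        .groupby(["chrom", "widx"], sort=False)
        .size()
    )
    key = pd.MultiIndex.from_arrays([windows["chrom"], windows["start"] // window_size])
    windows = windows.copy()
    windows["count"] = counts.reindex(key, fill_value=0).to_numpy().astype(np.int64)
    windows["rpm"] = windows["count"] * 1e6 / lib
    windows.attrs["library_size"] = int(lib)
    return windows


def size_distribution(reads: pd.DataFrame) -> pd.Series:
    """Histogram of read counts by length in nt (index sorted, int counts)."""
    lengths = (reads["end"] - reads["start"]).astype(int)
    return lengths.value_counts().sort_index().rename("count")


def call_dsrs(
    wt_windows: pd.DataFrame,
    mut_windows: pd.DataFrame,
    config: DsrConfig | None = None,
) -> pd.DataFrame:
    """Differential small-RNA regions between one mutant and its wild type.

    Both inputs come from :func:`count_reads_in_windows` on the same
    tiling.  Eligible windows (RPM floor) are tested with Fisher's exact
    test on the 2x2 table (window reads vs rest of library, wild type vs
    mutant); a DSR needs BH q < ``q_max`` and a pseudocounted RPM fold
    change >= ``fc_min``.  Direction is ``reduced``/``increased`` in the
    mutant.
    """
    config = config or DsrConfig()
    if not wt_windows[["chrom", "start", "end"]].equals(
        mut_windows[["chrom", "start", "end"]]
    ):
        raise ValueError("wild-type and mutant windows use different tilings")
    lib_wt = int(wt_windows.attrs.get("library_size", wt_windows["count"].sum()))
    lib_mut = int(mut_windows.attrs.get("library_size", mut_windows["count"].sum()))
    if lib_wt <= 0 or lib_mut <= 0:
        raise ValueError("zero library size")

    df = wt_windows[["chrom", "start", "end"]].copy()
    df["count_wt"] = wt_windows["count"].to_numpy()
    df["count_mut"] = mut_windows["count"].to_numpy()
    df["rpm_wt"] = wt_windows["rpm"].to_numpy()
    df["rpm_mut"] = mut_windows["rpm"].to_numpy()
    if config.rpm_min_scope == "either":
        eligible = (df["rpm_wt"] >= config.rpm_min) | (df["rpm_mut"] >= config.rpm_min)
    else:
        eligible = df["rpm_wt"] >= config.rpm_min
    df = df[eligible].reset_index(drop=True)
    if len(df) == 0:
        return df.assign(fold_change=[], p=[], q=[], direction=[])

    pc = config.pseudocount_rpm
    ratio = (df["rpm_wt"] + pc) / (df["rpm_mut"] + pc)
    df["fold_change"] = np.maximum(ratio, 1.0 / ratio)
    df["p"] = fisher_exact_batch(
        df["count_wt"].to_numpy(),
        lib_wt - df["count_wt"].to_numpy(),
        df["count_mut"].to_numpy(),
        lib_mut - df["count_mut"].to_numpy(),
    )
    df["q"] = fdr_adjust(df["p"].to_numpy())
    df["direction"] = np.where(ratio >= 1.0, REDUCED, INCREASED)
    dsrs = df[(df["q"] < config.q_max) & (df["fold_change"] >= config.fc_min)]
    logger.info(
        "DSR call: %d eligible windows, %d DSRs (%d reduced, %d increased)",
        len(df), len(dsrs),
        int((dsrs["direction"] == REDUCED).sum()),
        int((dsrs["direction"] == INCREASED).sum()),
    )
    return dsrs.reset_index(drop=True)


def global_abundance_test(
    wt_windows: pd.DataFrame,
    mut_windows: pd.DataFrame,
    rpm_min: float = 10.0,
) -> tuple[float, float]:
    """Global small-RNA abundance shift: Mann-Whitney U on window RPMs.

    Windows are eligible when the wild-type sample reaches ``rpm_min``;
    the two RPM vectors over those windows are compared with a two-sided
    unpaired rank test.  Returns (U, p).  Fewer than 2 eligible windows is
    an error.
    """
    if not wt_windows[["chrom", "start", "end"]].equals(
        mut_windows[["chrom", "start", "end"]]
    ):
        raise ValueError("wild-type and mutant windows use different tilings")
    eligible = wt_windows["rpm"].to_numpy() >= rpm_min
    if eligible.sum() < 2:
        raise ValueError("fewer than 2 eligible windows for the global test")
    return mann_whitney_u(
        wt_windows["rpm"].to_numpy()[eligible],
        mut_windows["rpm"].to_numpy()[eligible],
    )
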