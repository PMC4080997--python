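"""Windowed DMR calling.

The genome is tiled into fixed 100-bp windows and, per cytosine context
(CG, CHG, CHH), methylated/unmethylated read counts are pooled within each
window for the two samples being compared.  Windows are kept only if the
wild-type sample covers at least ``min_cytosines`` cytosines of that
context at depth >= ``min_cov_per_cytosine`` each.  The window methylation
level is the coverage-weighted level m = sum(a_i) / sum(a_i + b_i).  Each
kept window is tested with a two-sided Fisher exact test on the pooled
2x2 table (wild type vs mutant), p-values are BH-adjusted within one
(contrast, context) family, and a window is flagged when
|m_wt - m_mut| >= a context-specific difference cutoff (0.4 / 0.2 / 0.1
for CG / CHG / CHH) and q < 0.01.  Flagged windows of the same direction
within 200 bp of each other are merged into DMRs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .methcounts import SampleMethylome
from .stats import fdr_adjust, fisher_exact_batch

logger = logging.getLogger(__name__)

HYPO = "hypo_in_mutant"  # methylation reduced in the mutant (m_wt > m_mut)
HYPER = "hyper_in_mutant"

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "direction", "n_windows",
    "A_wt", "B_wt", "A_mut", "B_mut", "m_wt", "m_mut", "score",
]


@dataclasses.dataclass
class DmrConfig:
    """Cutoffs for window-based DMR calling (defaults as printed above)."""

    window_size: int = 100
    min_cytosines: int = 4
    min_cov_per_cytosine: int = 4
    diff_threshold: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
    )
    q_max: float = 0.01
    merge_gap: int = 200

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.merge_gap < 0:
            raise ValueError("window_size must be positive, merge_gap non-negative")
        if self.min_cytosines <= 0 or self.min_cov_per_cytosine <= 0:
            raise ValueError("coverage filter parameters must be positive")
        for ctx, t in self.diff_threshold.items():
            if not (0 < t <= 1):
                raise ValueError(f"diff_threshold[{ctx}] must be in (0, 1]")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")


def make_windows(
    chrom_lengths: Mapping[str, int], window_size: int = 100
) -> pd.DataFrame:
    """Tile every chromosome into consecutive non-overlapping windows.

    The final window is truncated at the chromosome end.  Returns a frame
    with columns (chrom, start, end), 0-based half-open.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def methylation_level(A: float, B: float) -> float:
    """Coverage-weighted methylation level sum(C reads) / sum(all reads)."""
    total = A + B
    if total <= 0:
        raise ValueError("methylation level undefined for zero coverage")
    return A / total


def aggregate_counts(
    methylome: SampleMethylome,
    chrom_lengths: Mapping[str, int],
    context: str,
    config: DmrConfig,
) -> pd.DataFrame:
    """Pool per-cytosine counts of one context into tiling windows.

    Returns one row per window (all tiles, including empty ones) with
    pooled counts A (= sum n_meth) and B (= sum n_unmeth) over both
    strands, plus ``n_cyt_cov``: the number of the window's context
    cytosines covered at >= ``min_cov_per_cytosine`` reads (used by the
    wild-type coverage filter).
    """
    windows = make_windows(chrom_lengths, config.window_size)
    rec = methylome.records
    rec = rec[rec["context"] == context]
    rec = rec[rec["chrom"].isin(chrom_lengths.keys())]
    if len(rec) == 0:
        out = windows.assign(A=0, B=0, n_cyt_cov=0)
        return out
    widx = rec["pos"].to_numpy() // config.window_size
    cov = (rec["n_meth"] + rec["n_unmeth"]).to_numpy()
    grouped = pd.DataFrame(
        {
            "chrom": rec["chrom"].to_numpy(),
            "widx": widx,
            "A": rec["n_meth"].to_numpy(),
            "B": rec["n_unmeth"].to_numpy(),
            "good": (cov >= config.min_cov_per_cytosine).astype(np.int64),
        }
    ).groupby(["chrom", "widx"], sort=False, observed=True).sum()
    key = pd.MultiIndex.from_arrays(
        [windows["chrom"], windows["start"] // config.window_size]
    )
    out = windows.copy()
    for col, name in (("A", "A"), ("B", "B"), ("good", "n_cyt_cov")):
        out[name] = (
            grouped[col].reindex(key, fill_value=0).to_numpy().astype(np.int64)
        )
    return out


def coverage_filter(n_cyt_cov: np.ndarray, config: DmrConfig) -> np.ndarray:
    """Keep windows whose wild-type sample covers enough context cytosines."""
    return np.asarray(n_cyt_cov) >= config.min_cytosines


def compare_windows(
    wildtype: SampleMethylome,
    mutant: SampleMethylome,
    context: str,
    chrom_lengths: Mapping[str, int],
    config: DmrConfig | None = None,
) -> pd.DataFrame:
    """Window-level differential test for one (contrast, context) family.

    Returns one row per coverage-passing window: pooled counts for both
    samples, methylation levels, diff = m_wt - m_mut, Fisher p, BH q and
    the ``passed`` flag.  Windows with zero pooled mutant coverage cannot
    be assigned a methylation difference; they are excluded and logged.
    The FDR family is all coverage-passing, testable windows of this
    contrast and context.
    """
    config = config or DmrConfig()
    wt = aggregate_counts(wildtype, chrom_lengths, context, config)
    mut = aggregate_counts(mutant, chrom_lengths, context, config)
    df = wt.rename(columns={"A": "A_wt", "B": "B_wt", "n_cyt_cov": "n_cyt_wt"})
    df["A_mut"] = mut["A"]
    df["B_mut"] = mut["B"]
    df = df[coverage_filter(df["n_cyt_wt"].to_numpy(), config)].reset_index(drop=True)

    zero_mut = (df["A_mut"] + df["B_mut"]) == 0
    n_zero = int(zero_mut.sum())
    if n_zero:
        logger.info(
            "%s vs %s [%s]: excluding %d windows with zero mutant coverage",
            wildtype.sample_id, mutant.sample_id, context, n_zero,
        )
    df = df[~zero_mut].reset_index(drop=True)
    # the wild-type filter guarantees wt coverage > 0 on every kept window
    df["context"] = context
    df["m_wt"] = df["A_wt"] / (df["A_wt"] + df["B_wt"])
    df["m_mut"] = df["A_mut"] / (df["A_mut"] + df["B_mut"])
    df["diff"] = df["m_wt"] - df["m_mut"]
    if len(df):
        df["p"] = fisher_exact_batch(
            df["A_wt"].to_numpy(), df["B_wt"].to_numpy(),
            df["A_mut"].to_numpy(), df["B_mut"].to_numpy(),
        )
        df["q"] = fdr_adjust(df["p"].to_numpy())
    else:
        df["p"] = np.zeros(0)
        df["q"] = np.zeros(0)
    return call_candidate_windows(df, context, config)


def call_candidate_windows(
    results: pd.DataFrame, context: str, config: DmrConfig | None = None
) -> pd.DataFrame:
    """Flag windows passing both the difference cutoff and the FDR cutoff.

    Adds/overwrites ``passed`` and ``direction`` columns; direction is the
    sign of diff = m_wt - m_mut (positive -> methylation lost in mutant).
    """
    config = config or DmrConfig()
    thr = config.diff_threshold[context]
    df = results.copy()
    df["passed"] = (df["diff"].abs() >= thr) & (df["q"] < config.q_max)
    df["direction"] = np.where(df["diff"] > 0, HYPO, HYPER)
    return df


def merge_windows_to_dmrs(
    results: pd.DataFrame, config: DmrConfig | None = None
) -> pd.DataFrame:
    """Merge flagged windows of one (contrast, context) family into DMRs.

    Windows sharing a direction whose gap is <= ``merge_gap`` (inclusive)
    are merged; opposite directions never merge.  Summary methylation
    levels are recomputed from the pooled member-window counts, and the
    score is -log10(q) of the best member window.
    """
    config = config or DmrConfig()
    flagged = results[results["passed"]] if "passed" in results else results
    dmrs = []
    for (chrom, direction), grp in flagged.groupby(
        ["chrom", "direction"], sort=True, observed=True
    ):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # new cluster when the gap to the running end exceeds merge_gap
        run_end = np.maximum.accumulate(ends)
        new_cluster = np.ones(len(grp), dtype=bool)
        new_cluster[1:] = starts[1:] - run_end[:-1] > config.merge_gap
        cluster = np.cumsum(new_cluster) - 1
        agg = grp.groupby(cluster).agg(
            start=("start", "min"),
            end=("end", "max"),
            n_windows=("start", "size"),
            A_wt=("A_wt", "sum"),
            B_wt=("B_wt", "sum"),
            A_mut=("A_mut", "sum"),
            B_mut=("B_mut", "sum"),
            q_best=("q", "min"),
        )
        agg["chrom"] = chrom
        agg["direction"] = direction
        agg["context"] = grp["context"].iloc[0]
        dmrs.append(agg)
    if not dmrs:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out = pd.concat(dmrs, ignore_index=True)
    out["m_wt"] = out["A_wt"] / (out["A_wt"] + out["B_wt"])
    out["m_mut"] = out["A_mut"] / (out["A_mut"] + out["B_mut"])
    with np.errstate(divide="ignore"):
        out["score"] = -np.log10(np.maximum(out["q_best"], 1e-300))
    out = out.sort_values(["chrom", "start", "direction"]).reset_index(drop=True)
    return out[DMR_COLUMNS]


def call_dmrs(
    wildtype: SampleMethylome,
    mutant: SampleMethylome,
    context: str,
    chrom_lengths: Mapping[str, int],
    config: DmrConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full single-replicate DMR call: window tests plus merged DMRs."""
    config = config or DmrConfig()
    results = compare_windows(wildtype, mutant, context, chrom_lengths, config)
    dmrs = merge_windows_to_dmrs(results, config)
    logger.info(
        "%s vs %s [%s]: %d windows tested, %d flagged, %d DMRs",
        wildtype.sample_id, mutant.sample_id, context,
        len(results), int(results["passed"].sum()) if len(results) else 0, len(dmrs),
    )
    return results, dmrs
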