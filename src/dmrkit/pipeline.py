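"""End-to-end workflow: per-replicate DMR calling, replicate intersection,
HV subtraction, annotation, DSR calling and summary tables.

The noise-reduction cascade mirrors how robust DMR sets are derived from
replicated bisulfite experiments: call windows per wild-type/mutant pair
within each biological replicate, merge nearby flagged windows, keep only
regions supported in both replicates (or mutant alleles), and drop regions
overlapping known hypervariable loci.  Stage-by-stage counts are logged so
a run documents its own attrition.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .dmr import DmrConfig, call_dmrs, merge_windows_to_dmrs
from .intervals import (
    classify_annotation,
    intersect_replicates,
    overlap_fraction,
    subtract_regions,
    write_bed,
)
from .methcounts import SampleMethylome, estimate_conversion_efficiency, write_count_table
from .simulate import (
    SimConfig,
    Simulation,
    simulate_genome,
    simulate_methylome,
    simulate_smallrna,
    write_simulation,
)
from .smallrna import DsrConfig, call_dsrs, count_reads_in_windows, global_abundance_test

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


@dataclasses.dataclass
class PipelineResult:
    """Bundle of every stage's tables for one simulated or file-based run."""

    window_results: Dict[tuple, pd.DataFrame]   # (context, replicate) -> windows
    dmrs_single: Dict[tuple, pd.DataFrame]      # (context, replicate) -> merged DMRs
    dmrs_intersected: Dict[str, pd.DataFrame]   # context -> replicate-supported
    dmrs_final: Dict[str, pd.DataFrame]         # context -> after HV subtraction
    stage_counts: pd.DataFrame
    annotation_fractions: Dict[str, pd.Series]
    dsrs: pd.DataFrame | None = None
    dsr_windows: tuple | None = None
    global_test: tuple | None = None
    recovery: pd.DataFrame | None = None
    conversion: Dict[str, float] | None = None


def run_replicated_dmr_analysis(
    pairs: Sequence[tuple[SampleMethylome, SampleMethylome]],
    chrom_lengths: Mapping[str, int],
    hv: pd.DataFrame,
    config: DmrConfig | None = None,
    contexts: Sequence[str] = CONTEXTS,
) -> PipelineResult:
    """DMR cascade over (wild type, mutant) pairs, one per replicate.

    With a single pair the intersection stage is skipped (with a prominent
    warning): the resulting set then rests on one replicate only.
    """
    config = config or DmrConfig()
    window_results: Dict[tuple, pd.DataFrame] = {}
    dmrs_single: Dict[tuple, pd.DataFrame] = {}
    dmrs_intersected: Dict[str, pd.DataFrame] = {}
    dmrs_final: Dict[str, pd.DataFrame] = {}
    rows = []
    for ctx in contexts:
        per_rep = []
        for rep, (wt, mut) in enumerate(pairs, start=1):
            results, dmrs = call_dmrs(wt, mut, ctx, chrom_lengths, config)
            window_results[(ctx, rep)] = results
            dmrs_single[(ctx, rep)] = dmrs
            per_rep.append(dmrs)
            rows.append((ctx, rep, "windows_tested", len(results)))
            rows.append((ctx, rep, "windows_flagged", int(results["passed"].sum()) if len(results) else 0))
            rows.append((ctx, rep, "dmrs_merged", len(dmrs)))
        if len(per_rep) == 1:
            logger.warning(
                "context %s: only one replicate pair supplied; replicate "
                "intersection SKIPPED - DMRs rest on a single replicate", ctx
            )
            inter = per_rep[0][["chrom", "start", "end", "context", "direction"]]
        else:
            inter = intersect_replicates(per_rep[0], per_rep[1])
            for extra in per_rep[2:]:
                inter = intersect_replicates(inter, extra)
        dmrs_intersected[ctx] = inter.reset_index(drop=True)
        rows.append((ctx, 0, "dmrs_intersected", len(inter)))
        final = subtract_regions(dmrs_intersected[ctx], hv)
        dmrs_final[ctx] = final
        rows.append((ctx, 0, "dmrs_hv_subtracted", len(final)))
    stage_counts = pd.DataFrame(rows, columns=["context", "replicate", "stage", "count"])
    return PipelineResult(
        window_results=window_results,
        dmrs_single=dmrs_single,
        dmrs_intersected=dmrs_intersected,
        dmrs_final=dmrs_final,
        stage_counts=stage_counts,
        annotation_fractions={},
    )


def truth_recovery(
    dmrs_final: Mapping[str, pd.DataFrame], truth_dmrs: pd.DataFrame
) -> pd.DataFrame:
    """Sensitivity/precision of the final DMR sets against planted truth.

    Per context: sensitivity = fraction of above-threshold planted regions
    overlapped by a final DMR; subthreshold_recovery = same for regions
    planted below the calling threshold; precision = fraction of final
    DMRs overlapping any planted region (of any effect size).
    """
    rows = []
    for ctx in sorted(dmrs_final):
        called = dmrs_final[ctx]
        planted = truth_dmrs[truth_dmrs["context"] == ctx]
        above = planted[planted["above_threshold"]]
        below = planted[~planted["above_threshold"]]
        sens = overlap_fraction(above, called) if len(above) else float("nan")
        sub = overlap_fraction(below, called) if len(below) else float("nan")
        prec = overlap_fraction(called, planted) if len(called) else float("nan")
        rows.append((ctx, len(above), len(below), len(called), sens, sub, prec))
    return pd.DataFrame(
        rows,
        columns=["context", "n_planted", "n_subthreshold", "n_called",
                 "sensitivity", "subthreshold_recovery", "precision"],
    )


def run_simulated_study(
    sim_config: SimConfig | None = None,
    dmr_config: DmrConfig | None = None,
    dsr_config: DsrConfig | None = None,
    contexts: Sequence[str] = CONTEXTS,
    outdir: str | Path | None = None,
    null: bool = False,
) -> tuple[Simulation, PipelineResult]:
    """Simulate a study and run the complete analysis on it.

    With ``null=True`` the 'mutant' samples are drawn as additional
    wild-type-role samples (no planted effect is expressed): the
    wild-type-vs-wild-type comparison that calibrates the false-positive
    behaviour of the cascade.
    """
    sim_config = sim_config or SimConfig()
    dmr_config = dmr_config or DmrConfig()
    dsr_config = dsr_config or DsrConfig()
    sim = simulate_genome(sim_config)

    pairs = []
    for rep in range(1, sim_config.replicates + 1):
        wt = simulate_methylome(sim, "wt", rep)
        if null:
            # an independent wild-type-role draw standing in the mutant slot
            mut = simulate_methylome(sim, "wt", rep + 1000, sample_id=f"wt_b_rep{rep}")
        else:
            mut = simulate_methylome(sim, "mut", rep)
        pairs.append((wt, mut))

    chrom_lengths = sim.analysis_chrom_lengths
    result = run_replicated_dmr_analysis(
        pairs, chrom_lengths, sim.truth.hv, dmr_config, contexts
    )

    for ctx in contexts:
        _, fractions = classify_annotation(result.dmrs_final[ctx], sim.genes, sim.tes)
        result.annotation_fractions[ctx] = fractions

    # small RNA: one library pair (replicate 1)
    wt_reads = simulate_smallrna(sim, "wt", 1)
    mut_reads = simulate_smallrna(sim, "wt" if null else "mut", 1001 if null else 1)
    wt_win = count_reads_in_windows(wt_reads, chrom_lengths, dsr_config.window_size)
    mut_win = count_reads_in_windows(mut_reads, chrom_lengths, dsr_config.window_size)
    result.dsr_windows = (wt_win, mut_win)
    result.dsrs = call_dsrs(wt_win, mut_win, dsr_config)
    result.global_test = global_abundance_test(wt_win, mut_win, dsr_config.rpm_min)

    if not null:
        result.recovery = truth_recovery(result.dmrs_final, sim.truth.dmrs)

    result.conversion = {}
    for rep, (wt, mut) in enumerate(pairs, start=1):
        for m in (wt, mut):
            result.conversion[m.sample_id] = estimate_conversion_efficiency(
                m, sim_config.control_chrom
            )

    if outdir is not None:
        write_results(sim, result, outdir, pairs, (wt_reads, mut_reads))
    return sim, result


def summarize(result: PipelineResult) -> Dict[str, pd.DataFrame]:
    """Report tables: DMR counts by context/direction, annotation
    fractions, DSR counts by direction, DMR/DSR overlap."""
    rows = []
    for ctx, df in sorted(result.dmrs_final.items()):
        for direction in ("hypo_in_mutant", "hyper_in_mutant"):
            n = int((df["direction"] == direction).sum()) if len(df) else 0
            rows.append((ctx, direction, n))
    dmr_counts = pd.DataFrame(rows, columns=["context", "direction", "n_dmrs"])
    totals = dmr_counts.groupby("context")["n_dmrs"].transform("sum")
    dmr_counts["fraction"] = (dmr_counts["n_dmrs"] / totals.where(totals > 0)).fillna(0.0)

    ann = pd.DataFrame(
        {ctx: fr for ctx, fr in sorted(result.annotation_fractions.items())}
    )
    ann.insert(0, "category", ann.index)
    ann = ann.reset_index(drop=True)

    dsr_rows = []
    if result.dsrs is not None and len(result.dsrs):
        for direction, grp in result.dsrs.groupby("direction"):
            dsr_rows.append((direction, len(grp)))
    dsr_counts = pd.DataFrame(dsr_rows, columns=["direction", "n_dsrs"])

    overlap_rows = []
    if result.dsrs is not None:
        for ctx, df in sorted(result.dmrs_final.items()):
            frac = overlap_fraction(df, result.dsrs) if len(df) else 0.0
            overlap_rows.append((ctx, len(df), frac))
    dmr_dsr_overlap = pd.DataFrame(
        overlap_rows, columns=["context", "n_dmrs", "fraction_overlapping_dsrs"]
    )

    tables = {
        "dmr_counts": dmr_counts,
        "annotation_fractions": ann,
        "dsr_counts": dsr_counts,
        "dmr_dsr_overlap": dmr_dsr_overlap,
        "stage_counts": result.stage_counts,
    }
    if result.recovery is not None:
        tables["recovery"] = result.recovery
    return tables


def _dmr_bed(df: pd.DataFrame) -> pd.DataFrame:
    out = df[["chrom", "start", "end"]].copy()
    ctx = df["context"].astype(str) if "context" in df.columns else pd.Series(
        ["NA"] * len(df), index=df.index
    )
    direction = df["direction"].astype(str) if "direction" in df.columns else pd.Series(
        ["NA"] * len(df), index=df.index
    )
    out["name"] = ctx + ":" + direction
    out["score"] = df["score"].round(3) if "score" in df.columns else 0
    return out


def write_results(
    sim: Simulation,
    result: PipelineResult,
    outdir: str | Path,
    pairs: Sequence[tuple] | None = None,
    srna_reads: tuple | None = None,
) -> None:
    """Write every stage's tables under ``outdir`` (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_simulation(sim, outdir / "sim")
    if pairs:
        d = outdir / "sim"
        for wt, mut in pairs:
            write_count_table(wt, d / f"meth_{wt.sample_id}.tsv")
            write_count_table(mut, d / f"meth_{mut.sample_id}.tsv")
    if srna_reads:
        for name, reads in zip(("wt", "mut"), srna_reads):
            write_bed(reads, outdir / "sim" / f"srna_{name}.bed")

    kw = dict(sep="\t", index=False, float_format="%.6g")
    for (ctx, rep), df in result.window_results.items():
        df.to_csv(outdir / f"windows_{ctx}_rep{rep}.tsv", **kw)
    for (ctx, rep), df in result.dmrs_single.items():
        write_bed(_dmr_bed(df), outdir / f"dmrs_{ctx}_rep{rep}.bed")
    for ctx, df in result.dmrs_intersected.items():
        write_bed(_dmr_bed(df), outdir / f"dmrs_{ctx}_intersected.bed")
    for ctx, df in result.dmrs_final.items():
        write_bed(_dmr_bed(df), outdir / f"dmrs_{ctx}_final.bed")
    if result.dsrs is not None:
        header = outdir / "dsrs.tsv"
        with open(header, "w") as fh:
            fh.write("# DSRs: RPM floor + fold change + Fisher/BH "
                     "(dmrkit procedure; not a published derivation)\n")
            result.dsrs.to_csv(fh, **kw)
    for name, table in summarize(result).items():
        table.to_csv(outdir / f"summary_{name}.tsv", **kw)
    if result.global_test is not None:
        u, p = result.global_test
        pd.DataFrame({"U": [u], "p": [p]}).to_csv(outdir / "global_srna_test.tsv", **kw)
    if result.conversion:
        pd.DataFrame(
            sorted(result.conversion.items()), columns=["sample_id", "conversion_efficiency"]
        ).to_csv(outdir / "conversion_efficiency.tsv", **kw)


def report_text(result: PipelineResult) -> str:
    """Single text summary of a run (the report the CLI prints)."""
    lines = ["dmrkit run summary", "=" * 40]
    tables = summarize(result)
    for name, table in tables.items():
        lines.append(f"\n[{name}]")
        lines.append(table.to_string(index=False))
    if result.global_test is not None:
        u, p = result.global_test
        lines.append(f"\nglobal small-RNA Mann-Whitney U = {u:.1f}, p = {p:.3g}")
    return "\n".join(lines) + "\n"
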