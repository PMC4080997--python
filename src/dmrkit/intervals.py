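"""Interval algebra for DMR/DSR post-processing, plus BED/GFF3 I/O.

All intervals are 0-based half-open; "overlap" always means at least one
shared base.  The operations implement the noise-reduction steps applied
after per-replicate DMR calling:

* replicate/allele intersection -- keep only regions supported in both
  biological replicates (or both mutant alleles), reported as the union
  span of each group of mutually overlapping intervals;
* hypervariable-region subtraction -- drop (entirely, not trim) any region
  overlapping a locus known to change methylation spontaneously across
  generations;
* annotation classification -- label each region TE / gene / intergenic
  (priority TE > gene when a region touches both).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TE_TYPES = ("transposable_element", "transposable_element_gene")
BED_COLUMNS = ["chrom", "start", "end"]


def _as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError("intervals must have start < end")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals, merging any pair separated by <= gap bases."""
    df = _as_intervals(df[BED_COLUMNS])
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = np.maximum.accumulate(grp["end"].to_numpy())
        new = np.ones(len(grp), dtype=bool)
        new[1:] = starts[1:] - ends[:-1] > gap
        cluster = np.cumsum(new) - 1
        g = pd.DataFrame({"start": starts, "end": grp["end"].to_numpy(), "c": cluster})
        agg = g.groupby("c").agg(start=("start", "min"), end=("end", "max"))
        agg["chrom"] = chrom
        rows.append(agg[["chrom", "start", "end"]])
    if not rows:
        return pd.DataFrame(columns=BED_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def _overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it share >= 1 base with any subject interval?"""
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    flat = merge_intervals(subject)
    for chrom, grp in flat.groupby("chrom", sort=False):
        sel = np.nonzero((query["chrom"] == chrom).to_numpy())[0]
        if sel.size == 0:
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        qs = query["start"].to_numpy()[sel]
        qe = query["end"].to_numpy()[sel]
        # overlap iff some flattened interval has start < qe and end > qs
        idx = np.searchsorted(s, qe, side="left") - 1  # last interval starting < qe
        hit = (idx >= 0) & (e[np.clip(idx, 0, None)] > qs)
        out[sel] = hit
    return out


def intersect_replicates(
    dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame, span: str = "union"
) -> pd.DataFrame:
    """Regions supported in both replicates (or both mutant alleles).

    A region of set A is retained iff it overlaps (>= 1 bp) a region of
    set B; when either frame carries a ``direction`` column, only
    same-direction pairs count.  Groups of mutually overlapping intervals
    (connected through A-B overlaps) are reported as one interval: their
    union span (default), the span of the flattened overlap pieces
    (``span="intersection"``), or the A-side members (``span="first"``).
    Columns context/direction are propagated when present and constant
    within a group.
    """
    if span not in {"union", "intersection", "first"}:
        raise ValueError(f"unknown span mode {span!r}")
    keys = [
        c for c in ("context", "direction") if c in dmrs_a.columns and c in dmrs_b.columns
    ]
    cols = BED_COLUMNS + keys
    if len(dmrs_a) == 0 or len(dmrs_b) == 0:
        return pd.DataFrame(columns=cols)
    a = _as_intervals(dmrs_a[cols])
    b = _as_intervals(dmrs_b[cols])
    out_rows = []
    group_cols = ["chrom"] + keys
    b_grouped = {
        (k if isinstance(k, tuple) else (k,)): grp
        for k, grp in b.groupby(group_cols, sort=True, observed=True)
    }
    for gkey, ga in a.groupby(group_cols, sort=True, observed=True):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        gb = b_grouped.get(gkey)
        if gb is None or len(gb) == 0:
            continue
        out_rows.extend(_intersect_one(ga, gb, gkey, keys, span))
    if not out_rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(out_rows, columns=cols)
    return _as_intervals(out)


def _intersect_one(ga, gb, gkey, keys, span):
    """Connected components of the A-B overlap graph within one group."""
    if not isinstance(gkey, tuple):
        gkey = (gkey,)
    sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
    sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
    # sweep over combined endpoints, union-find on overlap edges
    parent = list(range(len(sa) + len(sb)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    paired_a = np.zeros(len(sa), dtype=bool)
    paired_b = np.zeros(len(sb), dtype=bool)
    j0 = 0
    order_b = np.argsort(sb, kind="mergesort")
    sb_s, eb_s = sb[order_b], eb[order_b]
    for i in np.argsort(sa, kind="mergesort"):
        # all b intervals with sb < ea[i] and eb > sa[i]
        hi = np.searchsorted(sb_s, ea[i], side="left")
        for j in range(hi):
            if eb_s[j] > sa[i]:
                union(i, len(sa) + order_b[j])
                paired_a[i] = True
                paired_b[order_b[j]] = True
    rows = []
    comps: dict[int, list[int]] = {}
    for node in range(len(sa) + len(sb)):
        comps.setdefault(find(node), []).append(node)
    for comp in comps.values():
        a_nodes = [n for n in comp if n < len(sa) and paired_a[n]]
        b_nodes = [n - len(sa) for n in comp if n >= len(sa) and paired_b[n - len(sa)]]
        if not a_nodes or not b_nodes:
            continue
        if span == "first":
            for n in sorted(a_nodes):
                rows.append((gkey[0], int(sa[n]), int(ea[n]), *gkey[1:]))
            continue
        if span == "union":
            start = min(min(sa[a_nodes]), min(sb[b_nodes]))
            end = max(max(ea[a_nodes]), max(eb[b_nodes]))
            rows.append((gkey[0], int(start), int(end), *gkey[1:]))
        else:  # intersection: flattened pairwise-overlap pieces
            pieces = []
            for n in a_nodes:
                for m in b_nodes:
                    s = max(sa[n], sb[m])
                    e = min(ea[n], eb[m])
                    if s < e:
                        pieces.append((s, e))
            pieces.sort()
            cur_s, cur_e = pieces[0]
            for s, e in pieces[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((gkey[0], int(cur_s), int(cur_e), *gkey[1:]))
                    cur_s, cur_e = s, e
            rows.append((gkey[0], int(cur_s), int(cur_e), *gkey[1:]))
    return rows


def subtract_regions(dmrs: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove (entirely) every interval overlapping the blacklist.

    Used for hypervariable-region filtering: a DMR touching an HV locus is
    discarded rather than trimmed, because its evidence is suspect as a
    whole.
    """
    if len(dmrs) == 0 or len(blacklist) == 0:
        return dmrs.reset_index(drop=True)
    keep = ~_overlaps_any(dmrs, blacklist)
    return dmrs[keep].reset_index(drop=True)


def classify_annotation(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    priority: Sequence[str] = ("TE", "gene", "intergenic"),
) -> tuple[pd.Series, pd.Series]:
    """Label each region TE / gene / intergenic (exclusive, by priority).

    Returns (labels, fractions); fractions sum to 1 over the three
    categories (all zero for an empty input).
    """
    if set(priority) != {"TE", "gene", "intergenic"}:
        raise ValueError("priority must be a permutation of TE/gene/intergenic")
    hits = {
        "TE": _overlaps_any(dmrs, tes) if len(dmrs) else np.zeros(0, bool),
        "gene": _overlaps_any(dmrs, genes) if len(dmrs) else np.zeros(0, bool),
        "intergenic": np.ones(len(dmrs), dtype=bool),
    }
    labels = np.full(len(dmrs), "intergenic", dtype=object)
    assigned = np.zeros(len(dmrs), dtype=bool)
    for cat in priority:
        take = hits[cat] & ~assigned
        labels[take] = cat
        assigned |= take
    labels = pd.Series(labels, index=dmrs.index, name="annotation")
    counts = labels.value_counts().reindex(["TE", "gene", "intergenic"], fill_value=0)
    fractions = counts / len(dmrs) if len(dmrs) else counts.astype(float)
    return labels, fractions


def overlap_fraction(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Fraction of A's intervals that overlap (>= 1 bp) any interval of B."""
    if len(set_a) == 0:
        logger.info("overlap_fraction: empty query set, returning 0")
        return 0.0
    return float(_overlaps_any(set_a, set_b).mean())


# ---------------------------------------------------------------------------
# BED / GFF3 I/O

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a frame; extra columns become name/score/strand..."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        dtype={0: str}, names=None,
    )
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    df["chrom"] = df["chrom"].astype(str)
    return _as_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3(
    path: str | Path, te_types: Iterable[str] = DEFAULT_TE_TYPES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GFF3 into (genes, tes) interval frames.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based
    half-open.  Gene features are type ``gene``; TE features are any type
    in ``te_types``.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    df["id"] = df["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    te_types = set(te_types)
    genes = df[df["type"] == "gene"][["chrom", "start", "end", "strand", "id"]]
    tes = df[df["type"].isin(te_types)][["chrom", "start", "end", "strand", "id"]]
    return _as_intervals(genes), _as_intervals(tes)


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end, type, strand, id) intervals as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in features.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tdmrkit\t{r.type}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.id}\n"
            )
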