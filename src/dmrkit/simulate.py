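"""Seeded simulation of methylomes and small-RNA libraries with known truth.

The generator emulates the statistical structure the windowed analysis has
to cope with, at desk scale (default: two 1-Mb chromosomes plus a 100-kb
unmethylated control chromosome standing in for the chloroplast):

* random genome at a plant-like GC fraction, with TE-like loci methylated
  in all three contexts (CG/CHG/CHH baselines 0.85/0.35/0.10), gene-body
  loci methylated in CG only, and everything else unmethylated apart from
  a bisulfite non-conversion floor;
* replicate-to-replicate biological variability modelled as locus-level
  epimutation: per sample, a methylated locus may shift its latent level
  by a random amount, at a high rate inside designated hypervariable (HV)
  loci and a low rate elsewhere.  This is what makes single-replicate CHH
  comparisons of identical genotypes yield spurious candidate windows that
  replicate intersection and HV subtraction then remove;
* cytosine-level overdispersion: per-cytosine latent levels are drawn from
  a Beta around the locus level (dispersion ``rho``) and read counts are
  binomial at Poisson coverage, i.e. beta-binomial counts overall;
* planted differentially methylated regions with known per-context effect
  sizes (a configurable fraction planted below the calling threshold), and
  planted fold-changed small-RNA clusters -- the ground truth for recovery
  tests;
* 24-nt-dominated small-RNA clusters with negative-binomial abundance.

Identical configuration (including the seed) reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

from . import genome as genome_mod
from .genome import SnpRecord, cytosine_sites_frame, write_fasta, write_snp_table
from .intervals import write_bed, write_gff3
from .methcounts import SampleMethylome

HYPO = "hypo_in_mutant"


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), *stream])


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulation (defaults are the package's
    standard desk-scale scenario; all rates/levels documented in the
    methods note)."""

    chrom_lengths: Dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    control_chrom: str = "chrC"
    control_length: int = 100_000
    gc: float = 0.36

    # methylated-locus layout and latent levels
    baseline: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.35, "CHH": 0.10}
    )
    te_fraction: float = 0.10
    te_size: Tuple[int, int] = (500, 3000)
    gene_fraction: float = 0.15
    gene_size: Tuple[int, int] = (1000, 4000)

    # replicate variability: locus-level epimutation
    n_hv: int = 30
    p_epi_hv: float = 0.5
    p_epi_bg: float = 0.02
    epi_delta: Tuple[float, float] = (0.15, 0.4)

    # read-count model
    coverage_mean: float = 10.0
    rho: float = 0.05
    conversion_rate: float = 0.995

    # planted DMRs
    n_dmrs_per_context: Dict[str, int] = dataclasses.field(
        default_factory=lambda: {"CG": 50, "CHG": 50, "CHH": 50}
    )
    delta_m: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.4, "CHH": 0.3}
    )
    subthreshold_fraction: float = 0.2
    delta_m_subthreshold: float = 0.05
    dmr_size: Tuple[int, int] = (300, 800)
    dmr_te_fraction: float = 0.7  # fraction of planted DMRs placed inside TEs
    min_cytosines_per_dmr: int = 4

    replicates: int = 2
    n_snps: int = 200

    # small RNA
    n_clusters: int = 300
    cluster_size: Tuple[int, int] = (200, 400)
    cluster_mean_reads: float = 400.0
    nb_dispersion: float = 100.0
    n_background_reads: int = 30_000
    n_dsrs: int = 20
    dsr_fold: float = 0.1
    read_length_probs: Dict[int, float] = dataclasses.field(
        default_factory=lambda: {20: 0.05, 21: 0.20, 22: 0.05, 23: 0.10, 24: 0.60}
    )

    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("gc", self.gc), ("rho", self.rho),
                        ("conversion_rate", self.conversion_rate),
                        ("p_epi_hv", self.p_epi_hv), ("p_epi_bg", self.p_epi_bg),
                        ("subthreshold_fraction", self.subthreshold_fraction)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for ctx, m in self.baseline.items():
            if not (0 <= m <= 1):
                raise ValueError(f"baseline[{ctx}] out of [0, 1]")
        if min(self.chrom_lengths.values(), default=1) <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("te_size", "gene_size", "epi_delta", "dmr_size", "cluster_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "read_length_probs" in raw:
            raw["read_length_probs"] = {int(k): v for k, v in raw["read_length_probs"].items()}
        return cls(**raw)


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth of one simulated study (what the pipeline should find)."""

    dmrs: pd.DataFrame      # chrom start end context direction delta_m above_threshold
    dsrs: pd.DataFrame      # chrom start end fold
    hv: pd.DataFrame        # chrom start end
    loci: pd.DataFrame      # chrom start end kind(te|gene) is_hv
    clusters: pd.DataFrame  # chrom start end mean_reads is_dsr fold
    seed: int


@dataclasses.dataclass
class Simulation:
    """A simulated study: genome + annotation + truth (samples drawn on
    demand with :func:`simulate_methylome` / :func:`simulate_smallrna`)."""

    config: SimConfig
    genome: Dict[str, str]
    genes: pd.DataFrame
    tes: pd.DataFrame
    snps: list
    truth: SimulationTruth
    sites: pd.DataFrame  # cached cytosine site frame

    @property
    def analysis_chrom_lengths(self) -> Dict[str, int]:
        return dict(self.config.chrom_lengths)


def _place_intervals(
    rng: np.random.Generator,
    occupied: Dict[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    n: int,
    size_range: Tuple[int, int],
    max_tries: int = 10_000,
    accept=None,
) -> pd.DataFrame:
    """Place n non-overlapping intervals uniformly, rejecting collisions."""
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    tries = 0
    while len(rows) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} intervals of size {size_range}; "
                "genome too crowded for this configuration"
            )
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        length = chrom_lengths[chrom]
        if size >= length:
            continue
        start = int(rng.integers(0, length - size))
        if occupied[chrom][start : start + size].any():
            continue
        if accept is not None and not accept(chrom, start, start + size):
            continue
        occupied[chrom][start : start + size] = True
        rows.append((chrom, start, start + size))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_genome(config: SimConfig) -> Simulation:
    """Draw the genome, locus layout, planted truth, annotation and SNPs."""
    rng = _rng(config.seed, 1)
    genome: Dict[str, str] = {}
    all_lengths = dict(config.chrom_lengths)
    all_lengths[config.control_chrom] = config.control_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2,
                  (1 - config.gc) / 2])
    for chrom in sorted(all_lengths):
        draw = rng.choice(bases, size=all_lengths[chrom], p=p)
        genome[chrom] = draw.tobytes().decode("ascii")

    sites = cytosine_sites_frame(genome)

    occupied = {
        c: np.zeros(length, dtype=bool) for c, length in config.chrom_lengths.items()
    }
    genome_span = sum(config.chrom_lengths.values())
    n_te = max(1, int(config.te_fraction * genome_span / np.mean(config.te_size)))
    n_gene = max(1, int(config.gene_fraction * genome_span / np.mean(config.gene_size)))
    tes = _place_intervals(rng, occupied, config.chrom_lengths, n_te, config.te_size)
    genes = _place_intervals(rng, occupied, config.chrom_lengths, n_gene, config.gene_size)

    n_hv = min(config.n_hv, len(tes))
    hv_idx = np.sort(rng.choice(len(tes), size=n_hv, replace=False))
    hv = tes.iloc[hv_idx][["chrom", "start", "end"]].reset_index(drop=True)

    loci = pd.concat(
        [tes.assign(kind="te"), genes.assign(kind="gene")], ignore_index=True
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    loci["is_hv"] = False
    hv_keys = set(map(tuple, hv[["chrom", "start"]].itertuples(index=False)))
    loci["is_hv"] = [
        (r.chrom, r.start) in hv_keys and r.kind == "te"
        for r in loci.itertuples(index=False)
    ]

    # planted DMRs: mostly inside TE loci (the realistic location of
    # RdDM-controlled regions), the rest in unannotated space; never in HV
    # loci, never overlapping each other; each needs enough context sites
    site_pos = {
        (chrom, ctx): grp["pos"].to_numpy()
        for (chrom, ctx), grp in sites.groupby(["chrom", "context"], observed=True)
    }
    dmr_occupied = {
        c: np.zeros(length, dtype=bool) for c, length in config.chrom_lengths.items()
    }
    te_hosts = [
        (r.chrom, r.start, r.end)
        for i, r in enumerate(tes.itertuples(index=False))
        if i not in set(hv_idx)
    ]

    def enough_sites(chrom, start, end, ctx):
        pos = site_pos.get((chrom, ctx))
        if pos is None:
            return False
        k = np.searchsorted(pos, end) - np.searchsorted(pos, start)
        return k >= config.min_cytosines_per_dmr

    dmr_rows = []
    for ctx in sorted(config.n_dmrs_per_context):
        n = config.n_dmrs_per_context[ctx]
        if n == 0:
            continue
        n_sub = int(round(config.subthreshold_fraction * n))
        placed_rows = []
        for _ in range(n):
            for attempt in range(10_000):
                size = int(rng.integers(config.dmr_size[0], config.dmr_size[1] + 1))
                in_te = rng.random() < config.dmr_te_fraction and te_hosts
                if in_te:
                    chrom, lo, hi = te_hosts[int(rng.integers(len(te_hosts)))]
                    if hi - lo <= size:
                        continue
                    start = lo + int(rng.integers(0, hi - lo - size))
                else:
                    chrom = sorted(config.chrom_lengths)[
                        int(rng.integers(len(config.chrom_lengths)))
                    ]
                    start = int(rng.integers(0, config.chrom_lengths[chrom] - size))
                    if occupied[chrom][start : start + size].any():
                        continue
                if dmr_occupied[chrom][start : start + size].any():
                    continue
                if not enough_sites(chrom, start, start + size, ctx):
                    continue
                dmr_occupied[chrom][start : start + size] = True
                placed_rows.append((chrom, start, start + size))
                break
            else:
                raise ValueError("could not place planted DMRs; genome too crowded")
        placed = pd.DataFrame(placed_rows, columns=["chrom", "start", "end"])
        placed = placed.sort_values(["chrom", "start"]).reset_index(drop=True)
        sub = np.zeros(n, dtype=bool)
        if n_sub:
            sub[np.sort(rng.choice(n, size=n_sub, replace=False))] = True
        placed["context"] = ctx
        placed["direction"] = HYPO
        placed["delta_m"] = np.where(
            sub, config.delta_m_subthreshold, config.delta_m[ctx]
        )
        placed["above_threshold"] = ~sub
        dmr_rows.append(placed)
    dmrs = (
        pd.concat(dmr_rows, ignore_index=True)
        if dmr_rows
        else pd.DataFrame(
            columns=["chrom", "start", "end", "context", "direction",
                     "delta_m", "above_threshold"]
        )
    )

    # small-RNA clusters (may sit anywhere except planted-DMR space)
    clusters = _place_intervals(
        rng, occupied, config.chrom_lengths, config.n_clusters, config.cluster_size
    )
    clusters["mean_reads"] = config.cluster_mean_reads
    clusters["is_dsr"] = False
    clusters["fold"] = 1.0
    n_dsr = min(config.n_dsrs, len(clusters))
    dsr_idx = np.sort(rng.choice(len(clusters), size=n_dsr, replace=False))
    clusters.loc[clusters.index[dsr_idx], "is_dsr"] = True
    clusters.loc[clusters.index[dsr_idx], "fold"] = config.dsr_fold
    dsrs = clusters[clusters["is_dsr"]][["chrom", "start", "end", "fold"]].reset_index(
        drop=True
    )

    # SNP table consistent with the genome by construction
    snps = []
    chroms = sorted(config.chrom_lengths)
    for _ in range(config.n_snps):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
        ref = genome[chrom][pos - 1]
        alt = str(rng.choice(sorted({"A", "C", "G", "T"} - {ref})))
        snps.append(SnpRecord(chrom, pos, ref, alt))
    # one substitution per position
    snps = sorted({(s.chrom, s.pos): s for s in snps}.values(),
                  key=lambda s: (s.chrom, s.pos))

    truth = SimulationTruth(
        dmrs=dmrs, dsrs=dsrs, hv=hv, loci=loci, clusters=clusters, seed=config.seed
    )
    return Simulation(
        config=config, genome=genome, genes=genes, tes=tes, snps=snps,
        truth=truth, sites=sites,
    )


def _interval_index(
    chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Index of the (sorted, non-overlapping) interval containing each
    position, or -1."""
    out = np.full(len(pos), -1, dtype=np.int64)
    if len(intervals) == 0:
        return out
    for c, grp in intervals.groupby("chrom", sort=False):
        sel = np.nonzero(chrom == c)[0]
        if sel.size == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (idx >= 0) & (pos[sel] < ends[np.clip(idx, 0, None)])
        out[sel[ok]] = grp.index.to_numpy()[idx[ok]]
    return out


_ROLE_CODE = {"wt": 0, "mut": 1}
_CTX_CODE = {"CG": 0, "CHG": 1, "CHH": 2}


def simulate_methylome(
    sim: Simulation, role: str, replicate: int, sample_id: str | None = None
) -> SampleMethylome:
    """Draw one bisulfite library for a wild-type- or mutant-role sample.

    The latent methylome is: background ~0 everywhere; TE loci at the
    per-context baselines; gene loci at the CG baseline (CG only); inside
    a planted DMR of context c, the wild type at min(baseline_c + delta_m,
    0.95) and the mutant delta_m lower.  Locus-level epimutation and
    cytosine-level beta noise are then drawn per sample, and counts are
    binomial at Poisson coverage after applying the bisulfite conversion
    rate.  Epimutation never touches planted regions, so planted effects
    are consistent across replicates.
    """
    if role not in _ROLE_CODE:
        raise ValueError("role must be 'wt' or 'mut'")
    cfg = sim.config
    rng = _rng(cfg.seed, 2, _ROLE_CODE[role], int(replicate))
    sites = sim.sites
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ctx = sites["context"].astype(str).to_numpy()

    level = np.zeros(len(sites), dtype=np.float64)

    # locus baselines (TE: all contexts; gene body: CG only)
    loci = sim.truth.loci
    loc_idx = _interval_index(chrom, pos, loci)
    in_locus = loc_idx >= 0
    kind = np.full(len(sites), "", dtype=object)
    kind[in_locus] = loci["kind"].to_numpy()[loc_idx[in_locus]]
    for c, base in cfg.baseline.items():
        level[(kind == "te") & (ctx == c)] = base
    level[(kind == "gene") & (ctx == "CG")] = cfg.baseline["CG"]

    # per-sample locus epimutation
    p_epi = np.where(loci["is_hv"].to_numpy(), cfg.p_epi_hv, cfg.p_epi_bg)
    hit = rng.random(len(loci)) < p_epi
    delta = rng.uniform(cfg.epi_delta[0], cfg.epi_delta[1], size=len(loci))
    sign = np.where(rng.random(len(loci)) < 0.5, -1.0, 1.0)
    shift = np.where(hit, sign * delta, 0.0)
    level[in_locus] = np.clip(level[in_locus] + shift[loc_idx[in_locus]], 0.0, 0.95)

    # planted DMRs override everything in their context
    planted = sim.truth.dmrs
    if len(planted):
        for c in sorted(planted["context"].unique()):
            pc = planted[planted["context"] == c].reset_index(drop=True)
            pidx = _interval_index(chrom, pos, pc)
            mask = (pidx >= 0) & (ctx == c)
            wt_level = np.minimum(cfg.baseline[c] + pc["delta_m"].to_numpy(), 0.95)
            lv = wt_level[pidx[mask]]
            if role == "mut":
                lv = np.clip(lv - pc["delta_m"].to_numpy()[pidx[mask]], 0.0, 1.0)
            level[mask] = lv

    # cytosine-level beta noise around the latent locus level
    if cfg.rho > 0:
        interior = (level > 0) & (level < 1)
        r = (1 - cfg.rho) / cfg.rho
        lv = level[interior]
        level[interior] = rng.beta(lv * r, (1 - lv) * r)

    p_read = level + (1.0 - level) * (1.0 - cfg.conversion_rate)
    coverage = rng.poisson(cfg.coverage_mean, size=len(sites))
    n_meth = rng.binomial(coverage, p_read)
    covered = coverage > 0
    records = pd.DataFrame(
        {
            "chrom": chrom[covered],
            "pos": pos[covered],
            "strand": sites["strand"].astype(str).to_numpy()[covered],
            "context": ctx[covered],
            "n_meth": n_meth[covered].astype(np.int64),
            "n_unmeth": (coverage - n_meth)[covered].astype(np.int64),
        }
    )
    return SampleMethylome(
        sample_id=sample_id or f"{role}_rep{replicate}",
        genotype=role,
        replicate=str(replicate),
        records=records,
    )


def simulate_smallrna(
    sim: Simulation, role: str, replicate: int
) -> pd.DataFrame:
    """Draw one small-RNA library (BED-like frame of mapped read positions).

    Cluster read counts are negative-binomial around ``cluster_mean_reads``
    (dispersion parameter ``nb_dispersion``); in mutant-role libraries,
    planted DSR clusters have their mean multiplied by the planted fold
    change.  Background reads are uniform over the analysis chromosomes.
    Read lengths follow the configured distribution (24-nt mode).
    """
    if role not in _ROLE_CODE:
        raise ValueError("role must be 'wt' or 'mut'")
    cfg = sim.config
    rng = _rng(cfg.seed, 3, _ROLE_CODE[role], int(replicate))
    clusters = sim.truth.clusters
    means = clusters["mean_reads"].to_numpy().astype(float)
    if role == "mut":
        means = means * np.where(
            clusters["is_dsr"].to_numpy(), clusters["fold"].to_numpy(), 1.0
        )
    size = cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + means))

    lengths_all = np.array(sorted(cfg.read_length_probs), dtype=np.int64)
    probs = np.array([cfg.read_length_probs[k] for k in lengths_all], dtype=float)
    probs /= probs.sum()

    chroms_rep, starts, lengths = [], [], []
    for (c_chrom, c_start, c_end), n in zip(
        clusters[["chrom", "start", "end"]].itertuples(index=False, name=None), counts
    ):
        if n == 0:
            continue
        ln = rng.choice(lengths_all, size=n, p=probs)
        # read lies entirely within its cluster
        hi = np.maximum(c_end - ln, c_start + 1)
        st = c_start + (rng.random(n) * (hi - c_start)).astype(np.int64)
        chroms_rep.append(np.full(n, c_chrom, dtype=object))
        starts.append(st)
        lengths.append(ln)
    # background reads spread over the analysis genome
    chrom_names = sorted(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    bg_chrom_idx = rng.choice(len(chrom_names), size=cfg.n_background_reads,
                              p=lens / lens.sum())
    bg_len = rng.choice(lengths_all, size=cfg.n_background_reads, p=probs)
    bg_pos = (rng.random(cfg.n_background_reads) * (lens[bg_chrom_idx] - bg_len)).astype(
        np.int64
    )
    chroms_rep.append(np.array(chrom_names, dtype=object)[bg_chrom_idx])
    starts.append(bg_pos)
    lengths.append(bg_len)

    chrom = np.concatenate(chroms_rep)
    start = np.concatenate(starts).astype(np.int64)
    length = np.concatenate(lengths).astype(np.int64)
    n_reads = len(start)
    strand = np.where(rng.random(n_reads) < 0.5, "+", "-")
    reads = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + length,
            "name": [f"sr{i}" for i in range(n_reads)],
            "score": 0,
            "strand": strand,
        }
    )
    reads = reads.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    reads["name"] = [f"sr{i}" for i in range(n_reads)]
    return reads


def write_simulation(sim: Simulation, outdir: str | Path) -> Dict[str, Path]:
    """Write genome FASTA, GFF3 annotation, HV BED, SNP TSV, truth tables
    and a YAML manifest; per-sample files are written by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["fasta"] = outdir / "genome.fa"
    write_fasta(sim.genome, paths["fasta"])

    feats = pd.concat(
        [
            sim.genes.assign(type="gene"),
            sim.tes.assign(type="transposable_element"),
        ],
        ignore_index=True,
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    feats["strand"] = "+"
    feats["id"] = [f"feat{i}" for i in range(len(feats))]
    paths["gff3"] = outdir / "annotation.gff3"
    write_gff3(feats, paths["gff3"])

    paths["hv"] = outdir / "hv_regions.bed"
    write_bed(sim.truth.hv, paths["hv"])

    paths["snps"] = outdir / "snps.tsv"
    write_snp_table(sim.snps, paths["snps"])

    paths["truth_dmrs"] = outdir / "truth_dmrs.tsv"
    sim.truth.dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    paths["truth_dsrs"] = outdir / "truth_dsrs.tsv"
    sim.truth.dsrs.to_csv(paths["truth_dsrs"], sep="\t", index=False)
    paths["truth_clusters"] = outdir / "truth_clusters.tsv"
    sim.truth.clusters.to_csv(paths["truth_clusters"], sep="\t", index=False)

    paths["manifest"] = outdir / "manifest.yaml"
    sim.config.to_yaml(paths["manifest"])
    return paths
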