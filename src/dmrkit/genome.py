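"""Genome handling: FASTA I/O, pseudo-genome construction, cytosine contexts.

Plant methylomes are described in three cytosine sequence contexts -- CG,
CHG and CHH (H = A, C or T) -- determined by the two bases immediately
downstream of the cytosine on its own strand.  Samples from a diverged
accession are mapped against a *pseudo-genome*: the reference with that
accession's SNPs substituted in, which preserves reference coordinates and
lets differential regions be compared across accessions.

Coordinates are 0-based half-open internally; 1-based only in file formats
that require it (the SNP table).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

VALID_BASES = frozenset("ACGTN")
CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, name: str = "?") -> str:
    """Uppercase a nucleotide string and verify its alphabet is A/C/G/T/N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"sequence {name!r} contains invalid characters: {sorted(bad)!r}"
        )
    if len(seq) == 0:
        raise ValueError(f"sequence {name!r} is empty")
    return seq


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    fa = Fasta(str(path), read_long_names=False, rebuild=True, build_index=True)
    genome = {name: normalize_sequence(str(fa[name][:]), name) for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """A single-base substitution; ``pos`` is 1-based as in the table format."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} has ref == alt")
        for base, label in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in {"A", "C", "G", "T"}:
                raise ValueError(
                    f"SNP at {self.chrom}:{self.pos}: {label} base {base!r} invalid"
                )
        if self.pos < 1:
            raise ValueError(f"SNP position must be 1-based positive, got {self.pos}")


def read_snp_table(path: str | Path) -> List[SnpRecord]:
    """Read a 4-column TSV (chrom, pos[1-based], ref, alt) with a header line.

    Indels (multi-base ref or alt, or '-' alleles) are rejected: the
    pseudo-genome construction is substitution-only so that coordinates
    stay comparable with the reference.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"SNP table {path} must have 4 columns")
    snps = []
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = row[0], int(row[1]), str(row[2]), str(row[3])
        if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
            raise ValueError(
                f"indel at {chrom}:{pos} (ref={ref!r}, alt={alt!r}); "
                "only single-base substitutions are supported"
            )
        snps.append(SnpRecord(chrom, pos, ref.upper(), alt.upper()))
    return snps


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def apply_snp_table(
    genome: Mapping[str, str], snps: Iterable[SnpRecord]
) -> Dict[str, str]:
    """Build a pseudo-genome by substituting SNP alleles into the reference.

    Every SNP's ref allele must match the reference base at its position;
    a mismatch signals the wrong genome build and raises ``ValueError``.
    Chromosome lengths (and hence all coordinates) are unchanged.
    """
    out = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for s in snps:
        if s.chrom not in out:
            raise ValueError(f"SNP chromosome {s.chrom!r} not in genome")
        arr = out[s.chrom]
        if not (1 <= s.pos <= len(arr)):
            raise ValueError(
                f"SNP position {s.chrom}:{s.pos} outside chromosome (len {len(arr)})"
            )
        have = chr(arr[s.pos - 1])
        if have != s.ref:
            raise ValueError(
                f"SNP ref mismatch at {s.chrom}:{s.pos}: table says {s.ref}, "
                f"genome has {have}"
            )
        arr[s.pos - 1] = ord(s.alt)
    return {name: arr.decode("ascii") for name, arr in out.items()}


@dataclasses.dataclass(frozen=True)
class CytosineSite:
    """A cytosine (0-based ``pos``) with its strand and sequence context."""

    chrom: str
    pos: int
    strand: str
    context: str


def cytosine_sites_frame(genome: Mapping[str, str]) -> pd.DataFrame:
    """Vectorised context classification over a genome.

    Returns a DataFrame (chrom, pos, strand, context) with one row per
    cytosine on either strand.  Context is read 5'->3' on the site's own
    strand from the next two bases: CG if the next base is G, CHG if the
    pattern is C-H-G, CHH if C-H-H.  Sites within 2 bp of the chromosome
    end, or whose context window contains N, are omitted (context
    undefined).  Rows are sorted by (chrom, pos, strand).
    """
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        if n < 3:
            continue
        C, G, N = ord("C"), ord("G"), ord("N")
        is_h = (arr != G) & (arr != N)  # H = A/C/T

        # plus strand: C at i, context from bases i+1, i+2
        i = np.nonzero(arr[: n - 2] == C)[0]
        b1, b2 = arr[i + 1], arr[i + 2]
        ok = (b1 != N) & (b2 != N)
        i, b1, b2 = i[ok], b1[ok], b2[ok]
        ctx_p = np.where(b1 == G, 0, np.where(b2 == G, 1, 2))

        # minus strand: G at i on reference; on the minus strand this reads C
        # with downstream bases complement(arr[i-1]), complement(arr[i-2]).
        # complement(x) == G  <=>  x == C; complement H <=> H on reference.
        j = np.nonzero(arr[2:] == G)[0] + 2
        c1, c2 = arr[j - 1], arr[j - 2]
        ok = (c1 != N) & (c2 != N)
        j, c1, c2 = j[ok], c1[ok], c2[ok]
        ctx_m = np.where(c1 == C, 0, np.where(c2 == C, 1, 2))

        pos = np.concatenate([i, j])
        strand = np.concatenate(
            [np.zeros(len(i), dtype=np.uint8), np.ones(len(j), dtype=np.uint8)]
        )
        ctx = np.concatenate([ctx_p, ctx_m])
        order = np.lexsort((strand, pos))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[order].astype(np.int64),
                    "strand": pd.Categorical.from_codes(
                        strand[order], categories=["+", "-"]
                    ),
                    "context": pd.Categorical.from_codes(
                        ctx[order], categories=list(CONTEXTS)
                    ),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Categorical([], categories=["+", "-"]),
                "context": pd.Categorical([], categories=list(CONTEXTS)),
            }
        )
    return pd.concat(frames, ignore_index=True)


def classify_cytosine_contexts(genome: Mapping[str, str]) -> List[CytosineSite]:
    """Classify every cytosine in the genome; see :func:`cytosine_sites_frame`."""
    df = cytosine_sites_frame(genome)
    return [
        CytosineSite(r.chrom, int(r.pos), str(r.strand), str(r.context))
        for r in df.itertuples(index=False)
    ]
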