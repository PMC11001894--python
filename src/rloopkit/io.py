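"""Readers and writers for the plain-text genomics formats the toolkit uses.

Coverage is exchanged as fixed-bin bedGraph, peaks as ENCODE broadPeak,
gene models as GTF, simulated truth loci as BED6, and tabular data as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import GeneModel
    from .peaks import Peak

__all__ = [
    "CoverageTrack",
    "read_bedgraph",
    "read_fasta",
    "write_fasta",
    "write_gtf",
    "write_broadpeak",
    "read_broadpeak",
]


@dataclass
class CoverageTrack:
    """Binned read counts along one chromosome (fixed bin width, 0-based)."""

    chrom: str
    bin_bp: int
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_bp < 1:
            raise ValueError("bin_bp must be >= 1")
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key}={val}\n")
            for i, c in enumerate(self.counts):
                start = i * self.bin_bp
                fh.write(f"{self.chrom}\t{start}\t{start + self.bin_bp}\t{c:g}\n")


def read_bedgraph(path) -> CoverageTrack:
    """Read a fixed-bin bedGraph written by :meth:`CoverageTrack.write_bedgraph`."""
    chrom = None
    starts: list[int] = []
    values: list[float] = []
    meta: dict = {}
    bin_bp = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("track"):
                continue
            c, s, e, v = line.split("\t")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError("multi-chromosome bedGraph not supported")
            s, e = int(s), int(e)
            if bin_bp is None:
                bin_bp = e - s
            elif e - s != bin_bp:
                raise ValueError("bedGraph bins are not of uniform width")
            starts.append(s)
            values.append(float(v))
    if chrom is None or bin_bp is None:
        raise ValueError(f"empty bedGraph: {path}")
    order = np.argsort(starts)
    expected = np.arange(len(starts)) * bin_bp
    if not np.array_equal(np.asarray(starts)[order], expected):
        raise ValueError("bedGraph bins do not tile the chromosome from 0")
    return CoverageTrack(chrom, bin_bp, np.asarray(values)[order], meta)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence mapping."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: Iterable["GeneModel"], path, source: str = "rloopkit") -> None:
    """Write gene models as GTF (1-based, closed intervals per the format)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            rows = [("gene", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            if g.utr5 is not None:
                rows.append(("five_prime_utr", *g.utr5))
            if g.utr3 is not None:
                rows.append(("three_prime_utr", *g.utr3))
            for feature, s, e in rows:
                fh.write(
                    f"{g.chrom}\t{source}\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def write_broadpeak(peaks: Iterable["Peak"], path) -> None:
    """ENCODE broadPeak: -log10(p) and -log10(q) in columns 8 and 9."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            neglog_p = -np.log10(max(p.p_value, 5e-324))
            neglog_q = -np.log10(max(p.q_value, 5e-324)) if p.q_value is not None else -1
            score = int(min(1000, round(10 * neglog_q))) if p.q_value is not None else 0
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t{score}\t.\t"
                f"{p.fold_enrichment:.4f}\t{neglog_p:.4f}\t{neglog_q:.4f}\n"
            )


def read_broadpeak(path) -> list["Peak"]:
    from .peaks import Peak

    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            p_value = 10 ** (-float(f[7]))
            q_value = 10 ** (-float(f[8])) if float(f[8]) >= 0 else None
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    p_value=min(p_value, 1.0),
                    q_value=None if q_value is None else min(q_value, 1.0),
                    fold_enrichment=float(f[6]),
                )
            )
    return peaks


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
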