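"""Readers and writers for the standard text formats: GTF, BED6/BED12,
SAM (read-only, via pysam), bedGraph, chrom-sizes TSV and FASTA.

GTF coordinates (1-based, closed) are converted to the internal 0-based
half-open convention on read and back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, GeneModel, GenomeAnnotation, ReadInterval

__all__ = [
    "AnnotationReport",
    "read_annotation",
    "write_annotation",
    "read_intervals",
    "write_intervals_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed record in a text format; message names the line number."""


@dataclass
class AnnotationReport:
    """Genes rejected while loading an annotation, with reasons."""

    rejected: dict[str, str] = field(default_factory=dict)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().strip(";").split(";"):
        piece = piece.strip()
        if not piece:
            continue
        key, _, val = piece.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(
    path: str,
    format: str = "gtf",
    chrom_sizes: dict[str, int] | None = None,
    blacklist: list[tuple[str, int, int]] | None = None,
    report: AnnotationReport | None = None,
) -> GenomeAnnotation:
    """Load gene models from a GTF or BED12 file.

    GTF needs ``gene`` and ``exon`` features carrying a ``gene_id`` attribute;
    exon-only GTFs infer the gene span from the exon hull. If ``chrom_sizes``
    is omitted it is inferred as the maximum gene end per chromosome. Genes
    violating model invariants are dropped and recorded in ``report``.
    """
    if format not in ("gtf", "bed12"):
        raise ValueError(f"unknown annotation format {format!r}")
    report = report if report is not None else AnnotationReport()
    raw: dict[str, dict] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    chrom, _, feat, start1, end1, _, strand, _, attrs = fields[:9]
                    if feat not in ("gene", "exon", "transcript"):
                        continue
                    gid = _parse_gtf_attributes(attrs).get("gene_id")
                    if gid is None:
                        raise ValueError("missing gene_id attribute")
                    start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
                    entry = raw.setdefault(
                        gid, {"chrom": chrom, "strand": strand, "span": None, "exons": []}
                    )
                    if feat == "gene":
                        if entry["span"] is not None:
                            raise ValueError(f"duplicate gene_id {gid!r}")
                        entry["span"] = (start, end)
                    elif feat == "exon":
                        entry["exons"].append((start, end))
                else:  # bed12
                    if len(fields) < 12:
                        raise ValueError("expected 12 tab-separated BED12 fields")
                    chrom, start, end, gid, _, strand = fields[:6]
                    start, end = int(start), int(end)
                    n_blocks = int(fields[9])
                    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                    if len(sizes) != n_blocks or len(offsets) != n_blocks:
                        raise ValueError("block count does not match block lists")
                    if gid in raw:
                        raise ValueError(f"duplicate gene_id {gid!r}")
                    raw[gid] = {
                        "chrom": chrom,
                        "strand": strand,
                        "span": (start, end),
                        "exons": [(start + o, start + o + s) for o, s in zip(offsets, sizes)],
                    }
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for gid, entry in raw.items():
        exons = sorted(set(entry["exons"]))
        span = entry["span"]
        if span is None:
            if not exons:
                report.rejected[gid] = "no span and no exons"
                continue
            span = (min(s for s, _ in exons), max(e for _, e in exons))
        try:
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                start=span[0],
                end=span[1],
                exons=tuple(exons),
            )
        except ValueError as exc:
            report.rejected[gid] = str(exc)
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes.values():
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes, blacklist=list(blacklist or []))


def write_annotation(annotation: GenomeAnnotation, path: str, format: str = "bed12") -> None:
    """Write gene models as BED12 (one line per gene, exons as blocks)."""
    if format != "bed12":
        raise ValueError("only bed12 output is supported")
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{gid}\t0\t{g.strand}\t{g.start}\t{g.end}\t0\t"
                f"{len(exons)}\t{sizes}\t{offsets}\n"
            )


def read_intervals(
    path: str,
    format: str = "bed",
    chrom_sizes: dict[str, int] | None = None,
    on_unknown_chrom: str = "error",
) -> tuple[list[ReadInterval], int]:
    """Load aligned reads as intervals from BED or SAM.

    Returns ``(reads, n_skipped)`` where skipped records are unmapped SAM
    reads plus (if ``on_unknown_chrom="skip"``) reads on unlisted
    chromosomes.
    """
    reads: list[ReadInterval] = []
    skipped = 0

    def _admit(chrom: str, start: int, end: int, strand: str, lineno) -> None:
        nonlocal skipped
        if chrom_sizes is not None and chrom not in chrom_sizes:
            if on_unknown_chrom == "skip":
                warnings.warn(f"{path}:{lineno}: skipping read on unknown chromosome {chrom!r}")
                skipped += 1
                return
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or end <= start:
            raise ParseError(f"{path}:{lineno}: invalid coordinates [{start}, {end})")
        if strand not in ("+", "-"):
            strand = "+"  # BED '.' strand
        reads.append(ReadInterval(chrom, start, end, strand))

    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
                strand = fields[5] if len(fields) >= 6 else "+"
                _admit(fields[0], int(fields[1]), int(fields[2]), strand, lineno)
    elif format == "sam":
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for i, rec in enumerate(sam.fetch(until_eof=True), start=1):
                if rec.is_unmapped:
                    skipped += 1
                    continue
                strand = "-" if rec.is_reverse else "+"
                _admit(rec.reference_name, rec.reference_start, rec.reference_end, strand, i)
    else:
        raise ValueError(f"unknown read format {format!r}")
    return reads, skipped


def write_intervals_bed(reads: list[ReadInterval], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


def write_bedgraph(track: CoverageTrack, path: str, omit_zero: bool = True) -> None:
    """Write a coverage track as sorted, run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        fh.write(f"# bin_size={track.bin_size} total_mapped={track.total_mapped} "
                 f"normalization={track.normalization}\n")
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            size = track.chrom_sizes[chrom]
            if len(vals) == 0:
                continue
            change = np.nonzero(np.diff(vals))[0]
            run_starts = np.concatenate(([0], change + 1))
            run_ends = np.concatenate((change + 1, [len(vals)]))
            for rs, re_ in zip(run_starts, run_ends):
                v = vals[rs]
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{rs * track.bin_size}\t{min(re_ * track.bin_size, size)}\t{v:g}\n")


def read_bedgraph(path: str, chrom_sizes: dict[str, int], bin_size: int = 10) -> CoverageTrack:
    """Read a bedGraph back into a binned track (records must align to bins)."""
    track = CoverageTrack(bin_size, chrom_sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in track.values:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            b0 = start // bin_size
            b1 = (end - 1) // bin_size + 1
            track.values[chrom][b0:b1] = val
    return track


def read_chrom_sizes(path: str) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            out[fields[0]] = int(fields[1])
    return out


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")
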