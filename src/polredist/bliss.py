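"""BLISS double-strand-break quantification.

Pipeline: barcode demultiplexing (one mismatch), UMI deduplication,
in-silico restriction digestion of the genome, counting of deduplicated
breaks at restriction-site windows, cross-sample normalization anchored on
the restriction-enzyme (AsiSI-type) cuts, and genomic-region annotation.

The restriction anchor works because the enzyme cuts every sample's genome
with the same efficiency: differences in restriction-window counts reflect
library depth, so scaling all samples to the smallest restriction count and
subsampling genome-wide puts the remaining (biological) breaks on a common
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeAnnotation

__all__ = [
    "BreakEvent",
    "RestrictionSiteSet",
    "BlissSample",
    "demultiplex",
    "dedup",
    "digest",
    "count_at_sites",
    "asisi_normalize",
    "annotate_breaks",
    "relative_break_counts",
]

DEFAULT_MOTIF = "GCGATCGC"  # AsiSI recognition site (self-reverse-complementary)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class BreakEvent:
    """One deduplicated break: position, strand and molecular identifier."""

    chrom: str
    pos: int
    strand: str
    umi: str


@dataclass
class RestrictionSiteSet:
    """Exact motif occurrences per chromosome, sorted ascending."""

    motif: str
    positions: dict[str, np.ndarray]
    window: int = 250

    def total(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class BlissSample:
    """Deduplicated break events of one sample plus normalization state."""

    sample_id: str
    events: list[BreakEvent]
    asisi_count: int = 0
    normalized: bool = False

    @property
    def total_dedup(self) -> int:
        return len(self.events)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: pd.DataFrame,
    barcode_map: dict[str, str],
    max_mismatch: int = 1,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Assign reads to samples by barcode, tolerating ``max_mismatch``.

    ``barcode_map`` maps barcode sequence -> sample id. A read is assigned
    to the unique barcode within Hamming distance ``max_mismatch``; ties and
    larger distances are left unassigned. Barcode sets whose pairwise
    distance is <= 2 * max_mismatch can produce ambiguous reads; a warning
    is emitted and ties are discarded.
    """
    barcodes = list(barcode_map)
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("barcodes must have equal length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if _hamming(a, b) <= 2 * max_mismatch:
                import warnings

                warnings.warn(
                    f"barcodes {a!r} and {b!r} are within {2 * max_mismatch} mismatches; "
                    "ambiguous reads will be discarded"
                )
    # assignment table over the distinct observed barcodes only
    assign: dict[str, str | None] = {}
    for obs in reads["barcode"].unique():
        matches = [b for b in barcodes if _hamming(obs, b) <= max_mismatch]
        assign[obs] = barcode_map[matches[0]] if len(matches) == 1 else None
    sample_of = reads["barcode"].map(assign)
    unassigned = int(sample_of.isna().sum())
    out = {
        sid: reads[sample_of == sid].reset_index(drop=True)
        for sid in barcode_map.values()
    }
    return out, unassigned


def dedup(reads: pd.DataFrame) -> list[BreakEvent]:
    """One BreakEvent per distinct (chrom, pos, strand, umi); order-independent."""
    uniq = (
        reads[["chrom", "pos", "strand", "umi"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos", "strand", "umi"])
    )
    return [
        BreakEvent(str(r.chrom), int(r.pos), str(r.strand), str(r.umi))
        for r in uniq.itertuples()
    ]


def digest(
    sequences: dict[str, str],
    motif: str = DEFAULT_MOTIF,
    window: int = 250,
) -> RestrictionSiteSet:
    """In-silico digestion: all exact occurrences of ``motif``.

    A self-reverse-complementary motif (like AsiSI's GCGATCGC) needs only a
    forward scan; otherwise both strands are scanned and merged (reverse
    occurrences reported by their forward-strand start).
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be a non-empty exact ACGT string")
    rc = motif.translate(_COMPLEMENT)[::-1]
    motifs = [motif] if rc == motif else [motif, rc]
    positions: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        found: set[int] = set()
        for m in motifs:
            start = seq.find(m)
            while start != -1:
                found.add(start)
                start = seq.find(m, start + 1)  # overlapping occurrences count
        positions[chrom] = np.asarray(sorted(found), dtype=np.int64)
    return RestrictionSiteSet(motif=motif, positions=positions, window=window)


def count_at_sites(events: list[BreakEvent], sites: RestrictionSiteSet) -> int:
    """Events whose position falls in any [site - w, site + len(motif) + w).

    Each event is counted at most once even when site windows overlap.
    """
    w, mlen = sites.window, len(sites.motif)
    by_chrom: dict[str, list[int]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev.pos)
    n = 0
    for chrom, poss in by_chrom.items():
        sp = sites.positions.get(chrom)
        if sp is None or len(sp) == 0:
            continue
        pos = np.asarray(poss, dtype=np.int64)
        # nearest site starting at or before pos + w covers the left edge test
        idx = np.searchsorted(sp, pos + w, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < sp[idx[ok]] + mlen + w
        n += int(hit.sum())
    return n


def _event_mask_at_sites(events: list[BreakEvent], sites: RestrictionSiteSet) -> np.ndarray:
    w, mlen = sites.window, len(sites.motif)
    mask = np.zeros(len(events), dtype=bool)
    for i, ev in enumerate(events):
        sp = sites.positions.get(ev.chrom)
        if sp is None or len(sp) == 0:
            continue
        j = int(np.searchsorted(sp, ev.pos + w, side="right")) - 1
        mask[i] = j >= 0 and ev.pos < sp[j] + mlen + w
    return mask


def asisi_normalize(
    samples: list[BlissSample],
    sites: RestrictionSiteSet,
    seed: int = 0,
) -> list[BlissSample]:
    """Anchor samples on their restriction-window counts and subsample.

    For each sample i: ratio_i = min_j(asisi_j) / asisi_i and
    target_i = round(ratio_i * total_dedup_i); events are subsampled
    genome-wide without replacement to target_i.
    """
    for s in samples:
        s.asisi_count = count_at_sites(s.events, sites)
        if s.asisi_count == 0:
            raise ValueError(f"sample {s.sample_id!r}: zero restriction-window reads")
    min_asisi = min(s.asisi_count for s in samples)
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        ratio = min_asisi / s.asisi_count
        target = round(ratio * s.total_dedup)
        idx = rng.choice(s.total_dedup, size=target, replace=False)
        idx.sort()
        events = [s.events[i] for i in idx]
        norm = BlissSample(s.sample_id, events, normalized=True)
        norm.asisi_count = count_at_sites(events, sites)
        out.append(norm)
    return out


def annotate_breaks(
    events: list[BreakEvent],
    annotation: GenomeAnnotation,
    promoter_radius: int = 1000,
) -> dict[str, int]:
    """Classify each break as promoter, gene_body or intergenic.

    Promoter = TSS +/- promoter_radius (strand-aware single-base TSS);
    priority promoter > gene_body > intergenic. Counts sum to len(events).
    """
    from .intervals import MergedIntervalSet

    promoters: dict[str, list[tuple[int, int]]] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes.values():
        promoters.setdefault(g.chrom, []).append(
            (max(0, g.tss - promoter_radius), g.tss + promoter_radius + 1)
        )
        bodies.setdefault(g.chrom, []).append((g.start, g.end))
    prom_set = MergedIntervalSet(promoters)
    body_set = MergedIntervalSet(bodies)
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    by_chrom: dict[str, list[int]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev.pos)
    for chrom, poss in by_chrom.items():
        pos = np.asarray(poss, dtype=np.int64)
        in_prom = prom_set.overlaps(chrom, pos, pos + 1)
        in_body = body_set.overlaps(chrom, pos, pos + 1)
        counts["promoter"] += int(in_prom.sum())
        counts["gene_body"] += int((~in_prom & in_body).sum())
        counts["intergenic"] += int((~in_prom & ~in_body).sum())
    return counts


def relative_break_counts(
    samples: list[BlissSample],
    reference_sample: str,
    sites: RestrictionSiteSet | None = None,
    exclude_asisi: bool = True,
) -> dict[str, float]:
    """Per-sample break burden relative to a reference, after normalization.

    By default the exogenous restriction-window events (the calibration
    cuts, equalized across samples by construction) are excluded so the
    ratio reflects the biological break signal; set ``exclude_asisi=False``
    to compare raw normalized totals.
    """
    if exclude_asisi and sites is None:
        raise ValueError("sites required when exclude_asisi=True")
    burden: dict[str, float] = {}
    for s in samples:
        if not s.normalized:
            raise ValueError(f"sample {s.sample_id!r} is not normalized")
        if exclude_asisi:
            burden[s.sample_id] = s.total_dedup - count_at_sites(s.events, sites)
        else:
            burden[s.sample_id] = s.total_dedup
    ref = burden[reference_sample]
    if ref == 0:
        raise ValueError("reference sample has zero comparable events")
    return {sid: b / ref for sid, b in burden.items()}
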