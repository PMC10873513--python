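"""Length-aware profile analytics over coverage tracks.

Covers the nascent-transcription workflow: intronic read filtering,
expressed-gene selection, gene-length quartile stratification, TSS-anchored
profiles, scaled gene-body metagenes averaged per quartile, length-sorted
log2 fold-change occupancy heatmaps, and a promoter/body redistribution
statistic that summarizes the shift of polymerase signal from gene bodies
into promoter-proximal regions.

All profile extraction is strand-aware: minus-strand genes are read 3'->5'
in genomic coordinates so the profile axis always runs TSS -> TES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import warnings

from .core import CoverageTrack, GeneModel, GenomeAnnotation, ReadInterval
from .intervals import MergedIntervalSet


def _nanmean(a, axis=None):
    """nanmean without the all-NaN-slice RuntimeWarning (edge-clipped genes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)

__all__ = [
    "QuartileAssignment",
    "MetageneMatrix",
    "ScaledProfiles",
    "OccupancyFCMatrix",
    "filter_intronic",
    "expressed_genes",
    "stratify_by_length",
    "tss_profile",
    "scaled_metagene",
    "metagene_by_quartile",
    "occupancy_log2fc",
    "redistribution_stat",
    "body_log2fc_slope",
]


@dataclass
class QuartileAssignment:
    """Gene -> length group (1 = shortest), with per-gene exclusion reasons."""

    assignment: dict[str, int]
    excluded: dict[str, str] = field(default_factory=dict)
    n_groups: int = 4

    def genes_in(self, group: int) -> list[str]:
        return sorted(g for g, q in self.assignment.items() if q == group)

    def sizes(self) -> list[int]:
        return [len(self.genes_in(q)) for q in range(1, self.n_groups + 1)]


@dataclass
class MetageneMatrix:
    """Mean density per bin for one or more gene groups."""

    row_labels: list[str]
    values: np.ndarray  # rows x bins
    n_genes: list[int]
    bin_desc: str = ""


@dataclass
class ScaledProfiles:
    """Per-gene profiles on a common axis: flank bins + scaled body bins."""

    gene_ids: list[str]
    matrix: np.ndarray  # genes x (n_flank + body_bins + n_flank)
    n_flank_bins: int
    body_bins: int
    total_mapped: int
    excluded: dict[str, str] = field(default_factory=dict)

    def body(self) -> np.ndarray:
        return self.matrix[:, self.n_flank_bins : self.n_flank_bins + self.body_bins]


@dataclass
class OccupancyFCMatrix:
    """Per-gene log2(treated/control), rows sorted by ascending gene length."""

    gene_ids: list[str]
    lengths: np.ndarray
    values: np.ndarray  # genes x (body_bins + downstream_bins)
    body_end_index: int  # first downstream bin (the end-of-gene boundary)


def filter_intronic(
    reads: list[ReadInterval],
    annotation: GenomeAnnotation,
) -> list[ReadInterval]:
    """Drop reads touching any exon of any gene or any blacklist interval.

    A read overlapping both intron and exon is removed (any-overlap rule);
    reads entirely outside genes are kept — downstream counting decides
    whether they matter.
    """
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes.values():
        forbidden.setdefault(g.chrom, []).extend(g.exons)
    for chrom, s, e in annotation.blacklist:
        forbidden.setdefault(chrom, []).append((s, e))
    fset = MergedIntervalSet(forbidden)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        by_chrom.setdefault(r.chrom, []).append(i)
    keep_mask = np.ones(len(reads), dtype=bool)
    for chrom, idxs in by_chrom.items():
        idx = np.asarray(idxs)
        starts = np.asarray([reads[i].start for i in idxs], dtype=np.int64)
        ends = np.asarray([reads[i].end for i in idxs], dtype=np.int64)
        keep_mask[idx[fset.overlaps(chrom, starts, ends)]] = False
    return [r for i, r in enumerate(reads) if keep_mask[i]]


def expressed_genes(count_matrix: pd.DataFrame, min_reads: int = 10) -> set[str]:
    """Genes whose summed count across samples reaches ``min_reads``."""
    if count_matrix.empty:
        return set()
    totals = count_matrix.sum(axis=1)
    return set(totals.index[totals >= min_reads])


def stratify_by_length(
    genes: dict[str, GeneModel] | dict[str, int],
    n_groups: int = 4,
    min_length: int = 10_000,
    expressed: set[str] | None = None,
) -> QuartileAssignment:
    """Contiguous length groups after a minimum-length exclusion.

    Genes are stably sorted by (length, gene_id); group sizes are
    ``n // n_groups`` with the remainder spread over the last group(s), so
    sizes differ by at most one and group 1 holds the shortest genes.
    """
    lengths = {
        gid: (g.length if isinstance(g, GeneModel) else int(g)) for gid, g in genes.items()
    }
    excluded: dict[str, str] = {}
    eligible = []
    for gid, L in lengths.items():
        if expressed is not None and gid not in expressed:
            excluded[gid] = "not_expressed"
        elif L < min_length:
            excluded[gid] = "too_short"
        else:
            eligible.append(gid)
    n = len(eligible)
    if n < n_groups:
        raise ValueError(f"only {n} genes after exclusion; need >= {n_groups}")
    eligible.sort(key=lambda g: (lengths[g], g))
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    assignment: dict[str, int] = {}
    pos = 0
    for q, sz in enumerate(sizes, start=1):
        for gid in eligible[pos : pos + sz]:
            assignment[gid] = q
        pos += sz
    return QuartileAssignment(assignment=assignment, excluded=excluded, n_groups=n_groups)


def _oriented_base_values(track: CoverageTrack, gene: GeneModel, a: int, b: int) -> np.ndarray:
    """Per-base values over genomic [a, b), flipped for minus-strand genes."""
    vals = track.base_values(gene.chrom, a, b)
    return vals[::-1] if gene.strand == "-" else vals


def _gene_window(gene: GeneModel, flank: int) -> tuple[int, int]:
    return gene.start - flank, gene.end + flank


def tss_profile(
    track: CoverageTrack,
    genes: dict[str, GeneModel],
    flank: int = 2000,
    out_bin: int = 10,
) -> MetageneMatrix:
    """Mean density around the TSS (±flank), strand-aware, one output row.

    Genes running off a chromosome edge contribute only their in-bounds
    bases (NaN-masked mean).
    """
    if flank % out_bin != 0:
        raise ValueError("flank must be a multiple of out_bin")
    nb = 2 * flank // out_bin
    acc = np.zeros((len(genes), nb))
    for i, g in enumerate(genes.values()):
        if g.strand == "+":
            vals = track.base_values(g.chrom, g.tss - flank, g.tss + flank)
        else:
            vals = track.base_values(g.chrom, g.tss - flank + 1, g.tss + flank + 1)[::-1]
        acc[i] = _nanmean(vals.reshape(nb, out_bin), axis=1)
    profile = _nanmean(acc, axis=0)
    return MetageneMatrix(
        row_labels=["all"],
        values=profile[None, :],
        n_genes=[len(genes)],
        bin_desc=f"TSS±{flank} bp in {out_bin}-bp bins",
    )


def _segment_means(vals: np.ndarray, n_segments: int) -> np.ndarray:
    """Mean of ``vals`` over ``n_segments`` equal-width segments."""
    L = len(vals)
    bounds = np.floor(np.linspace(0, L, n_segments + 1)).astype(np.int64)
    sums = np.add.reduceat(np.nan_to_num(vals), bounds[:-1])
    counts = np.add.reduceat((~np.isnan(vals)).astype(np.int64), bounds[:-1])
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def scaled_metagene(
    track: CoverageTrack,
    genes: dict[str, GeneModel],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bin: int = 50,
) -> ScaledProfiles:
    """Per-gene profiles: fixed flank bins plus a body rescaled to
    ``body_bins`` equal-width segments (mean density per segment).

    Genes shorter than ``body_bins`` bp are excluded with a reason.
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    nfb = flank // flank_bin
    rows, ids, excluded = [], [], {}
    for gid, g in genes.items():
        if g.length < body_bins:
            excluded[gid] = "shorter_than_body_bins"
            continue
        a, b = _gene_window(g, flank)
        vals = _oriented_base_values(track, g, a, b)
        up = _nanmean(vals[:flank].reshape(nfb, flank_bin), axis=1) if flank else np.empty(0)
        body = _segment_means(vals[flank : flank + g.length], body_bins)
        down = (
            _nanmean(vals[flank + g.length :].reshape(nfb, flank_bin), axis=1)
            if flank
            else np.empty(0)
        )
        rows.append(np.concatenate([up, body, down]))
        ids.append(gid)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * nfb + body_bins))
    return ScaledProfiles(
        gene_ids=ids,
        matrix=matrix,
        n_flank_bins=nfb,
        body_bins=body_bins,
        total_mapped=track.total_mapped,
        excluded=excluded,
    )


def metagene_by_quartile(
    profiles: ScaledProfiles,
    assignment: QuartileAssignment,
    cpm_normalize: bool = True,
) -> MetageneMatrix:
    """Average per-gene profiles within each length group (CPM-scaled).

    CPM scaling multiplies densities by 1e6 / total mapped reads of the
    profile's source library, so libraries of different depth are
    comparable and duplicating every read leaves the matrix unchanged.
    """
    scale = 1e6 / profiles.total_mapped if cpm_normalize else 1.0
    rows, labels, ns = [], [], []
    gid_to_row = {g: i for i, g in enumerate(profiles.gene_ids)}
    for q in range(1, assignment.n_groups + 1):
        members = [gid_to_row[g] for g in assignment.genes_in(q) if g in gid_to_row]
        labels.append(f"Q{q}")
        ns.append(len(members))
        if members:
            rows.append(_nanmean(profiles.matrix[members], axis=0) * scale)
        else:
            rows.append(np.full(profiles.matrix.shape[1], np.nan))
    return MetageneMatrix(row_labels=labels, values=np.vstack(rows), n_genes=ns)


def _cpm_profiles(track: CoverageTrack, genes, body_bins, flank, flank_bin) -> ScaledProfiles:
    prof = scaled_metagene(track, genes, body_bins=body_bins, flank=flank, flank_bin=flank_bin)
    prof.matrix = prof.matrix * (1e6 / prof.total_mapped)
    return prof


def occupancy_log2fc(
    track_t: CoverageTrack,
    track_c: CoverageTrack,
    genes: dict[str, GeneModel],
    body_bins: int = 100,
    downstream: int = 10_000,
    downstream_bin: int = 500,
    pseudocount: float = 1.0,
) -> OccupancyFCMatrix:
    """Length-sorted per-gene log2((treated + eps) / (control + eps)) heatmap.

    The axis is the scaled gene body plus a fixed downstream extension, so
    the end-of-gene boundary (``body_end_index``) is visible regardless of
    gene length. Both tracks are CPM-scaled before the ratio; ``pseudocount``
    is in CPM units.
    """
    pt = _cpm_profiles(track_t, genes, body_bins, downstream, downstream_bin)
    pc = _cpm_profiles(track_c, genes, body_bins, downstream, downstream_bin)
    common = [g for g in pt.gene_ids if g in set(pc.gene_ids)]
    it = {g: i for i, g in enumerate(pt.gene_ids)}
    ic = {g: i for i, g in enumerate(pc.gene_ids)}
    order = sorted(common, key=lambda g: (genes[g].length, g))
    nfb = pt.n_flank_bins
    sel = slice(nfb, None)  # body + downstream flank; drop the upstream flank
    t = np.vstack([pt.matrix[it[g], sel] for g in order])
    c = np.vstack([pc.matrix[ic[g], sel] for g in order])
    values = np.log2((t + pseudocount) / (c + pseudocount))
    return OccupancyFCMatrix(
        gene_ids=order,
        lengths=np.asarray([genes[g].length for g in order]),
        values=values,
        body_end_index=body_bins,
    )


def redistribution_stat(
    track_t: CoverageTrack,
    track_c: CoverageTrack,
    genes: dict[str, GeneModel],
    assignment: QuartileAssignment,
    promoter_window: int = 500,
    body_bins: int = 50,
    pseudocount: float = 0.05,
) -> pd.DataFrame:
    """Per-quartile promoter and body log2FC of treated over control.

    Promoter = [TSS, TSS + window) strand-aware; body = the rest of the
    gene, rescaled to ``body_bins`` equal-width segments. Both tracks are
    CPM-scaled; the statistic is the mean over positions of the per-segment
    log2 fold change (so a within-body 5'-to-3' redistribution registers,
    which a ratio of body means would cancel out). A positive promoter value
    with a negative body value is the signature of an elongation defect.
    """
    st = 1e6 / track_t.total_mapped
    sc = 1e6 / track_c.total_mapped
    recs = []
    for gid, q in assignment.assignment.items():
        g = genes[gid]
        w = min(promoter_window, g.length)
        vt = _oriented_base_values(track_t, g, g.start, g.end) * st
        vc = _oriented_base_values(track_c, g, g.start, g.end) * sc
        prom = np.log2((_nanmean(vt[:w]) + pseudocount) / (_nanmean(vc[:w]) + pseudocount))
        nb = min(body_bins, max(1, g.length - w))
        bt = _segment_means(vt[w:], nb)
        bc = _segment_means(vc[w:], nb)
        body = float(_nanmean(np.log2((bt + pseudocount) / (bc + pseudocount))))
        recs.append((gid, q, prom, body))
    df = pd.DataFrame(recs, columns=["gene_id", "quartile", "promoter_log2fc", "body_log2fc"])
    return (
        df.groupby("quartile")[["promoter_log2fc", "body_log2fc"]]
        .mean()
        .reset_index()
    )


def body_log2fc_slope(
    track_t: CoverageTrack,
    track_c: CoverageTrack,
    genes: dict[str, GeneModel],
    body_bins: int = 50,
    pseudocount: float = 0.05,
    skip_promoter_bins: int = 2,
) -> float:
    """Mean per-gene OLS slope of body log2FC versus TSS distance (per kb).

    Under the survival elongation model the expected body log2FC of a gene
    is ``intercept_g + d_kb * log2(s_t / s_c)``: the slope is shared across
    genes while the intercept is gene-specific (truncation constants), so
    slopes are fitted per gene and averaged. The first ``skip_promoter_bins``
    scaled bins are dropped to keep the promoter-proximal pool out of the
    body fit.
    """
    pt = _cpm_profiles(track_t, genes, body_bins, 0, 50)
    pc = _cpm_profiles(track_c, genes, body_bins, 0, 50)
    ic = {g: i for i, g in enumerate(pc.gene_ids)}
    slopes = []
    for i, gid in enumerate(pt.gene_ids):
        if gid not in ic:
            continue
        L_kb = genes[gid].length / 1000.0
        t = pt.matrix[i]
        c = pc.matrix[ic[gid]]
        fc = np.log2((t + pseudocount) / (c + pseudocount))[skip_promoter_bins:]
        d = (np.arange(body_bins) + 0.5) / body_bins * L_kb
        d = d[skip_promoter_bins:]
        ok = np.isfinite(fc)
        if ok.sum() < 3:
            continue
        slope = np.polyfit(d[ok], fc[ok], 1)[0]
        slopes.append(slope)
    if not slopes:
        raise ValueError("no genes with enough finite bins for a slope fit")
    return float(np.mean(slopes))
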