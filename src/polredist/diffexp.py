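"""Gene-level counting, a defined differential-expression statistic, and
gene-length versus fold-change analytics.

Counting supports three region modes: ``exonic`` (exon union), ``second_half``
(strand-aware 3' half of the gene span) and ``intronic`` (intron union, after
exon/blacklist read filtering). Reads overlapping regions of more than one
gene are ambiguous and counted for none.

The differential statistic is deliberately simple and fully specified:
library-size normalization to the smallest sample, log2 fold change of
pseudocounted arm means, a two-sided equal-variance t-test on
log2(normalized + pseudocount) replicate values and Benjamini-Hochberg FDR
adjustment. The interface also accepts externally computed p-values so a
negative-binomial test can be spliced in.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeAnnotation, ReadInterval
from .intervals import RegionIndex
from .metagene import filter_intronic

__all__ = [
    "count_genes",
    "filter_low",
    "normalize_libsize",
    "bh_adjust",
    "differential",
    "length_fc_correlation",
    "select_downregulated",
    "length_class_summary",
]

COUNT_MODES = ("exonic", "second_half", "intronic")


def _gene_regions(annotation: GenomeAnnotation, mode: str) -> list[tuple[str, int, int, str]]:
    regions = []
    for gid, g in annotation.genes.items():
        if mode == "exonic":
            ivs = g.exons or ((g.start, g.end),)
        elif mode == "second_half":
            # strand-aware 3' half by genomic midpoint: [mid, end) on +, [start, mid) on -
            mid = (g.start + g.end) // 2
            ivs = ((mid, g.end),) if g.strand == "+" else ((g.start, mid),)
        else:  # intronic
            ivs = g.introns()
        for s, e in ivs:
            if e > s:
                regions.append((g.chrom, s, e, gid))
    return regions


def count_genes(
    reads_by_sample: dict[str, list[ReadInterval]],
    annotation: GenomeAnnotation,
    mode: str = "exonic",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count reads per gene in one of the three region modes.

    Returns ``(matrix, ambiguous)`` where ``matrix`` is genes x samples
    (all annotation genes, zeros included) and ``ambiguous`` counts reads
    discarded per sample for overlapping regions of more than one gene.
    In ``intronic`` mode reads are first passed through the exon/blacklist
    filter, mirroring nascent-transcription practice.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    index = RegionIndex(_gene_regions(annotation, mode))
    gids = sorted(annotation.genes)
    gpos = {g: i for i, g in enumerate(gids)}
    counts = np.zeros((len(gids), len(reads_by_sample)), dtype=np.int64)
    ambiguous: dict[str, int] = {}
    for j, (sample, reads) in enumerate(reads_by_sample.items()):
        if mode == "intronic":
            reads = filter_intronic(reads, annotation)
        by_chrom: dict[str, list[ReadInterval]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        n_amb = 0
        for chrom, rs in by_chrom.items():
            starts = np.asarray([r.start for r in rs], dtype=np.int64)
            ends = np.asarray([r.end for r in rs], dtype=np.int64)
            labels = index.query_single_labels(chrom, starts, ends)
            for lab in labels:
                if len(lab) == 1:
                    counts[gpos[lab[0]], j] += 1
                elif len(lab) > 1:
                    n_amb += 1
        ambiguous[sample] = n_amb
    matrix = pd.DataFrame(counts, index=gids, columns=list(reads_by_sample))
    return matrix, ambiguous


def filter_low(matrix: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Remove genes with summed count below ``min_reads``."""
    kept = matrix[matrix.sum(axis=1) >= min_reads]
    if kept.empty and not matrix.empty:
        warnings.warn("all genes fell below the expression filter")
    return kept


def normalize_libsize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by min(library size) / its library size."""
    libsizes = matrix.sum(axis=0).astype(float)
    if (libsizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return matrix * (libsizes.min() / libsizes)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sort ascending, set q_i = min_{j >= i} p_j * n / j, clip at 1, restore
    the input order. NaNs pass through unadjusted (and do not count toward n).
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = len(pv)
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    adj = np.empty(n)
    adj[order] = q
    out[ok] = adj
    return out


def differential(
    matrix: pd.DataFrame,
    design: dict[str, str],
    lengths: dict[str, int] | None = None,
    pseudocount: float = 1.0,
    pvalues: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC, p and BH FDR for control-vs-treated designs.

    ``design`` maps sample -> {"control", "treated"}. On library-size
    normalized counts: log2FC = log2((mean_t + c) / (mean_c + c)); p from a
    two-sided equal-variance t on log2(normalized + c) replicate values
    (NaN with fewer than two replicates per arm or degenerate variance,
    flagged). ``pvalues``, if given, replaces the built-in test gene-wise.
    """
    ctrl = [s for s, arm in design.items() if arm == "control"]
    trt = [s for s, arm in design.items() if arm == "treated"]
    if not ctrl or not trt:
        raise ValueError("design needs at least one control and one treated sample")
    norm = normalize_libsize(matrix[ctrl + trt])
    mc = norm[ctrl].mean(axis=1)
    mt = norm[trt].mean(axis=1)
    log2fc = np.log2((mt + pseudocount) / (mc + pseudocount))
    if pvalues is not None:
        p = pvalues.reindex(matrix.index).to_numpy(float)
    elif len(ctrl) >= 2 and len(trt) >= 2:
        lc = np.log2(norm[ctrl].to_numpy(float) + pseudocount)
        lt = np.log2(norm[trt].to_numpy(float) + pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # constant genes yield NaN t and are flagged below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(lt, lc, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = (lc.std(axis=1) == 0) & (lt.std(axis=1) == 0)
        p[degenerate] = np.nan
    else:
        p = np.full(len(matrix), np.nan)
    out = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "length": [lengths.get(g, np.nan) if lengths else np.nan for g in matrix.index],
            "mean_control": mc.to_numpy(),
            "mean_treated": mt.to_numpy(),
            "log2FC": np.asarray(log2fc),
            "p": p,
        }
    ).set_index("gene_id", drop=False)
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    out["flagged"] = np.isnan(p)
    return out


def length_fc_correlation(
    table: pd.DataFrame,
    geneset_a: set[str] | None = None,
    geneset_b: set[str] | None = None,
    length_scale: str = "log10",
) -> tuple[float, float, int, int]:
    """Pearson correlation of gene length with log2FC over two gene sets.

    Sets are intersected with the table's genes; their union is correlated.
    ``length_scale`` is ``"log10"`` (default) or ``"bp"``. Returns
    ``(r, p, n_a, n_b)`` with a two-sided p from the t transform.
    """
    genes = set(table.index)
    a = genes & geneset_a if geneset_a is not None else genes
    b = genes & geneset_b if geneset_b is not None else set()
    union = sorted(a | b)
    sub = table.loc[union].dropna(subset=["length", "log2FC"])
    x = sub["length"].to_numpy(float)
    if length_scale == "log10":
        x = np.log10(x)
    elif length_scale != "bp":
        raise ValueError("length_scale must be 'log10' or 'bp'")
    r, p = stats.pearsonr(x, sub["log2FC"].to_numpy(float))
    return float(r), float(p), len(a), len(b)


def select_downregulated(
    table: pd.DataFrame,
    geneset: set[str] | None = None,
    fc_cut: float = 0.0,
    fdr_cut: float = 0.05,
) -> list[str]:
    """Genes (in ``geneset``) with log2FC < fc_cut and FDR < fdr_cut."""
    sub = table if geneset is None else table.loc[table.index.intersection(list(geneset))]
    hit = (sub["log2FC"] < fc_cut) & (sub["FDR"] < fdr_cut)
    return sorted(sub.index[hit.fillna(False)])


def length_class_summary(
    table: pd.DataFrame,
    short_max: int,
    long_min: int,
    fc_cut: float = 0.0,
) -> dict:
    """2x2 table of up/down calls in short vs long genes, with an odds ratio.

    Orientation: odds of up-regulation in short genes over long genes, the
    signature of promoter-released short genes vs elongation-limited long
    genes. Empty classes flag the odds ratio as undefined (NaN).
    """
    if short_max > long_min:
        raise ValueError("length classes must be disjoint (short_max <= long_min)")
    short = table[table["length"] <= short_max]
    long_ = table[table["length"] >= long_min]
    up_s = int((short["log2FC"] > fc_cut).sum())
    dn_s = int((short["log2FC"] < fc_cut).sum())
    up_l = int((long_["log2FC"] > fc_cut).sum())
    dn_l = int((long_["log2FC"] < fc_cut).sum())
    if min(up_s + dn_s, up_l + dn_l) == 0 or dn_s == 0 or up_l == 0:
        odds = float("nan")
    else:
        odds = (up_s / dn_s) / (up_l / dn_l)
    return {
        "short": {"up": up_s, "down": dn_s},
        "long": {"up": up_l, "down": dn_l},
        "odds_ratio": odds,
    }
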