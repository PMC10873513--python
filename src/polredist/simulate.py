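"""Seeded synthetic-data generators with recoverable ground truth.

Four generators mirror the four data types the analysis modules consume:

* ``simulate_annotation`` — non-overlapping gene models with log-uniform
  lengths and sparse exons, plus a reserved spike-in chromosome.
* ``simulate_elongation_reads`` — nascent-transcription-style read libraries
  under a promoter-pause + per-kb survival elongation model, with a
  constant-fraction spike-in library.
* ``simulate_bliss`` — double-strand-break sequencing reads with barcodes,
  UMIs, PCR duplication, barcode errors and fixed-efficiency cutting at
  planted restriction sites.
* ``simulate_screen`` — per-well percent-positive tables with planted
  effects and replicate noise.

The elongation model: a read's 5' end falls in the promoter-proximal window
with probability ``pause_fraction``; otherwise its distance ``d`` (bp) from
the TSS follows a truncated exponential whose per-kb survival is
``survival_per_kb``, i.e. density proportional to ``survival_per_kb**(d/1000)``
over the gene body. Expected body log2 fold change between two conditions at
distance d kb is therefore ``d * log2(s_dep / s_ctrl)`` plus a gene-level
intercept from the truncation constants — a closed form every downstream
recovery test leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlignedLibrary, GeneModel, GenomeAnnotation, ReadInterval

__all__ = [
    "ElongationParams",
    "ConditionSpec",
    "BlissSimParams",
    "ScreenSimParams",
    "SPIKE_CHROM",
    "simulate_annotation",
    "simulate_elongation_reads",
    "simulate_genome",
    "simulate_bliss",
    "simulate_screen",
    "reference_screen",
    "default_conditions",
]

SPIKE_CHROM = "spike1"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ElongationParams:
    """Parameters of the promoter-pause + survival elongation model."""

    reads_total: int = 200_000
    spike_fraction: float = 0.05
    pause_fraction: float = 0.3
    survival_per_kb: float = 0.999
    promoter_window: int = 500
    read_length: int = 50
    initiation_weight: dict[str, float] | None = None  # None -> uniform

    def __post_init__(self) -> None:
        if not (0.0 <= self.pause_fraction <= 1.0):
            raise ValueError("pause_fraction must be in [0, 1]")
        if not (0.0 < self.survival_per_kb <= 1.0):
            raise ValueError("survival_per_kb must be in (0, 1]")
        if not (0.0 < self.spike_fraction < 1.0):
            raise ValueError("spike_fraction must be in (0, 1)")


@dataclass
class ConditionSpec:
    """A named condition; depletion lowers survival and raises pausing."""

    name: str
    params: ElongationParams


def default_conditions() -> tuple[ConditionSpec, ConditionSpec]:
    """The study conditions: control vs elongation-factor depletion.

    Depletion lowers per-kb survival (0.999 -> 0.99) and raises the
    promoter-proximal pause share (0.3 -> 0.5).
    """
    control = ConditionSpec("control", ElongationParams(survival_per_kb=0.999, pause_fraction=0.3))
    depleted = ConditionSpec("depleted", ElongationParams(survival_per_kb=0.99, pause_fraction=0.5))
    if depleted.params.survival_per_kb > control.params.survival_per_kb:
        raise ValueError("depleted survival must not exceed control survival")
    return control, depleted


def simulate_annotation(
    n_genes: int,
    length_log_range: tuple[int, int] = (2_000, 300_000),
    exon_density: float = 0.3,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    spike_chrom_size: int = 1_000_000,
) -> GenomeAnnotation:
    """Place ``n_genes`` non-overlapping genes with log-uniform lengths.

    ``exon_density`` is the expected number of exons per kb of gene length
    (at least one exon per gene); exons cover at most half the gene span so
    introns always exist. A geneless spike-in chromosome (``spike1``) is
    appended to ``chrom_sizes``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_log_range
    if not (0 < lo < hi):
        raise ValueError("invalid length_log_range")
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes)).astype(np.int64)
    if chrom_sizes is None:
        # four autosome-like chromosomes sized to hold the genes with ~30% slack
        total = int(lengths.sum() * 1.3) + 4 * 10_000
        chrom_sizes = {f"chr{i + 1}": total // 4 + 1 for i in range(4)}
    chroms = sorted(c for c in chrom_sizes if not c.startswith("spike"))
    capacity = sum(chrom_sizes[c] for c in chroms)
    slack = capacity - int(lengths.sum())
    if slack < n_genes:
        raise ValueError("genome too small to place genes without overlap; enlarge chrom_sizes")

    # first-fit assignment of genes to chromosomes, then random gaps that
    # exactly exhaust each chromosome's slack — placement cannot fail
    order = rng.permutation(n_genes)
    strands = rng.choice(["+", "-"], n_genes)
    remaining = {c: chrom_sizes[c] for c in chroms}
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for idx in order:
        L = int(lengths[idx])
        home = next((c for c in chroms if remaining[c] >= L + 1), None)
        if home is None:
            raise ValueError("gene placement overflowed the genome; enlarge chrom_sizes")
        per_chrom[home].append(int(idx))
        remaining[home] -= L + 1
    genes: dict[str, GeneModel] = {}
    for c in chroms:
        idxs = per_chrom[c]
        slack_c = chrom_sizes[c] - int(sum(lengths[i] for i in idxs))
        raw_gaps = rng.random(len(idxs) + 1)
        gaps = (raw_gaps / raw_gaps.sum() * slack_c).astype(np.int64)
        cursor = 0
        for k, idx in enumerate(idxs):
            L = int(lengths[idx])
            start = cursor + int(gaps[k])
            gid = f"g{idx:05d}"
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=c,
                strand=str(strands[idx]),
                start=start,
                end=start + L,
                exons=_make_exons(start, L, exon_density, rng),
            )
            cursor = start + L
    sizes = dict(chrom_sizes)
    sizes.setdefault(SPIKE_CHROM, spike_chrom_size)
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def _make_exons(start: int, length: int, exon_density: float, rng) -> tuple[tuple[int, int], ...]:
    n_exons = max(1, int(round(exon_density * length / 1000)))
    chunk = length / n_exons
    exons = []
    for i in range(n_exons):
        c0 = start + int(i * chunk)
        c1 = start + int((i + 1) * chunk)
        size = int(min(rng.integers(100, 301), max(1, (c1 - c0) // 2)))
        s = int(rng.integers(c0, max(c0 + 1, c1 - size)))
        exons.append((s, s + size))
    # cap exon coverage at 50% of the span (guaranteed by construction above)
    return tuple(exons)


def simulate_elongation_reads(
    annotation: GenomeAnnotation,
    condition: ConditionSpec,
    seed: int = 0,
    sample_id: str | None = None,
) -> tuple[AlignedLibrary, AlignedLibrary]:
    """Draw a (main, spike) read-library pair under the elongation model.

    Exactly ``reads_total`` reads are emitted; the spike count is binomial
    with probability ``spike_fraction`` and spike reads are uniform over the
    spike chromosome. Main-read 5' ends follow the pause + survival density;
    reads are ``read_length`` bp on the gene's strand.
    """
    p = condition.params
    rng = np.random.default_rng(seed)
    sample_id = sample_id or condition.name
    spike_chrom = next((c for c in annotation.chrom_sizes if c.startswith("spike")), None)
    if spike_chrom is None:
        raise ValueError("annotation lacks a spike-in chromosome (name starting with 'spike')")

    n_spike = int(rng.binomial(p.reads_total, p.spike_fraction))
    n_main = p.reads_total - n_spike

    gids = sorted(annotation.genes)
    gene_arr = [annotation.genes[g] for g in gids]
    starts = np.array([g.start for g in gene_arr], dtype=np.int64)
    ends = np.array([g.end for g in gene_arr], dtype=np.int64)
    minus = np.array([g.strand == "-" for g in gene_arr])
    lengths = ends - starts
    if p.initiation_weight is None:
        w = np.ones(len(gids))
    else:
        w = np.array([p.initiation_weight.get(g, 1.0) for g in gids], dtype=float)

    # Per-base intensity is globally proportional across genes:
    # pause_fraction * w_g in the promoter window, (1 - pause_fraction) * w_g
    # * s^(d/1000) along the body. Reads are therefore allocated to genes in
    # proportion to each gene's total mass under that intensity, which keeps
    # the closed-form body log2FC (slope log2(s_t/s_c) per kb, no
    # gene-specific renormalization) exact.
    winv = np.minimum(p.promoter_window, lengths).astype(float)
    Lf = lengths.astype(float)
    if p.survival_per_kb >= 1.0:
        body_mass = Lf
    else:
        lam_bp = -np.log(p.survival_per_kb) / 1000.0
        body_mass = (1.0 - np.exp(-lam_bp * Lf)) / lam_bp
    mass = w * (p.pause_fraction * winv + (1.0 - p.pause_fraction) * body_mass)
    pause_prob = np.where(mass > 0, p.pause_fraction * winv / np.maximum(mass / w, 1e-300), 0.0)

    gi = rng.choice(len(gids), size=n_main, p=mass / mass.sum())
    L = Lf[gi]
    paused = rng.random(n_main) < pause_prob[gi]
    d = np.empty(n_main)
    # promoter-proximal pool: uniform over the (clipped) promoter window
    win = winv[gi]
    d[paused] = rng.random(paused.sum()) * win[paused]
    # body pool: truncated exponential with per-kb survival s
    nb = (~paused).sum()
    u = rng.random(nb)
    if p.survival_per_kb >= 1.0:
        d[~paused] = u * L[~paused]
    else:
        lam = -np.log(p.survival_per_kb) / 1000.0  # per bp
        trunc = 1.0 - np.exp(-lam * L[~paused])
        d[~paused] = -np.log1p(-u * trunc) / lam
    d = np.minimum(d.astype(np.int64), lengths[gi] - 1)

    five = np.where(minus[gi], ends[gi] - 1 - d, starts[gi] + d)
    rstart = np.where(minus[gi], five - (p.read_length - 1), five)
    rend = rstart + p.read_length
    # clip to chromosome bounds
    csize = np.array([annotation.chrom_sizes[g.chrom] for g in gene_arr], dtype=np.int64)[gi]
    rstart = np.clip(rstart, 0, None)
    rend = np.minimum(rend, csize)

    chrom_list = [g.chrom for g in gene_arr]
    strand_list = ["-" if m else "+" for m in minus]
    read_chroms = [chrom_list[i] for i in gi]
    read_strands = [strand_list[i] for i in gi]
    main_reads = [
        ReadInterval(c, s, e, st)
        for c, s, e, st in zip(read_chroms, rstart.tolist(), rend.tolist(), read_strands)
    ]

    spike_size = annotation.chrom_sizes[spike_chrom]
    sstart = rng.integers(0, spike_size - p.read_length, n_spike)
    sstrand = rng.choice(["+", "-"], n_spike)
    spike_reads = [
        ReadInterval(spike_chrom, s, s + p.read_length, st)
        for s, st in zip(sstart.tolist(), sstrand.tolist())
    ]
    return (
        AlignedLibrary(sample_id, "main", main_reads),
        AlignedLibrary(sample_id, "spike", spike_reads),
    )


# --------------------------------------------------------------------------
# BLISS generator
# --------------------------------------------------------------------------


@dataclass
class BlissSimParams:
    """One BLISS sample: break rates, cutting, UMI/PCR and barcode behaviour."""

    barcode: str = "ACGTACGT"
    background_rate: float = 10.0  # breaks per Mb
    hotspots: list[tuple[str, int, float]] = field(default_factory=list)  # (chrom, pos, fold)
    hotspot_window: int = 2_000
    cut_efficiency: float = 0.5
    site_molecules: float = 40.0  # mean molecules per cut restriction site at depth 1
    depth: float = 1.0
    umi_length: int = 8
    duplication_rate: float = 0.0
    barcode_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (0.0 < self.cut_efficiency <= 1.0):
            raise ValueError("cut_efficiency must be in (0, 1]")
        if not (0.0 <= self.duplication_rate < 1.0):
            raise ValueError("duplication_rate must be in [0, 1)")


def _random_strings(rng, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    idx = rng.integers(0, 4, size=(n, length))
    return [bytes(_BASES[row]).decode() for row in idx]


def simulate_genome(
    chrom_sizes: dict[str, int],
    motif: str = "GCGATCGC",
    sites_per_mb: float = 1.0,
    seed: int = 0,
    gc: float = 0.42,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome sequence with planted restriction-motif occurrences.

    Returns ``(sequences, planted_sites)``. Chance occurrences of the motif
    in the random background are possible (and real sites); ``planted_sites``
    records only the deliberately placed ones.
    """
    if len(motif) > 20:
        raise ValueError("motif longer than 20 bp")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, str] = {}
    planted: dict[str, list[int]] = {}
    motif_b = np.frombuffer(motif.encode(), dtype=np.uint8)
    for chrom, size in chrom_sizes.items():
        arr = _BASES[rng.choice(4, size=size, p=p)]
        n_sites = rng.poisson(sites_per_mb * size / 1e6)
        pos = np.sort(rng.choice(max(size - len(motif), 1), size=n_sites, replace=False))
        # drop planted sites that would overlap each other
        planted[chrom] = []
        for x in sorted(set(pos.tolist())):
            if planted[chrom] and x < planted[chrom][-1] + len(motif):
                continue
            arr[x : x + len(motif)] = motif_b
            planted[chrom].append(int(x))
        seqs[chrom] = bytes(arr).decode()
    return seqs, planted


def simulate_bliss(
    chrom_sizes: dict[str, int],
    samples: list[BlissSimParams],
    seed: int = 0,
    motif: str = "GCGATCGC",
    sites_per_mb: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Simulate raw BLISS reads for several samples on a shared genome.

    Returns ``(reads, sequences, truth)`` where ``reads`` has columns
    ``barcode, umi, chrom, pos, strand, sample`` (``sample`` is ground
    truth, not available to the demultiplexer) and ``truth`` records planted
    sites and per-sample molecule counts.
    """
    rng = np.random.default_rng(seed)
    seqs, planted = simulate_genome(chrom_sizes, motif, sites_per_mb,
                                    seed=int(rng.integers(2**31)))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    rows: list[tuple] = []
    truth: dict = {"planted_sites": planted, "samples": {}}

    for sp in samples:
        srng = np.random.default_rng(int(rng.integers(2**31)))
        molecules: list[tuple[str, int, str]] = []
        # genome-wide background breaks
        n_bg = int(srng.poisson(sp.background_rate * sizes.sum() / 1e6 * sp.depth))
        ci = srng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
        bgpos = (srng.random(n_bg) * (sizes[ci] - 1)).astype(np.int64)
        for i in range(n_bg):
            molecules.append((chroms[ci[i]], int(bgpos[i]), "+" if srng.random() < 0.5 else "-"))
        # hotspots: extra breaks at (fold - 1) x background within the window
        n_hot_total = 0
        for chrom, center, fold in sp.hotspots:
            extra_rate = (fold - 1.0) * sp.background_rate * (sp.hotspot_window / 1e6) * sp.depth
            n_hot = int(srng.poisson(extra_rate))
            n_hot_total += n_hot
            hp = srng.integers(center - sp.hotspot_window // 2,
                               center + sp.hotspot_window // 2, n_hot)
            for x in hp:
                molecules.append((chrom, int(x), "+" if srng.random() < 0.5 else "-"))
        # restriction sites: fixed-efficiency cutting across the cell
        # population -> Poisson(molecules x efficiency x depth) per site
        n_site_mol = 0
        for chrom, sites in planted.items():
            for s in sites:
                m = int(srng.poisson(sp.site_molecules * sp.cut_efficiency * sp.depth))
                n_site_mol += m
                cut = s + len(motif) // 2
                for _ in range(m):
                    molecules.append((chrom, cut, "+" if srng.random() < 0.5 else "-"))
        umis = _random_strings(srng, len(molecules), sp.umi_length)
        # PCR: each molecule emitted geometric(1 - duplication_rate) times
        copies = srng.geometric(1.0 - sp.duplication_rate, len(molecules))
        for (chrom, pos, strand), umi, k in zip(molecules, umis, copies):
            for _ in range(int(k)):
                bc = sp.barcode
                if sp.barcode_error_rate > 0 and srng.random() < sp.barcode_error_rate:
                    j = int(srng.integers(len(bc)))
                    alt = "ACGT".replace(bc[j], "")[int(srng.integers(3))]
                    bc = bc[:j] + alt + bc[j + 1 :]
                rows.append((bc, umi, chrom, pos, strand, sp.barcode))
        truth["samples"][sp.barcode] = {
            "n_background": n_bg,
            "n_hotspot": n_hot_total,
            "n_site_molecules": n_site_mol,
            "n_molecules": len(molecules),
        }
    reads = pd.DataFrame(rows, columns=["barcode", "umi", "chrom", "pos", "strand", "sample"])
    return reads, seqs, truth


# --------------------------------------------------------------------------
# Screen generator
# --------------------------------------------------------------------------

READOUTS = ("edu", "pkap1_noatri", "pkap1_atri")


@dataclass
class ScreenSimParams:
    """A simulated high-content screen plate set."""

    n_targets: int = 86
    n_replicates: dict[str, int] = field(
        default_factory=lambda: {"edu": 3, "pkap1_noatri": 3, "pkap1_atri": 2}
    )
    ntc_replicates: int = 12
    baseline: dict[str, float] = field(
        default_factory=lambda: {"edu": 40.0, "pkap1_noatri": 10.0, "pkap1_atri": 20.0}
    )
    effects: dict[str, dict[str, float]] = field(default_factory=dict)  # target -> readout -> shift
    noise_sd: float = 1.0
    target_names: list[str] | None = None


def simulate_screen(params: ScreenSimParams, seed: int = 0) -> pd.DataFrame:
    """Well table with columns target, readout, replicate, percent_positive.

    percent_positive = clip(baseline + effect + Normal(0, sd), 0, 100);
    non-targeting control wells are labelled ``NTC`` with zero effect.
    """
    rng = np.random.default_rng(seed)
    names = params.target_names or [f"T{i + 1:03d}" for i in range(params.n_targets)]
    if len(names) != params.n_targets:
        raise ValueError("target_names length must equal n_targets")
    rows = []
    for readout in READOUTS:
        base = params.baseline[readout]
        nrep = params.n_replicates[readout]
        for target in names:
            eff = params.effects.get(target, {}).get(readout, 0.0)
            x = np.clip(base + eff + rng.normal(0.0, params.noise_sd, nrep), 0.0, 100.0)
            for r in range(nrep):
                rows.append((target, readout, r + 1, float(x[r])))
        xn = np.clip(base + rng.normal(0.0, params.noise_sd, params.ntc_replicates), 0.0, 100.0)
        for r in range(params.ntc_replicates):
            rows.append(("NTC", readout, r + 1, float(xn[r])))
    return pd.DataFrame(rows, columns=["target", "readout", "replicate", "percent_positive"])


def reference_screen(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Synthetic stand-in for an 86-target three-readout screen table.

    The planted ground truth emulates the hit structure of a focused
    elongation-factor screen: 4 targets respond in all three readouts,
    8 in exactly two, and further readout-specific singles so per-readout
    hit counts land between 8 and 56. Non-responding targets carry small
    opposite-direction offsets so the planted structure is recoverable
    essentially deterministically at the default noise level. This is a
    synthetic construction, not measured data.

    Returns ``(wells, truth)`` with truth holding the planted per-readout
    hit sets.
    """
    triple = ["CTR9", "CDC73", "RTF1", "EXOSC5"]
    pairs_edu_noatri = ["P01", "P02", "P03"]
    pairs_edu_atri = ["P04", "P05"]
    pairs_noatri_atri = ["P06", "P07", "P08"]
    singles_edu = [f"SE{i}" for i in range(1, 3)]
    singles_noatri = [f"SN{i}" for i in range(1, 9)]
    singles_atri = [f"SA{i}" for i in range(1, 31)]
    planted = (triple + pairs_edu_noatri + pairs_edu_atri + pairs_noatri_atri
               + singles_edu + singles_noatri + singles_atri)
    nulls = [f"N{i:02d}" for i in range(1, 87 - len(planted))]
    names = planted + nulls
    assert len(names) == 86

    hit_edu = set(triple + pairs_edu_noatri + pairs_edu_atri + singles_edu)
    hit_noatri = set(triple + pairs_edu_noatri + pairs_noatri_atri + singles_noatri)
    hit_atri = set(triple + pairs_edu_atri + pairs_noatri_atri + singles_atri)

    effects: dict[str, dict[str, float]] = {}
    for t in names:
        effects[t] = {
            # EdU hits decrease incorporation; pKAP1 hits increase positivity.
            "edu": -8.0 if t in hit_edu else 3.0,
            "pkap1_noatri": 8.0 if t in hit_noatri else -3.0,
            "pkap1_atri": 8.0 if t in hit_atri else -3.0,
        }
    params = ScreenSimParams(n_targets=86, effects=effects, target_names=names, noise_sd=1.0)
    wells = simulate_screen(params, seed=seed)
    truth = {"edu": hit_edu, "pkap1_noatri": hit_noatri, "pkap1_atri": hit_atri}
    return wells, truth
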