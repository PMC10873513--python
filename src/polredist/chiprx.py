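"""Cross-sample normalization for chromatin sequencing.

Two schemes are provided:

* spike-in (ChIP-Rx): each sample's factor is the smallest spike-in mapped
  count divided by that sample's spike-in mapped count; the factor is then
  applied to the main-genome library, either by seeded subsampling of reads
  or by scaling coverage values (``scale_track``).
* smallest-library read-count normalization (CUT&RUN-style): every library
  is subsampled to the size of the smallest one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignedLibrary, CoverageTrack

__all__ = [
    "SpikeInStats",
    "spikein_factors",
    "subsample_reads",
    "apply_spikein",
    "readcount_normalize",
    "scale_track",
]


@dataclass
class SpikeInStats:
    """Spike-in normalization state for one sample."""

    sample_id: str
    main_mapped: int
    spike_mapped: int
    factor: float
    target_reads: int


def spikein_factors(libraries: list[tuple[AlignedLibrary, AlignedLibrary]]) -> list[SpikeInStats]:
    """Compute spike-in factors from (main, spike) library pairs.

    factor_i = min_j(spike_j) / spike_i, so the sample with the fewest
    spike-in reads keeps factor 1.0. ``target_reads`` uses banker's rounding
    (round half to even) for cross-platform determinism.
    """
    for main, spike in libraries:
        if spike.mapped_count == 0:
            raise ValueError(f"sample {main.sample_id!r}: zero spike-in reads")
    min_spike = min(spike.mapped_count for _, spike in libraries)
    out = []
    for main, spike in libraries:
        factor = min_spike / spike.mapped_count
        out.append(
            SpikeInStats(
                sample_id=main.sample_id,
                main_mapped=main.mapped_count,
                spike_mapped=spike.mapped_count,
                factor=factor,
                target_reads=round(factor * main.mapped_count),
            )
        )
    return out


def subsample_reads(library: AlignedLibrary, n: int, seed: int = 0) -> AlignedLibrary:
    """Draw exactly ``n`` reads without replacement (seeded, deterministic)."""
    if not (0 <= n <= library.mapped_count):
        raise ValueError(
            f"cannot subsample {n} reads from a library of {library.mapped_count}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(library.mapped_count, size=n, replace=False)
    idx.sort()
    return AlignedLibrary(library.sample_id, library.genome_label,
                          [library.reads[i] for i in idx])


def apply_spikein(
    libraries: list[tuple[AlignedLibrary, AlignedLibrary]],
    stats: list[SpikeInStats] | None = None,
    seed: int = 0,
) -> list[tuple[AlignedLibrary, AlignedLibrary]]:
    """Apply spike-in factors by subsampling both main and spike libraries.

    Post-normalization, every sample's spike-in library has (up to rounding)
    the size of the smallest spike-in library — the property the factors
    exist to enforce.
    """
    stats = stats or spikein_factors(libraries)
    rng = np.random.default_rng(seed)
    out = []
    for (main, spike), st in zip(libraries, stats):
        s_main = int(rng.integers(2**31))
        s_spk = int(rng.integers(2**31))
        out.append(
            (
                subsample_reads(main, st.target_reads, seed=s_main),
                subsample_reads(spike, round(st.factor * spike.mapped_count), seed=s_spk),
            )
        )
    return out


def readcount_normalize(libraries: list[AlignedLibrary], seed: int = 0) -> list[AlignedLibrary]:
    """Subsample every library to the size of the smallest one."""
    if not libraries:
        raise ValueError("no libraries given")
    n = min(lib.mapped_count for lib in libraries)
    rng = np.random.default_rng(seed)
    return [subsample_reads(lib, n, seed=int(rng.integers(2**31))) for lib in libraries]


def scale_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Scale-only application of a normalization factor to a coverage track."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return track.scaled(factor)
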