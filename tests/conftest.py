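import numpy as np
import pytest

from polredist.core import GeneModel, GenomeAnnotation, ReadInterval


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes on opposite strands with introns, plus a blacklist interval."""
    genes = {
        "gA": GeneModel("gA", "chr1", "+", 100, 1100, exons=((100, 300), (900, 1100))),
        "gB": GeneModel("gB", "chr1", "-", 2000, 3000, exons=((2000, 2200), (2800, 3000))),
        "gC": GeneModel("gC", "chr2", "+", 500, 5500, exons=((500, 700),)),
    }
    return GenomeAnnotation(
        genes=genes,
        chrom_sizes={"chr1": 10_000, "chr2": 10_000},
        blacklist=[("chr2", 6000, 6500)],
    )


@pytest.fixture
def random_reads():
    def _make(n: int, chrom_sizes: dict[str, int], seed: int = 0, read_len: int = 50):
        rng = np.random.default_rng(seed)
        chroms = list(chrom_sizes)
        out = []
        for _ in range(n):
            c = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_sizes[c] - read_len))
            out.append(ReadInterval(c, start, start + read_len, "+" if rng.random() < 0.5 else "-"))
        return out

    return _make
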