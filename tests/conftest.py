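import numpy as np
import pytest

from coreacc import ExperimentalDesign, GeneAbundanceTable


@pytest.fixture
def toy_table() -> GeneAbundanceTable:
    """5 genes x 4 samples with hand-countable presence structure."""
    counts = np.array(
        [
            [10, 20, 30, 40],  # everywhere
            [5, 0, 7, 9],      # missing in s2
            [0, 0, 0, 0],      # nowhere
            [1, 1, 1, 1],      # everywhere (low)
            [0, 3, 0, 0],      # only s2
        ]
    )
    return GeneAbundanceTable(
        ["gA", "gB", "gC", "gD", "gE"], ["s1", "s2", "s3", "s4"], counts
    )


@pytest.fixture
def design_2x2() -> ExperimentalDesign:
    """Complete balanced 4-block split-plot design, 16 samples."""
    samples, blocks, ns, ws = [], [], [], []
    for b in range(1, 5):
        for n in (False, True):
            for w in (False, True):
                label = "NW" if (n and w) else "N" if n else "W" if w else "CK"
                samples.append(f"B{b}_{label}")
                blocks.append(f"block{b}")
                ns.append(n)
                ws.append(w)
    return ExperimentalDesign(samples, blocks, ns, ws)


def random_design(rng: np.random.Generator, n_blocks: int = 4) -> ExperimentalDesign:
    samples, blocks, ns, ws = [], [], [], []
    for b in range(n_blocks):
        for n in (False, True):
            for w in (False, True):
                samples.append(f"b{b}n{int(n)}w{int(w)}")
                blocks.append(f"b{b}")
                ns.append(n)
                ws.append(w)
    return ExperimentalDesign(samples, blocks, ns, ws)
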