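import logging

import numpy as np
import pytest

from jepeg import GenotypePanel, SummaryDataset, SummaryRecord

logging.getLogger("jepeg").setLevel(logging.ERROR)
for name in ("jepeg.data_io", "jepeg.annotation", "jepeg.impute", "jepeg.genetest", "jepeg.simulate"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture
def tiny_panel():
    """4 samples; rs2 duplicates rs1 exactly, rs6a sits on another chromosome."""
    dos = np.array(
        [
            [0.0, 0.0, 2.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
            [2.0, 2.0, 0.0, 2.0],
            [1.0, 1.0, 2.0, 1.0],
        ]
    )
    return GenotypePanel(
        snp_ids=["rs1", "rs2", "rs3", "rs6a"],
        chrom=np.array(["1", "1", "1", "6"], dtype=object),
        pos=np.array([100, 200, 300, 500]),
        ref=["A", "C", "G", "T"],
        alt=["G", "T", "A", "C"],
        dosages=dos,
    )


@pytest.fixture
def tiny_sumstats():
    return SummaryDataset(
        [
            SummaryRecord("rs1", "1", 100, "G", "A", 1.5),
            SummaryRecord("rs2", "1", 200, "T", "C", -0.5),
            SummaryRecord("rs3", "1", 300, "A", "G", 2.0),
            SummaryRecord("rs6a", "6", 500, "C", "T", 0.3),
        ]
    )


def random_correlation(m: int, rng, n: int = 200) -> np.ndarray:
    """Empirical correlation of correlated Gaussian columns: PSD by construction."""
    base = rng.standard_normal((n, max(m // 2, 1)))
    mix = rng.standard_normal((max(m // 2, 1), m))
    x = base @ mix + 0.8 * rng.standard_normal((n, m))
    return np.corrcoef(x, rowvar=False)
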