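import numpy as np
import pytest

from condsig.genome_io import CapAnnotations, GenomeBinning


@pytest.fixture
def binning():
    """chr1 of 10 kb + chr2 of 5.5 kb (trailing 500 bp dropped), 1 kb bins."""
    return GenomeBinning.from_chrom_sizes({"chr1": 10_000, "chr2": 5_500})


@pytest.fixture
def simple_annotations():
    records = {
        "A": {"is_llps": True, "has_idr": True, "is_rbp": False,
              "mlos": frozenset({"nucleolus"}), "ps_self": 0.9, "ps_part": 0.8},
        "B": {"is_llps": True, "has_idr": False, "is_rbp": True,
              "mlos": frozenset({"nucleolus"}), "ps_self": 0.7, "ps_part": 0.9},
        "C": {"is_llps": False, "has_idr": False, "is_rbp": False,
              "mlos": frozenset({"speckle"}), "ps_self": 0.2, "ps_part": 0.3},
        "D": {"is_llps": False, "has_idr": True, "is_rbp": False,
              "mlos": frozenset(), "ps_self": 0.4, "ps_part": 0.1},
    }
    return CapAnnotations(records, {frozenset(("A", "B"))})


def make_occupancy(matrix, binning=None, caps=None):
    """OccupancyMatrix directly from a dense 0/1 array (test helper)."""
    from condsig.occupancy import OccupancyMatrix

    O = np.asarray(matrix, dtype=np.uint8)
    n, m = O.shape
    if binning is None:
        binning = GenomeBinning.from_chrom_sizes({"chr1": n * 1000})
    if caps is None:
        caps = [f"CAP{j:02d}" for j in range(m)]
    return OccupancyMatrix(binning, list(caps), O, np.arange(n))


@pytest.fixture
def make_occ():
    return make_occupancy
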