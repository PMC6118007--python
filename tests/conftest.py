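import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ximosaic import CRE_NEG, CRE_POS, GenomeFixture, MethylomeState, make_genome_fixture

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale fixture: 2 autosomes, 400 autosomal + 120 X genes."""
    return make_genome_fixture(
        n_autosomal_genes=400, n_x_genes=120, n_islands_per_chrom=60,
        seed=123, n_autosomes=2,
    )


@pytest.fixture(scope="session")
def default_fixture():
    """Full default-scale fixture used for calibration checks."""
    return make_genome_fixture(seed=7)


def manual_fixture(site_positions, *, chrom="X", chrom_len=100_000,
                   assayable=None, island_bounds=None, p_xa=1.0, p_xi=1.0,
                   p_auto=0.5):
    """Hand-built single-island fixture for digestion geometry tests."""
    pos = np.asarray(site_positions, dtype=np.int64)
    if assayable is None:
        assayable = np.ones(len(pos), dtype=bool)
    if island_bounds is None:
        island_bounds = (int(pos.min()) - 5, int(pos.max()) + 5) if len(pos) else (0, 10)
    genes = pd.DataFrame({
        "gene_id": ["g1"], "chrom": [chrom], "strand": ["+"],
        "start": [10], "end": [1010], "tss": [10], "expr_rate": [1.0],
    }).astype({"start": np.int64, "end": np.int64, "tss": np.int64})
    islands = pd.DataFrame({
        "island_id": ["isl1"], "chrom": [chrom],
        "start": [island_bounds[0]], "end": [island_bounds[1]],
        "host_gene_id": ["g1"], "hyper": [False],
    }).astype({"start": np.int64, "end": np.int64})
    sites = pd.DataFrame({
        "island_id": ["isl1"] * len(pos), "chrom": [chrom] * len(pos),
        "pos": pos, "assayable": np.asarray(assayable, dtype=bool),
    })
    n = len(pos)
    on_x = chrom == "X"
    probs = {
        cond: {
            "auto": np.full(n, 0.0 if on_x else p_auto),
            "xa": np.full(n, p_xa if on_x else 0.0),
            "xi": np.full(n, p_xi if on_x else 0.0),
        }
        for cond in (CRE_NEG, CRE_POS)
    }
    return GenomeFixture({chrom: chrom_len}, genes, islands, sites,
                         MethylomeState(probs), {"seed": 0})
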