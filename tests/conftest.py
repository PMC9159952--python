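import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from regulome.intervals import PeakSet
from regulome.simulate import SimulationConfig, generate_multiome


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_peakset(rng, n, genome_length=10_000, max_width=300):
    """Random unique intervals on a toy genome."""
    seen, rows = set(), []
    while len(rows) < n:
        start = int(rng.integers(0, genome_length - 2))
        end = int(start + rng.integers(1, max_width))
        if (start, end) in seen:
            continue
        seen.add((start, end))
        rows.append(("chr1", start, end))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture
def small_multiome():
    """~600-cell multiome with planted effects, shared across tests."""
    cfg = SimulationConfig(
        seed=42, n_clusters=3, cells_per_cluster_per_replicate=25,
        replicates_per_sex=4, n_genes=400, n_peaks=600,
        n_sex_degs=40, n_regulators=2, peaks_per_regulator=30,
        n_tfs=20, n_links=10, n_sex_biased_peaks=30,
    )
    return generate_multiome(cfg)


def toy_cells(counts, **obs_cols) -> AnnData:
    """Build an AnnData from a dense gene-major array (cells x genes)."""
    counts = np.asarray(counts)
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(counts.shape[0])])
    var = pd.DataFrame(index=[f"g{j}" for j in range(counts.shape[1])])
    return AnnData(X=counts.astype(np.int32), obs=obs, var=var)
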