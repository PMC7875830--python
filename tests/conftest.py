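import numpy as np
import pandas as pd
import pytest

from introkit.genio import GenotypeMatrix


def make_matrix(
    dosages,
    sample_ids=None,
    quals=None,
    alt_counts=None,
    populations=None,
    missing=(),
):
    """Build a GenotypeMatrix from a dosage table (rows = samples).

    ``missing`` lists (sample_idx, locus_idx) cells to blank out;
    ``alt_counts`` gives the number of ALT alleles per locus (default 1).
    """
    dosages = np.asarray(dosages, dtype=int)
    s, l = dosages.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(s)]
    quals = quals if quals is not None else [1000.0] * l
    alt_counts = alt_counts or [1] * l
    alts = [tuple("ACGT"[1 : 1 + c]) for c in alt_counts]
    loci = pd.DataFrame(
        {
            "chrom": ["chr1"] * l,
            "pos": np.arange(1, l + 1) * 10,
            "ref": ["A"] * l,
            "alt": alts,
            "qual": [float(q) if q is not None else np.nan for q in quals],
        }
    )
    gt = np.zeros((s, l, 2), dtype=np.int16)
    gt[:, :, 0] = (dosages == 2).astype(np.int16)
    gt[:, :, 1] = (dosages >= 1).astype(np.int16)
    for i, j in missing:
        gt[i, j] = -1
    return GenotypeMatrix(sample_ids, loci, gt, populations=populations)


@pytest.fixture
def toy_matrix():
    # 3 samples x 4 loci, fully typed, variable
    return make_matrix(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
        ]
    )


@pytest.fixture
def sim_separated():
    """Two well-separated species + outgroup, no introgression."""
    from introkit.simdata import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_loci=1500, F_A=0.3, F_B=0.3, seed=11)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth
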