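import numpy as np
import pytest

from icamir import ica_core, synthetic_data as sd
from icamir.seed_targets import build_target_map


@pytest.fixture(scope="session")
def small_bundle():
    """Compact synthetic fixture shared across the suite: 600 genes, 4
    programs (2 design-mapped), 4 planted miRNAs + 2 decoys, 12 samples."""
    return sd.generate_bundle(
        G=600,
        T=4,
        sparsity=0.15,
        factors={"pdx1": ["off", "on"], "il1b": ["no", "yes"]},
        replicates=3,
        effect_map={0: ("pdx1", 5.0), 1: ("il1b", 5.0)},
        n_mirnas=4,
        n_decoys=2,
        target_fraction=0.08,
        effect=-1.5,
        noise_sd=0.05,
        mirna_noise_sd=0.02,
        utr_length=200,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_decomp(small_bundle):
    return ica_core.fast_ica(small_bundle.mrna, restarts=3, max_iter=400, rng_seed=1)


@pytest.fixture(scope="session")
def small_ranking(small_bundle, small_decomp):
    return ica_core.rank_components(small_decomp, small_bundle.design)


@pytest.fixture(scope="session")
def small_targets(small_bundle):
    return build_target_map(small_bundle.mirna_seqs, small_bundle.utrs)


def match_components(true_loads: np.ndarray, est_loads: np.ndarray):
    """Greedy bipartite matching on the absolute correlation matrix.

    Returns (matching, abs_r): for each true program, the index of the best
    unused estimated component and the matched |Pearson r|.
    """
    T = true_loads.shape[1]
    n = est_loads.shape[1]
    corr = np.abs(np.corrcoef(true_loads.T, est_loads.T)[:T, T:])
    matching = np.full(T, -1)
    abs_r = np.zeros(T)
    work = corr.copy()
    for _ in range(min(T, n)):
        t, j = np.unravel_index(np.argmax(work), work.shape)
        matching[t] = j
        abs_r[t] = corr[t, j]
        work[t, :] = -1
        work[:, j] = -1
    return matching, abs_r
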