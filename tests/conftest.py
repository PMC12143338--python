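import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from immunogate import CountBundle
from immunogate.normalize import lognormalize
from immunogate.simulate import (
    coarse_default_config,
    simulate_immune_dataset,
    sorted_reference_config,
)

COARSE_SEED = 11
SORTED_SEED = 7


@pytest.fixture(scope="session")
def coarse_sim():
    """Default six-population dataset with doublets, ADT and clonotypes."""
    return simulate_immune_dataset(coarse_default_config(seed=COARSE_SEED))


@pytest.fixture(scope="session")
def sorted_sim():
    """Seven sorted T cell populations along the differentiation gradient."""
    return simulate_immune_dataset(sorted_reference_config(seed=SORTED_SEED))


@pytest.fixture(scope="session")
def coarse_annotation(coarse_sim):
    from immunogate import annotate_coarse

    bundle, _, _ = coarse_sim
    return annotate_coarse(bundle)


@pytest.fixture(scope="session")
def coarse_norm(coarse_sim):
    bundle, _, _ = coarse_sim
    return lognormalize(bundle.rna_counts, cell_ids=bundle.cell_ids)


@pytest.fixture(scope="session")
def sorted_norm(sorted_sim):
    bundle, _, _ = sorted_sim
    return lognormalize(bundle.rna_counts, cell_ids=bundle.cell_ids)


@pytest.fixture(scope="session")
def sorted_eds(sorted_sim, sorted_norm):
    """Full EDS derivation on an 80/20 split of the sorted-reference data,
    plus the shuffled-label negative control."""
    from immunogate import derive_eds, pairwise_de, select_robust_markers
    from immunogate.exceptions import ValidationError

    bundle, truth, _ = sorted_sim
    labels = truth.cells["population"]
    rng = np.random.default_rng(SORTED_SEED)
    idx = rng.permutation(bundle.n_cells)
    cut = int(0.8 * len(idx))
    train, test = np.sort(idx[:cut]), np.sort(idx[cut:])

    de = pairwise_de(sorted_norm[train], bundle.gene_ids, labels.iloc[train])
    markers = select_robust_markers(
        de, sorted_norm[train], bundle.gene_ids, labels.iloc[train]
    )
    signature = derive_eds(
        sorted_norm[train],
        bundle.gene_ids,
        labels.iloc[train],
        markers,
        neg_pop="CD8_TN",
        pos_pop="CD8_TEM",
    )

    # negative control: rerun the whole derivation with shuffled labels;
    # if no robust markers survive (the expected outcome), record collapse
    shuffled = labels.iloc[train].sample(
        frac=1.0, random_state=SORTED_SEED
    ).reset_index(drop=True)
    try:
        de_s = pairwise_de(sorted_norm[train], bundle.gene_ids, shuffled)
        markers_s = select_robust_markers(
            de_s, sorted_norm[train], bundle.gene_ids, shuffled
        )
        sig_s = derive_eds(
            sorted_norm[train], bundle.gene_ids, shuffled, markers_s,
            neg_pop="CD8_TN", pos_pop="CD8_TEM",
        )
    except ValidationError:
        sig_s = None

    return {
        "train": train,
        "test": test,
        "de": de,
        "markers": markers,
        "signature": signature,
        "shuffled_signature": sig_s,
    }


def make_bundle(counts, reads=None, gene_ids=None, **kwargs) -> CountBundle:
    """Small hand-rolled bundle for unit tests."""
    if not sparse.issparse(counts):
        counts = np.asarray(counts)
    counts = sparse.csr_matrix(counts)
    n, g = counts.shape
    cell_ids = kwargs.pop("cell_ids", [f"c{i}" for i in range(n)])
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(g)]
    if reads is None:
        reads = np.asarray(counts.sum(axis=1)).ravel() * 2
    meta = kwargs.pop(
        "meta",
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "subject_id": ["S1"] * n,
                "tissue": ["PBMC"] * n,
                "lane": ["L1"] * n,
            }
        ),
    )
    return CountBundle(
        cell_ids=cell_ids,
        gene_ids=list(gene_ids),
        rna_counts=counts,
        rna_reads_per_cell=np.asarray(reads),
        meta=meta,
        **kwargs,
    )
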