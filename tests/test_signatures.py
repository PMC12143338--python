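"""Rank-score oracle tests, dot-plot summaries and ADT positivity calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunogate import (
    GeneModule,
    ValidationError,
    call_adt_positive,
    clr_normalize_adt,
    default_registry,
    score_module,
    score_modules,
    summarize_groups,
)


def bruteforce_rank_score(expression, module_idx, max_rank):
    """Independent rank-score oracle: explicit sort-based average ranks,
    capped rank sum mapped through the Mann-Whitney U formula."""
    x = list(expression)
    order = sorted(range(len(x)), key=lambda j: -x[j])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n = len(module_idx)
    u = sum(min(ranks[j], max_rank + 1) for j in module_idx) - n * (n + 1) / 2
    return max(0.0, 1.0 - u / (n * max_rank))


def test_top_ranked_single_gene_scores_one():
    x = np.array([[9.0, 1.0, 0.5, 0.0]])
    module = GeneModule("m", ("g0",))
    assert score_module(x, ["g0", "g1", "g2", "g3"], module, max_rank=3)[0] == 1.0


def test_unexpressed_gene_beyond_max_rank_scores_zero():
    # gene unexpressed with more than max_rank genes above it -> capped -> 0
    x = np.zeros((1, 30))
    x[0, :29] = np.arange(29, 0, -1)
    module = GeneModule("m", ("g29",))
    score = score_module(x, [f"g{j}" for j in range(30)], module, max_rank=20)
    assert score[0] == 0.0


def test_ten_gene_toy_example():
    # module at ranks {2, 5, 9}, max_rank 5 -> capped {2, 5, 6},
    # U = 13 - 6 = 7, score = 1 - 7/15
    x = np.array([[10, 9, 8, 7, 6, 5, 4, 3, 2, 1]], dtype=float)
    gene_ids = [f"g{j}" for j in range(10)]
    module = GeneModule("m", ("g1", "g4", "g8"))
    score = score_module(x, gene_ids, module, max_rank=5)
    assert score[0] == pytest.approx(1 - 7 / 15)
    assert score[0] == pytest.approx(0.5333, abs=1e-4)


def test_rank_score_matches_bruteforce_on_random_cells():
    rng = np.random.default_rng(0)
    for trial in range(200):
        n_genes = int(rng.integers(5, 51))
        x = np.round(rng.exponential(2.0, size=(1, n_genes)), 1)
        gene_ids = [f"g{j}" for j in range(n_genes)]
        max_rank = int(rng.integers(3, 21))
        size = int(rng.integers(1, min(n_genes, max_rank) + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        module = GeneModule("m", tuple(gene_ids[j] for j in idx))
        got = score_module(x, gene_ids, module, max_rank=max_rank)[0]
        want = bruteforce_rank_score(x[0], list(idx), max_rank)
        assert got == pytest.approx(want, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rank_score_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0, size=(1, 40))
    gene_ids = [f"g{j}" for j in range(40)]
    module = GeneModule("m", tuple(gene_ids[j] for j in rng.choice(40, 5, False)))
    base = score_module(x, gene_ids, module, max_rank=20)
    for transform in (np.log1p, np.sqrt, lambda v: 3 * v + 1):
        np.testing.assert_allclose(
            score_module(transform(x), gene_ids, module, max_rank=20), base
        )


def test_permuting_non_module_genes_preserves_score():
    rng = np.random.default_rng(1)
    x = rng.exponential(1.0, size=(1, 30))
    gene_ids = [f"g{j}" for j in range(30)]
    module = GeneModule("m", ("g0", "g1", "g2"))
    base = score_module(x, gene_ids, module, max_rank=15)
    perm = np.concatenate([np.arange(3), 3 + rng.permutation(27)])
    x_p = x[:, perm]
    ids_p = [gene_ids[j] for j in perm]
    np.testing.assert_allclose(score_module(x_p, ids_p, module, max_rank=15), base)


def test_adding_minimum_expression_gene_never_raises_positive_score():
    # holds whenever the base score exceeds n/max_rank; in the capped
    # near-zero tail both scores are pinned to ~0 by the clamp instead
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.exponential(1.0, size=(1, 60))
        worst = int(np.argmin(x[0]))
        gene_ids = [f"g{j}" for j in range(60)]
        order = np.argsort(-x[0])
        top = [gene_ids[j] for j in order[:3]]
        small = GeneModule("s", tuple(top))
        bigger = GeneModule("b", tuple(top + [gene_ids[worst]]))
        s_small = score_module(x, gene_ids, small, max_rank=40)[0]
        s_big = score_module(x, gene_ids, bigger, max_rank=40)[0]
        assert s_small >= len(small.genes) / 40  # in the regime where it holds
        assert s_big <= s_small + 1e-12


def test_missing_module_errors():
    x = np.ones((1, 3))
    with pytest.raises(ValidationError, match="no genes"):
        score_module(x, ["a", "b", "c"], GeneModule("m", ("zz",)), max_rank=2)


def test_registry_modules_are_consistent():
    reg = default_registry()
    for name in ("T_NK", "B", "Myeloid", "S100A_memory",
                 "Granzyme_KM", "Granzyme_ABH"):
        assert name in reg
    assert set(reg["Granzyme_KM"].genes) == {"GZMK", "GZMM"}
    assert set(reg["Granzyme_ABH"].genes) == {"GZMA", "GZMB", "GZMH"}


def test_scores_lie_in_unit_interval(coarse_sim, coarse_norm):
    bundle, _, _ = coarse_sim
    scores = score_modules(coarse_norm[:200], bundle.gene_ids, default_registry())
    assert (scores.to_numpy() >= 0).all() and (scores.to_numpy() <= 1).all()


# -- group summaries -------------------------------------------------------


def test_summarize_groups_fraction_and_single_group():
    counts = np.array([[0], [0], [5]])
    norm = np.log1p(counts.astype(float))
    out = summarize_groups(norm, counts, ["a", "a", "a"], ["g"], ["g"])
    assert out["frac_expressing"].item() == pytest.approx(1 / 3)
    assert out["scaled_mean"].item() == 0.0  # single group


def test_summarize_groups_matches_bruteforce():
    rng = np.random.default_rng(3)
    counts = rng.poisson(3.0, size=(30, 2))
    norm = np.log1p(counts * 0.7)
    groups = ["x"] * 10 + ["y"] * 10 + ["z"] * 10
    out = summarize_groups(norm, counts, groups, ["gA", "gB"])
    lin = np.expm1(norm)
    for gi, g in enumerate(["x", "y", "z"]):
        mask = np.array(groups) == g
        for j, gene in enumerate(["gA", "gB"]):
            row = out[(out.group == g) & (out.gene == gene)].iloc[0]
            assert row["mean"] == pytest.approx(lin[mask, j].mean())
            assert row["frac_expressing"] == pytest.approx(
                (counts[mask, j] > 0).mean()
            )
    # column scaling: z across the three group means, sample SD
    means = np.array(
        [lin[np.array(groups) == g, 0].mean() for g in ["x", "y", "z"]]
    )
    expect = (means - means.mean()) / means.std(ddof=1)
    got = out[out.gene == "gA"].sort_values("group")["scaled_mean"].to_numpy()
    np.testing.assert_allclose(got, expect, rtol=1e-10)


# -- ADT positivity --------------------------------------------------------


def test_adt_all_zero_tag_is_all_negative():
    clr = np.zeros((50, 1))
    positive, info = call_adt_positive(clr, ["L1"] * 50)
    assert not positive.any()
    assert info["frac_positive"].item() == 0.0


def test_adt_bimodal_recovery_and_lane_independence():
    rng = np.random.default_rng(4)
    n = 400
    truth = rng.random(n) < 0.4
    lane1 = np.where(truth, rng.normal(2.0, 0.15, n), rng.normal(0.1, 0.1, n))
    lane2 = rng.normal(0.1, 0.1, n)  # all background
    clr = np.concatenate([lane1, lane2])[:, None]
    lanes = ["L1"] * n + ["L2"] * n
    positive, info = call_adt_positive(clr, lanes)
    agree = (positive[:n, 0] == truth).mean()
    assert agree >= 0.99
    assert not positive[n:, 0].any()  # background lane called independently


def test_adt_low_separation_falls_back_to_negative():
    rng = np.random.default_rng(5)
    clr = rng.normal(1.0, 0.05, size=(100, 1))
    positive, info = call_adt_positive(clr, ["L1"] * 100, min_separation=0.5)
    assert not positive.any()
    assert info["separation"].item() < 0.5


def test_adt_nonfinite_rejected():
    clr = np.zeros((20, 1))
    clr[0] = np.nan
    with pytest.raises(ValidationError):
        call_adt_positive(clr, ["L1"] * 20)


def test_simulated_adt_positivity_matches_population_truth(coarse_sim):
    bundle, truth, _ = coarse_sim
    clr = clr_normalize_adt(bundle.adt_counts, bundle.meta["lane"])
    positive, _ = call_adt_positive(clr, bundle.meta["lane"], bundle.adt_ids)
    singlet = ~truth.cells.is_doublet.to_numpy()
    b_cells = (truth.cells.population == "B").to_numpy() & singlet
    t_cells = truth.cells.population.isin(["T_naive", "T_cm", "T_em"]).to_numpy() & singlet
    cd20 = bundle.adt_ids.index("CD20")
    cd3 = bundle.adt_ids.index("CD3")
    assert positive[b_cells, cd20].mean() > 0.9
    assert positive[t_cells, cd3].mean() > 0.9
    assert positive[b_cells, cd3].mean() < 0.1
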