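"""EDS derivation machinery: DE oracle, marker filtering, PCA closed forms,
signature portability."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from immunogate import (
    ConfigError,
    EdsSignature,
    ValidationError,
    apply_eds,
    categorize_by_eds,
    derive_eds,
    load_packaged_signature,
    pairwise_de,
    select_robust_markers,
)


def exact_ranksum_pvalue(a, b):
    """Enumerate all C(n+m, n) group assignments of the pooled values and
    count rank sums at least as extreme (two-sided) as observed."""
    pooled = sorted(a + b)
    ranks = {}
    for v in set(pooled):
        pos = [i + 1 for i, t in enumerate(pooled) if t == v]
        ranks[v] = sum(pos) / len(pos)
    obs = sum(ranks[v] for v in a)
    n = len(a)
    total = list(range(len(pooled)))
    mean_sum = n * (len(pooled) + 1) / 2.0
    count = 0
    arrangements = list(combinations(range(len(pooled)), n))
    for comb in arrangements:
        s = sum(ranks[pooled[i]] for i in comb)
        if abs(s - mean_sum) >= abs(obs - mean_sum) - 1e-12:
            count += 1
    return count / len(arrangements)


def test_wilcoxon_exact_small_groups():
    # [1,2,3] vs [4,5,6]: 2 of C(6,3)=20 arrangements are as extreme -> p=0.1
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert exact_ranksum_pvalue(a, b) == pytest.approx(0.1)
    x = np.array(a + b)[:, None]
    labels = ["lo"] * 3 + ["hi"] * 3
    de = pairwise_de(x, ["g"], labels, alpha=0.2, lfc_min=0.0)
    assert len(de) == 1
    assert de["p"].item() == pytest.approx(0.1)


def test_exact_pvalues_match_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = list(np.round(rng.normal(0, 1, 4), 2))
        b = list(np.round(rng.normal(0.5, 1, 5), 2))
        if len(set(a + b)) != 9:
            continue  # oracle below assumes method="exact" (no ties)
        x = np.concatenate([a, b])[:, None]
        de = pairwise_de(
            np.repeat(x, 3, axis=1), ["g0", "g1", "g2"],
            ["A"] * 4 + ["B"] * 5, alpha=1.1, lfc_min=0.0, min_frac_detect=0.0,
        )
        want = exact_ranksum_pvalue(a, b)
        for p in de[de.gene == "g0"]["p"]:
            assert p == pytest.approx(want, abs=1e-12)


def test_identical_distributions_yield_no_candidates():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(40, 30))
    x[20:] = x[:20]  # both groups identical values
    de = pairwise_de(x, [f"g{j}" for j in range(30)], ["A"] * 20 + ["B"] * 20)
    assert de.empty


def test_planted_marker_is_detected():
    rng = np.random.default_rng(2)
    x = np.abs(rng.normal(1.0, 0.3, size=(60, 20)))
    x[:30, 4] *= 4.0  # 4-fold marker for group A
    de = pairwise_de(x, [f"g{j}" for j in range(20)], ["A"] * 30 + ["B"] * 30)
    hit = de[(de.gene == "g4")]
    assert len(hit) == 1 and hit["marker_for"].item() == "A"


def test_small_population_rejected():
    with pytest.raises(ValidationError, match="fewer than 3"):
        pairwise_de(np.ones((4, 2)), ["a", "b"], ["A", "A", "A", "B"])


def test_robust_marker_expression_fraction_filter():
    rng = np.random.default_rng(3)
    x = np.zeros((40, 2))
    x[:20, 0] = np.where(rng.random(20) < 0.2, 1.0, 0.0)  # sparse: ~20%
    x[:20, 1] = np.where(rng.random(20) < 0.9, 1.0, 0.0)  # robust: ~90%
    labels = ["A"] * 20 + ["B"] * 20
    de = pd.DataFrame(
        {
            "gene": ["sparse", "robust"],
            "group_a": ["A"] * 2,
            "group_b": ["B"] * 2,
            "log2fc": [1.0, 1.0],
            "u_statistic": [0, 0],
            "p": [0.001] * 2,
            "p_adj": [0.001] * 2,
            "frac_a": [0.2, 0.9],
            "frac_b": [0.0, 0.0],
            "marker_for": ["A", "A"],
        }
    )
    markers = select_robust_markers(de, x, ["sparse", "robust"], labels)
    assert markers == ["robust"]
    with pytest.raises(ValidationError):
        select_robust_markers(
            de, x, ["sparse", "robust"], labels, expr_fraction_min=0.99
        )


def test_two_correlated_genes_closed_form():
    # perfectly correlated pair: correlation matrix [[1,1],[1,1]] has first
    # eigenvector (1,1)/sqrt(2); a cell at z=(1,1) scores sqrt(2)
    rng = np.random.default_rng(4)
    g = rng.normal(size=200)
    x = np.column_stack([g, 2.0 * g + 5.0])
    labels = ["neg"] * 100 + ["pos"] * 100
    x[100:] += 2.0  # make pos pole higher for orientation
    sig = derive_eds(x, ["gA", "gB"], labels, ["gA", "gB"], "neg", "pos")
    np.testing.assert_allclose(np.abs(sig.loadings), 1 / math.sqrt(2), rtol=1e-10)
    z = np.array([[1.0, 1.0]])
    score = float((z @ sig.loadings)[0])
    assert score == pytest.approx(math.sqrt(2), rel=1e-10)


def test_orientation_fixed_under_negation(sorted_sim, sorted_norm, sorted_eds):
    bundle, truth, _ = sorted_sim
    labels = truth.cells["population"]
    markers = sorted_eds["markers"][:50]
    sig = derive_eds(sorted_norm, bundle.gene_ids, labels, markers,
                     "CD8_TN", "CD8_TEM")
    sig_neg = derive_eds(-sorted_norm, bundle.gene_ids, labels, markers,
                         "CD8_TN", "CD8_TEM")
    for s in (sig, sig_neg):
        tem = s.derivation_scores[(labels == "CD8_TEM").to_numpy()].mean()
        tn = s.derivation_scores[(labels == "CD8_TN").to_numpy()].mean()
        assert tem > tn
    np.testing.assert_allclose(
        sig.derivation_scores, sig_neg.derivation_scores, atol=1e-8
    )


def test_apply_at_center_scores_zero():
    sig = EdsSignature(
        genes=["a", "b"],
        loadings=np.array([1.0, 1.0]) / math.sqrt(2),
        mu=np.array([2.0, 3.0]),
        sigma=np.array([1.0, 2.0]),
        orientation={"neg": "x", "pos": "y"},
        thresholds={"naive": -1.0, "effector": 6.0},
    )
    scores, coverage = apply_eds(sig, np.array([[2.0, 3.0]]), ["a", "b"])
    assert scores[0] == 0.0 and coverage == 1.0


def test_apply_is_linear_in_standardized_expression():
    rng = np.random.default_rng(5)
    v = rng.normal(size=3)
    sig = EdsSignature(
        genes=["a", "b", "c"],
        loadings=v / np.linalg.norm(v),
        mu=np.zeros(3),
        sigma=np.ones(3),
        orientation={"neg": "x", "pos": "y"},
        thresholds={"naive": -1.0, "effector": 6.0},
    )
    x = rng.normal(size=(1, 3))
    y = rng.normal(size=(1, 3))
    for alpha in (0.0, 0.3, 1.0):
        mix = alpha * x + (1 - alpha) * y
        s_mix, _ = apply_eds(sig, mix, ["a", "b", "c"])
        s_x, _ = apply_eds(sig, x, ["a", "b", "c"])
        s_y, _ = apply_eds(sig, y, ["a", "b", "c"])
        assert s_mix[0] == pytest.approx(alpha * s_x[0] + (1 - alpha) * s_y[0])


def test_signature_roundtrip_bit_identical(tmp_path, sorted_sim, sorted_norm,
                                           sorted_eds):
    bundle, _, _ = sorted_sim
    sig = sorted_eds["signature"]
    sig.to_json(tmp_path / "sig.json")
    back = EdsSignature.from_json(tmp_path / "sig.json")
    s1, _ = apply_eds(sig, sorted_norm[:100], bundle.gene_ids)
    s2, _ = apply_eds(back, sorted_norm[:100], bundle.gene_ids)
    np.testing.assert_array_equal(s1, s2)


def test_missing_genes_reduce_coverage_not_crash():
    sig = EdsSignature(
        genes=["a", "b"],
        loadings=np.array([0.6, 0.8]),
        mu=np.zeros(2),
        sigma=np.ones(2),
        orientation={"neg": "x", "pos": "y"},
        thresholds={"naive": -1.0, "effector": 6.0},
    )
    with pytest.warns(UserWarning, match="coverage"):
        scores, coverage = apply_eds(sig, np.array([[2.0]]), ["a"])
    assert coverage == pytest.approx(0.6 / 1.4)
    assert scores[0] == pytest.approx(0.6 * 2.0)
    with pytest.raises(ValidationError):
        apply_eds(sig, np.array([[1.0]]), ["zz"])


def test_case_insensitive_symbol_mapping():
    sig = EdsSignature(
        genes=["S100A4", "GZMB"],
        loadings=np.array([0.6, 0.8]),
        mu=np.zeros(2),
        sigma=np.ones(2),
        orientation={"neg": "x", "pos": "y"},
        thresholds={"naive": -1.0, "effector": 6.0},
    )
    scores, coverage = apply_eds(
        sig, np.array([[1.0, 1.0]]), ["s100a4", "Gzmb"], case_insensitive=True
    )
    assert coverage == 1.0
    assert scores[0] == pytest.approx(1.4)


def test_categorization_boundaries():
    thresholds = {"naive": -5.0, "effector": 6.0}
    cats = categorize_by_eds(np.array([6.0, 7.2, -7.0, 0.0]), thresholds)
    assert list(cats) == ["intermediate", "effector", "naive-like", "intermediate"]
    with pytest.raises(ConfigError):
        categorize_by_eds(np.array([0.0]), {"naive": 6.0, "effector": 6.0})


def test_packaged_signature_contract():
    sig = load_packaged_signature()
    assert len(sig.genes) == len(set(sig.genes)) == 175
    assert sig.loadings.shape == (175,)
    assert float(sig.loadings @ sig.loadings) == pytest.approx(1.0, abs=1e-9)
    assert (sig.sigma > 0).all()
    assert sig.thresholds["effector"] == 6.0
    assert sig.meta.get("synthetic") is True
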