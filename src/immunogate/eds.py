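"""The effector-differentiation score (EDS): derivation from sorted reference
T cell populations and portable application to new datasets.

Derivation: pairwise Wilcoxon rank-sum contrasts between the sorted
populations identify candidate markers (BH-adjusted p < alpha, |log2FC| above
a floor, detected in a minimum fraction of either group); candidates are
filtered to robust markers expressed in a high fraction of the population
they mark; the marker genes are z-scored over the derivation cells and the
first principal axis of that reduced space — oriented so effector-memory
cells score above naive cells — becomes a portable weighted gene list. The
signature stores, per gene, the loading plus the derivation-set centering and
scaling constants, so applying it elsewhere is a single weighted sum of
standardized expression; genes missing from a target dataset contribute zero
(equivalent to imputing the derivation mean) and the reported coverage is the
|weight| fraction present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, ValidationError

SORTED_POPULATIONS = (
    "CD4_TN",
    "CD8_TN",
    "CD4_TCM_TM",
    "CD8_TCM_TM",
    "CD4_TEM",
    "CD8_TEM",
    "GD",
)

EFFECTOR_THRESHOLD = 6.0  # reference convention: effector iff score > 6 (strict)


@dataclass
class EdsSignature:
    """Portable weighted gene list with standardization constants."""

    genes: list[str]
    loadings: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    orientation: dict  # {"neg": population, "pos": population}
    thresholds: dict  # {"naive": float, "effector": float}
    meta: dict = field(default_factory=dict)
    derivation_scores: np.ndarray | None = None  # not serialized

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.genes)
        if not (len(self.loadings) == len(self.mu) == len(self.sigma) == n):
            raise ValidationError("signature arrays misaligned with genes")
        if np.any(self.sigma <= 0):
            raise ValidationError("signature sigma must be positive")
        if abs(float(self.loadings @ self.loadings) - 1.0) > 1e-6:
            raise ValidationError("signature loadings must have unit norm")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genes": self.genes,
                    "loadings": self.loadings.tolist(),
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "orientation": self.orientation,
                    "thresholds": self.thresholds,
                    "meta": self.meta,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "EdsSignature":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            genes=raw["genes"],
            loadings=np.array(raw["loadings"]),
            mu=np.array(raw["mu"]),
            sigma=np.array(raw["sigma"]),
            orientation=raw["orientation"],
            thresholds=raw["thresholds"],
            meta=raw.get("meta", {}),
        )


def pairwise_de(
    normalized: np.ndarray,
    gene_ids: list[str],
    labels,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
    min_frac_detect: float = 0.10,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum contrasts for every population pair and gene.

    Exact null when both groups have <= 8 cells and the gene has no ties;
    normal approximation with tie correction otherwise. p values are
    BH-corrected within each pair. A gene is a candidate marker for the group
    where it is higher when ``p_adj < alpha``, ``|log2FC| >= lfc_min`` and it
    is detected in at least ``min_frac_detect`` of either group. log2FC is the
    difference of ln-normalized group means divided by ln 2.
    """
    x = np.asarray(normalized, dtype=float)
    labels = pd.Series(list(labels))
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("pairwise DE requires at least two populations")
    masks = {g: (labels == g).to_numpy() for g in groups}
    for g, m in masks.items():
        if m.sum() < 3:
            raise ValidationError(f"population {g!r} has fewer than 3 cells")

    rows = []
    for a, b in combinations(groups, 2):
        xa, xb = x[masks[a]], x[masks[b]]
        na, nb = xa.shape[0], xb.shape[0]
        if na <= 8 and nb <= 8:
            p = np.empty(x.shape[1])
            u = np.empty(x.shape[1])
            for j in range(x.shape[1]):
                col = np.concatenate([xa[:, j], xb[:, j]])
                method = "exact" if len(np.unique(col)) == len(col) else "asymptotic"
                res = stats.mannwhitneyu(
                    xa[:, j], xb[:, j], alternative="two-sided", method=method
                )
                u[j], p[j] = res.statistic, res.pvalue
        else:
            res = stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method="asymptotic", axis=0
            )
            u, p = res.statistic, res.pvalue
        p = np.nan_to_num(p, nan=1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
        lfc = (mean_a - mean_b) / np.log(2.0)
        frac_a = (xa > 0).mean(axis=0)
        frac_b = (xb > 0).mean(axis=0)
        candidate = (
            (p_adj < alpha)
            & (np.abs(lfc) >= lfc_min)
            & (np.maximum(frac_a, frac_b) >= min_frac_detect)
        )
        marker_for = np.where(lfc > 0, a, b)
        for j in np.flatnonzero(candidate):
            rows.append(
                {
                    "gene": gene_ids[j],
                    "group_a": a,
                    "group_b": b,
                    "log2fc": lfc[j],
                    "u_statistic": u[j],
                    "p": p[j],
                    "p_adj": p_adj[j],
                    "frac_a": frac_a[j],
                    "frac_b": frac_b[j],
                    "marker_for": marker_for[j],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "group_a",
            "group_b",
            "log2fc",
            "u_statistic",
            "p",
            "p_adj",
            "frac_a",
            "frac_b",
            "marker_for",
        ],
    )


def select_robust_markers(
    de: pd.DataFrame,
    normalized: np.ndarray,
    gene_ids: list[str],
    labels,
    expr_fraction_min: float = 0.5,
    top_per_population: int | None = None,
) -> list[str]:
    """Keep candidates expressed in >= ``expr_fraction_min`` of the population
    they mark; optionally cap per population by effect size; return the union
    (sorted)."""
    if de.empty:
        raise ValidationError(
            "no DE candidates; relax alpha/lfc/detection thresholds"
        )
    x = np.asarray(normalized, dtype=float)
    labels = pd.Series(list(labels))
    index = {g: i for i, g in enumerate(gene_ids)}
    frac_cache: dict[tuple[str, str], float] = {}

    def frac_in(gene: str, pop: str) -> float:
        key = (gene, pop)
        if key not in frac_cache:
            mask = (labels == pop).to_numpy()
            frac_cache[key] = float((x[mask, index[gene]] > 0).mean())
        return frac_cache[key]

    kept: dict[str, list[tuple[float, str]]] = {}
    for _, row in de.iterrows():
        if frac_in(row["gene"], row["marker_for"]) >= expr_fraction_min:
            kept.setdefault(row["marker_for"], []).append(
                (abs(row["log2fc"]), row["gene"])
            )
    union: set[str] = set()
    for pop, entries in kept.items():
        entries.sort(key=lambda t: (-t[0], t[1]))
        seen: list[str] = []
        for _, g in entries:
            if g not in seen:
                seen.append(g)
        if top_per_population is not None:
            seen = seen[:top_per_population]
        union.update(seen)
    if not union:
        raise ValidationError(
            "no robust markers survive; relax expr_fraction_min"
        )
    return sorted(union)


def derive_eds(
    normalized: np.ndarray,
    gene_ids: list[str],
    labels,
    markers: list[str],
    neg_pop: str,
    pos_pop: str,
    thresholds: dict | None = None,
) -> EdsSignature:
    """Correlation-PCA on the marker space; the oriented first axis is the EDS.

    Marker genes are z-scored over the derivation cells (sample SD; constant
    genes dropped with a warning); the unit-norm first principal axis is
    flipped, if needed, so the ``pos_pop`` population scores above
    ``neg_pop``. Default thresholds: naive = 25th percentile of the
    negative-pole population's scores, effector = 75th percentile of the
    positive pole's.
    """
    labels = pd.Series(list(labels))
    for anchor in (neg_pop, pos_pop):
        if anchor not in set(labels):
            raise ValidationError(f"orientation anchor {anchor!r} not among labels")
    x = np.asarray(normalized, dtype=float)
    if x.shape[0] < 10:
        raise ValidationError("EDS derivation requires >= 10 cells")
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in markers if g in index]
    if len(present) < 2:
        raise ValidationError("need at least two marker genes present")
    sub = x[:, [index[g] for g in present]]
    mu = sub.mean(axis=0)
    sigma = sub.std(axis=0, ddof=1)
    keep = sigma > 0
    if not keep.all():
        dropped = [g for g, k in zip(present, keep) if not k]
        warnings.warn(f"dropping constant marker genes: {dropped}")
        present = [g for g, k in zip(present, keep) if k]
        sub, mu, sigma = sub[:, keep], mu[keep], sigma[keep]
    if len(present) < 2:
        raise ValidationError("fewer than two non-constant marker genes")
    z = (sub - mu) / sigma
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    w = vt[0]
    scores = z @ w
    if scores[(labels == pos_pop).to_numpy()].mean() < scores[
        (labels == neg_pop).to_numpy()
    ].mean():
        w = -w
        scores = -scores
    if thresholds is None:
        thresholds = {
            "naive": float(
                np.percentile(scores[(labels == neg_pop).to_numpy()], 25)
            ),
            "effector": float(
                np.percentile(scores[(labels == pos_pop).to_numpy()], 75)
            ),
        }
    return EdsSignature(
        genes=present,
        loadings=w,
        mu=mu,
        sigma=sigma,
        orientation={"neg": neg_pop, "pos": pos_pop},
        thresholds=thresholds,
        meta={"n_cells": int(x.shape[0]), "n_genes": len(present)},
        derivation_scores=scores,
    )


def apply_eds(
    signature: EdsSignature,
    normalized: np.ndarray,
    gene_ids: list[str],
    case_insensitive: bool = False,
) -> tuple[np.ndarray, float]:
    """Score cells with a signature: sum of loading * standardized expression
    over the signature genes present. Returns (scores, coverage) where
    coverage is the present fraction of total |loading| mass."""
    x = np.asarray(normalized, dtype=float)
    if case_insensitive:
        index = {}
        for i, g in enumerate(gene_ids):
            index.setdefault(g.upper(), i)
        cols = [index.get(g.upper(), -1) for g in signature.genes]
    else:
        index = {g: i for i, g in enumerate(gene_ids)}
        cols = [index.get(g, -1) for g in signature.genes]
    present = np.array([c >= 0 for c in cols])
    if not present.any():
        raise ValidationError("no signature genes present in the target")
    abs_w = np.abs(signature.loadings)
    coverage = float(abs_w[present].sum() / abs_w.sum())
    if coverage < 1.0:
        warnings.warn(
            f"signature coverage {coverage:.2%}; missing genes contribute 0"
        )
    scores = np.zeros(x.shape[0])
    for j, c in enumerate(cols):
        if c >= 0:
            scores += signature.loadings[j] * (
                (x[:, c] - signature.mu[j]) / signature.sigma[j]
            )
    return scores, coverage


def categorize_by_eds(
    scores: np.ndarray, thresholds: dict | None = None
) -> pd.Series:
    """Classify scores into naive-like / intermediate / effector.

    Effector iff score strictly exceeds the effector threshold; naive-like iff
    strictly below the naive threshold; intermediate otherwise.
    """
    if thresholds is None:
        thresholds = {"naive": 0.0, "effector": EFFECTOR_THRESHOLD}
    naive, effector = thresholds["naive"], thresholds["effector"]
    if not naive < effector:
        raise ConfigError("thresholds must satisfy naive < effector")
    scores = np.asarray(scores, dtype=float)
    out = np.where(
        scores > effector,
        "effector",
        np.where(scores < naive, "naive-like", "intermediate"),
    )
    return pd.Series(out, name="eds_category")


def load_packaged_signature() -> EdsSignature:
    """The packaged EDS signature.

    This is a synthetic stand-in built from the bundled sorted-reference
    simulator (see ``scripts`` / ``immunogate.eds.build_synthetic_signature``):
    a 175-gene weighted list with the reference effector threshold of 6.0.
    It exercises the full signature machinery but does not encode any real
    reference dataset.
    """
    from importlib import resources

    path = resources.files("immunogate.data").joinpath(
        "eds_signature_synthetic.json"
    )
    with resources.as_file(path) as p:
        return EdsSignature.from_json(p)


def build_synthetic_signature(
    seed: int = 20260919, n_signature_genes: int = 175
) -> EdsSignature:
    """Derive the packaged synthetic signature from the sorted-reference
    simulator: pairwise DE -> robust markers -> top genes by effect size ->
    oriented PC1, with the reference effector threshold of 6.0."""
    from .normalize import lognormalize
    from .simulate import simulate_immune_dataset, sorted_reference_config

    bundle, truth, _ = simulate_immune_dataset(sorted_reference_config(seed=seed))
    normalized = lognormalize(bundle.rna_counts, cell_ids=bundle.cell_ids)
    labels = truth.cells["population"]
    de = pairwise_de(normalized, bundle.gene_ids, labels)
    markers = select_robust_markers(de, normalized, bundle.gene_ids, labels)
    if len(markers) < n_signature_genes:
        raise ValidationError(
            f"only {len(markers)} robust markers; need {n_signature_genes}"
        )
    best_lfc = de.groupby("gene")["log2fc"].apply(lambda s: s.abs().max())
    x = np.asarray(normalized)
    index = {g: i for i, g in enumerate(bundle.gene_ids)}
    markers = [g for g in markers if x[:, index[g]].std() > 0]
    ranked = sorted(markers, key=lambda g: (-best_lfc.get(g, 0.0), g))
    chosen = sorted(ranked[:n_signature_genes])
    sig = derive_eds(
        normalized,
        bundle.gene_ids,
        labels,
        chosen,
        neg_pop="CD8_TN",
        pos_pop="CD8_TEM",
    )
    sig.thresholds = {"naive": sig.thresholds["naive"], "effector": EFFECTOR_THRESHOLD}
    sig.meta.update({"synthetic": True, "seed": seed})
    return sig
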