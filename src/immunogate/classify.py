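"""Two-phase coarse annotation: module gating, then a probabilistic linear
classifier trained on the high-confidence gated cells, followed by an
incompatibility doublet filter.

Gating assigns a cell to a lineage when all of the lineage's positive modules
score at or above their thresholds (and any negative modules below theirs);
cells passing multiple gates are ``ambiguous`` and cells passing none are
``unassigned``. Confidently gated cells are down-sampled to a balanced
training set for an L2-regularized multinomial logistic model over the full
transcriptome, which then labels every cell (argmax probability if it exceeds
a confidence threshold tau). Finally, cells whose raw module scores are
simultaneously high for two incompatible lineages — e.g. B and T — are
flagged as likely doublets: a multinomial model normalizes co-occurring
identities away, but raw module co-positivity is exactly the doublet
fingerprint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .bundle import CountBundle
from .exceptions import ConfigError, ValidationError
from .normalize import lognormalize
from .signatures import ModuleRegistry, default_registry, score_modules

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
DOUBLET = "doublet"


@dataclass(frozen=True)
class GateDefinition:
    """Positive/negative module thresholds defining one lineage gate."""

    label: str
    positive: tuple[tuple[str, float], ...]  # (module, threshold >= )
    negative: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for _, thr in list(self.positive) + list(self.negative):
            if not (0.0 <= thr <= 1.0):
                raise ConfigError(f"gate {self.label}: threshold outside [0,1]")


DEFAULT_GATE_THRESHOLD = 0.2


def default_gates() -> list[GateDefinition]:
    t = DEFAULT_GATE_THRESHOLD
    return [
        GateDefinition("T_NK", (("T_NK", t),)),
        GateDefinition("B", (("B", t),)),
        GateDefinition("Myeloid", (("Myeloid", t),)),
        GateDefinition("Erythroid", (("Erythroid", t),)),
    ]


def load_gates(path: str | Path) -> list[GateDefinition]:
    """Gate file: JSON list of {label, positive:[{module,threshold}], negative:[...]}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        GateDefinition(
            label=r["label"],
            positive=tuple(
                (p["module"], float(p.get("threshold", DEFAULT_GATE_THRESHOLD)))
                for p in r["positive"]
            ),
            negative=tuple(
                (p["module"], float(p.get("threshold", DEFAULT_GATE_THRESHOLD)))
                for p in r.get("negative", [])
            ),
        )
        for r in raw
    ]


# Unordered lineage pairs that cannot co-occur in a singlet.
DEFAULT_INCOMPATIBILITY_RULES: list[tuple[str, str]] = [
    ("B", "T_NK"),
    ("T_NK", "Erythroid"),
    ("B", "Myeloid"),
    ("T_NK", "Myeloid"),
]


def smooth_scores(
    scores: pd.DataFrame,
    normalized: np.ndarray,
    k: int = 30,
    n_components: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Average each cell's module scores over its k nearest neighbors in
    top-principal-component space."""
    if normalized.shape[0] < k + 1:
        raise ValidationError("kNN smoothing requires at least k+1 cells")
    n_comp = min(n_components, normalized.shape[0] - 1, normalized.shape[1])
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(normalized)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    smoothed = scores.to_numpy()[idx].mean(axis=1)
    return pd.DataFrame(smoothed, columns=scores.columns, index=scores.index)


def gate_cells(
    scores: pd.DataFrame, gates: list[GateDefinition] | None = None
) -> pd.Series:
    """Assign each cell the unique passing gate label, else ambiguous/unassigned."""
    if gates is None:
        gates = default_gates()
    if not gates:
        raise ConfigError("empty gate list")
    passing = np.zeros((len(scores), len(gates)), dtype=bool)
    for j, gate in enumerate(gates):
        ok = np.ones(len(scores), dtype=bool)
        for module, thr in gate.positive:
            ok &= scores[module].to_numpy() >= thr
        for module, thr in gate.negative:
            ok &= scores[module].to_numpy() < thr
        passing[:, j] = ok
    n_pass = passing.sum(axis=1)
    labels = np.where(n_pass == 0, UNASSIGNED, AMBIGUOUS)
    unique = n_pass == 1
    labels = labels.astype(object)
    gate_labels = np.array([g.label for g in gates], dtype=object)
    labels[unique] = gate_labels[np.argmax(passing[unique], axis=1)]
    return pd.Series(labels, index=scores.index, name="gate_label")


def build_training_set(
    labels: pd.Series,
    cap: int | None = None,
    seed: int = 0,
    min_class_size: int = 1,
) -> np.ndarray:
    """Balanced per-class index sample (without replacement) of confident cells.

    Classes with fewer than ``min_class_size`` confident cells are excluded —
    a handful of spuriously gated cells would otherwise drag every class down
    to their size under balanced sampling.
    """
    rng = np.random.default_rng(seed)
    confident = labels[~labels.isin([AMBIGUOUS, UNASSIGNED])]
    per_class_all = confident.groupby(confident).size()
    small = per_class_all[per_class_all < min_class_size].index
    if len(small):
        warnings.warn(
            f"excluding classes below {min_class_size} confident cells: "
            f"{sorted(small)}"
        )
        confident = confident[~confident.isin(small)]
    classes = sorted(confident.unique())
    if len(classes) < 2:
        raise ValidationError("need confident cells from at least two classes")
    per_class = confident.groupby(confident).size()
    target = int(per_class.min()) if cap is None else cap
    idx: list[int] = []
    positions = {lbl: i for i, lbl in enumerate(labels.index)}
    for cls in classes:
        members = np.array([positions[i] for i in confident[confident == cls].index])
        take = min(len(members), target)
        idx.extend(sorted(rng.choice(members, size=take, replace=False).tolist()))
    return np.array(sorted(idx))


@dataclass
class LinearClassifier:
    """Multinomial probabilistic linear model over normalized expression."""

    classes: list[str]
    genes: list[str]
    weights: np.ndarray  # classes x genes (single row for 2 classes)
    intercepts: np.ndarray
    tau: float = 0.5
    normalization: str = "lognorm10k"
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not (0.0 < self.tau < 1.0):
            raise ConfigError("confidence threshold tau must lie in (0,1)")

    def _design(self, values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(gene_ids)}
        cols = [index.get(g, -1) for g in self.genes]
        present = sum(c >= 0 for c in cols)
        if present == 0:
            raise ValidationError("no classifier feature genes present in data")
        if present < len(cols):
            warnings.warn(
                f"only {present}/{len(cols)} classifier genes present; "
                "missing genes imputed as 0"
            )
        x = np.zeros((values.shape[0], len(cols)))
        for j, c in enumerate(cols):
            if c >= 0:
                x[:, j] = values[:, c]
        return x

    def predict_proba(self, values: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
        x = self._design(np.asarray(values, dtype=float), gene_ids)
        logits = x @ self.weights.T + self.intercepts
        if len(self.classes) == 2 and self.weights.shape[0] == 1:
            p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            probs = np.column_stack([1.0 - p1, p1])
        else:
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, columns=self.classes)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "classes": self.classes,
                    "genes": self.genes,
                    "weights": self.weights.tolist(),
                    "intercepts": self.intercepts.tolist(),
                    "tau": self.tau,
                    "normalization": self.normalization,
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearClassifier":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            classes=raw["classes"],
            genes=raw["genes"],
            weights=np.array(raw["weights"]),
            intercepts=np.array(raw["intercepts"]),
            tau=raw["tau"],
            normalization=raw["normalization"],
            seed=raw["seed"],
        )


def train_classifier(
    values: np.ndarray,
    gene_ids: list[str],
    labels,
    train_idx: np.ndarray | None = None,
    C: float = 1.0,
    tau: float = 0.5,
    seed: int = 0,
    max_iter: int = 500,
) -> LinearClassifier:
    """Fit the L2-regularized multinomial linear model on the training subset."""
    labels = pd.Series(list(labels))
    if train_idx is not None:
        x = np.asarray(values, dtype=float)[train_idx]
        y = labels.iloc[train_idx]
    else:
        x = np.asarray(values, dtype=float)
        y = labels
    if y.nunique() < 2:
        raise ValidationError("training requires at least two classes")
    # default penalty is L2; C controls its strength
    model = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
    model.fit(x, y)
    return LinearClassifier(
        classes=list(model.classes_),
        genes=list(gene_ids),
        weights=model.coef_,
        intercepts=model.intercept_,
        tau=tau,
        seed=seed,
    )


def classify_cells(
    model: LinearClassifier, values: np.ndarray, gene_ids: list[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Label every cell: argmax class if its probability >= tau, else unassigned."""
    probs = model.predict_proba(values, gene_ids)
    arg = probs.to_numpy().argmax(axis=1)
    pmax = probs.to_numpy().max(axis=1)
    labels = np.array([model.classes[a] for a in arg], dtype=object)
    labels[pmax < model.tau] = UNASSIGNED
    return pd.Series(labels, name="label"), probs


def filter_incompatible(
    scores: pd.DataFrame,
    gates: list[GateDefinition] | None = None,
    rules: list[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Flag cells whose module scores pass the gates of two incompatible
    lineages simultaneously."""
    if gates is None:
        gates = default_gates()
    if rules is None:
        rules = DEFAULT_INCOMPATIBILITY_RULES
    by_label = {g.label: g for g in gates}
    for a, b in rules:
        if a == b:
            raise ConfigError(f"self-pair rule {a!r}")
        for lbl in (a, b):
            if lbl not in by_label:
                raise ConfigError(f"rule names unknown lineage {lbl!r}")

    def hot(label: str) -> np.ndarray:
        ok = np.ones(len(scores), dtype=bool)
        for module, thr in by_label[label].positive:
            ok &= scores[module].to_numpy() >= thr
        return ok

    flags = np.zeros(len(scores), dtype=bool)
    for a, b in rules:
        flags |= hot(a) & hot(b)
    return flags


@dataclass
class AnnotateConfig:
    cap: int | None = None
    min_class_size: int = 25
    tau: float = 0.5
    C: float = 1.0
    seed: int = 0
    smoothing: bool = False
    smoothing_k: int = 30
    max_rank: int = 1500


@dataclass
class AnnotationResult:
    labels: pd.Series  # final: lineage, unassigned, or doublet
    gate_labels: pd.Series
    probabilities: pd.DataFrame
    doublet_flags: np.ndarray
    module_scores: pd.DataFrame
    model: LinearClassifier
    report: dict


def annotate_coarse(
    bundle: CountBundle,
    gates: list[GateDefinition] | None = None,
    rules: list[tuple[str, str]] | None = None,
    registry: ModuleRegistry | None = None,
    config: AnnotateConfig | None = None,
) -> AnnotationResult:
    """Gate -> balanced training set -> train -> classify -> doublet filter."""
    if gates is None:
        gates = default_gates()
    if rules is None:
        rules = DEFAULT_INCOMPATIBILITY_RULES
    if registry is None:
        registry = default_registry()
    if config is None:
        config = AnnotateConfig()

    normalized = lognormalize(bundle.rna_counts, cell_ids=bundle.cell_ids)
    needed = sorted({m for g in gates for m, _ in list(g.positive) + list(g.negative)})
    modules = [registry[m] for m in needed]
    scores = score_modules(
        normalized, bundle.gene_ids, modules, max_rank=config.max_rank
    )
    gate_scores = scores
    if config.smoothing:
        gate_scores = smooth_scores(
            scores, normalized, k=config.smoothing_k, seed=config.seed
        )
    gate_labels = gate_cells(gate_scores, gates)
    train_idx = build_training_set(
        gate_labels,
        cap=config.cap,
        seed=config.seed,
        min_class_size=config.min_class_size,
    )
    model = train_classifier(
        normalized,
        bundle.gene_ids,
        gate_labels,
        train_idx=train_idx,
        C=config.C,
        tau=config.tau,
        seed=config.seed,
    )
    labels, probs = classify_cells(model, normalized, bundle.gene_ids)
    flags = filter_incompatible(scores, gates, rules)
    final = labels.copy().astype(object)
    final[flags] = DOUBLET
    report = {
        "n_cells": bundle.n_cells,
        "n_gated": int((~gate_labels.isin([AMBIGUOUS, UNASSIGNED])).sum()),
        "n_trained_on": int(len(train_idx)),
        "n_confident": int((labels != UNASSIGNED).sum()),
        "n_incompatible": int(flags.sum()),
        "per_class": final.value_counts().to_dict(),
    }
    return AnnotationResult(
        labels=final,
        gate_labels=gate_labels,
        probabilities=probs,
        doublet_flags=flags,
        module_scores=scores,
        model=model,
        report=report,
    )
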