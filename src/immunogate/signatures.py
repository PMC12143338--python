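"""Rank-based per-cell gene-module scores, dot-plot summaries, ADT positivity.

The module score is a Mann-Whitney-style statistic: within each cell, all
genes are ranked by decreasing expression (average ties), module-gene ranks
are capped at ``max_rank + 1``, and the capped rank-sum U statistic is mapped
to [0, 1] — 1 when the module genes occupy the cell's top ranks, ~0 when they
are unexpressed in a matrix with many more than ``max_rank`` genes. Because it
depends only on within-cell ranks, the score is invariant to any monotone
per-cell transform (library size, log scale) and transfers across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError
from .normalize import _dense

DEFAULT_MAX_RANK = 1500


@dataclass(frozen=True)
class GeneModule:
    """A named, optionally signed, gene set."""

    name: str
    genes: tuple[str, ...]
    signs: tuple[float, ...] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"module {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"module {self.name!r} has duplicate genes")
        if self.signs is not None and len(self.signs) != len(self.genes):
            raise ValidationError(f"module {self.name!r}: signs misaligned")


class ModuleRegistry:
    """Collection of uniquely named modules, serializable to JSON."""

    def __init__(self, modules: list[GeneModule] | None = None):
        self._modules: dict[str, GeneModule] = {}
        for m in modules or []:
            self.add(m)

    def add(self, module: GeneModule) -> None:
        if module.name in self._modules:
            raise ValidationError(f"duplicate module name {module.name!r}")
        self._modules[module.name] = module

    def __getitem__(self, name: str) -> GeneModule:
        return self._modules[name]

    def __contains__(self, name: str) -> bool:
        return name in self._modules

    def __iter__(self):
        return iter(self._modules.values())

    def __len__(self) -> int:
        return len(self._modules)

    @property
    def names(self) -> list[str]:
        return list(self._modules)

    @classmethod
    def from_json(cls, path: str | Path) -> "ModuleRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        return cls._from_records(raw)

    @classmethod
    def _from_records(cls, raw: list[dict]) -> "ModuleRegistry":
        modules = [
            GeneModule(
                name=r["name"],
                genes=tuple(r["genes"]),
                signs=tuple(r["signs"]) if r.get("signs") else None,
                note=r.get("note", ""),
            )
            for r in raw
        ]
        return cls(modules)

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "name": m.name,
                "genes": list(m.genes),
                **({"signs": list(m.signs)} if m.signs else {}),
                "note": m.note,
            }
            for m in self
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)


def default_registry() -> ModuleRegistry:
    """The packaged diagnostic modules: coarse lineages with erythroid/platelet
    guards, the S100A memory program, the two granzyme programs, and the three
    mature-B-cell programs."""
    raw = json.loads(
        resources.files("immunogate.data").joinpath("modules.json").read_text()
    )
    return ModuleRegistry._from_records(raw)


def score_modules(
    values,
    gene_ids: list[str],
    modules: list[GeneModule] | ModuleRegistry,
    max_rank: int = DEFAULT_MAX_RANK,
) -> pd.DataFrame:
    """Score every cell for every module; returns a cells x modules DataFrame.

    ``values`` may be counts or normalized expression (the score is rank
    based, so any within-cell monotone scale gives identical results). Module
    genes absent from the matrix are treated as maximally lowly expressed
    (rank ``max_rank + 1``); a module with no genes present raises.
    """
    x = _dense(values)
    modules = list(modules)
    index = {g: i for i, g in enumerate(gene_ids)}
    for m in modules:
        if len(m.genes) > max_rank:
            raise ValidationError(
                f"module {m.name!r} larger than max_rank={max_rank}"
            )
        if not any(g in index for g in m.genes):
            raise ValidationError(
                f"no genes of module {m.name!r} present; missing: {list(m.genes)}"
            )

    ranks = rankdata(-x, axis=1, method="average")
    capped = np.minimum(ranks, max_rank + 1)

    out = {}
    for m in modules:
        cols = [index[g] for g in m.genes if g in index]
        n_missing = len(m.genes) - len(cols)
        n = len(m.genes)
        rank_sum = capped[:, cols].sum(axis=1) + n_missing * (max_rank + 1)
        u = rank_sum - n * (n + 1) / 2.0
        out[m.name] = np.maximum(0.0, 1.0 - u / (n * max_rank))
    return pd.DataFrame(out)


def score_module(
    values,
    gene_ids: list[str],
    module: GeneModule,
    max_rank: int = DEFAULT_MAX_RANK,
) -> np.ndarray:
    """Per-cell score for a single module (see :func:`score_modules`)."""
    return score_modules(values, gene_ids, [module], max_rank)[module.name].to_numpy()


def summarize_groups(
    normalized: np.ndarray,
    counts,
    group_labels,
    gene_ids: list[str],
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Dot-plot statistics per (group, gene).

    ``mean``: group mean of library-size-normalized expression (the linear
    per-10k scale, i.e. ``expm1`` of the log values); ``scaled_mean``: z-score
    of the group means per gene across groups (all zeros with a single group);
    ``frac_expressing``: fraction of the group's cells with count > 0.
    Empty groups are excluded with a warning.
    """
    labels = pd.Series(list(group_labels))
    if labels.isna().any():
        raise ValidationError("every cell must carry a group label")
    genes = genes if genes is not None else list(gene_ids)
    idx = [gene_ids.index(g) for g in genes]
    lin = np.expm1(np.asarray(normalized, dtype=float)[:, idx])
    cnt = _dense(counts)[:, idx]

    groups = [g for g in pd.unique(labels)]
    rows = []
    means = []
    for g in groups:
        mask = (labels == g).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"group {g!r} has no cells; excluded")
            continue
        means.append(lin[mask].mean(axis=0))
        rows.append((g, (cnt[mask] > 0).mean(axis=0)))
    mean_mat = np.vstack(means)
    if mean_mat.shape[0] >= 2:
        mu = mean_mat.mean(axis=0)
        sd = mean_mat.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (mean_mat - mu) / sd
        scaled[:, sd == 0] = 0.0
    else:
        scaled = np.zeros_like(mean_mat)

    records = []
    for i, (g, frac) in enumerate(rows):
        for j, gene in enumerate(genes):
            records.append(
                {
                    "group": g,
                    "gene": gene,
                    "mean": mean_mat[i, j],
                    "scaled_mean": scaled[i, j],
                    "frac_expressing": frac[j],
                }
            )
    return pd.DataFrame(records)


def _split_1d_2means(values: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D two-cluster k-means via sorted prefix sums.

    Returns (threshold, low mean, high mean); cells strictly above the
    threshold belong to the high cluster. Deterministic.
    """
    srt = np.sort(values)
    n = len(srt)
    prefix = np.concatenate([[0.0], np.cumsum(srt)])
    prefix2 = np.concatenate([[0.0], np.cumsum(srt**2)])
    best = (np.inf, n)  # (sse, split size k of low cluster)
    for k in range(1, n):
        lo_sum, hi_sum = prefix[k], prefix[n] - prefix[k]
        lo_ss, hi_ss = prefix2[k], prefix2[n] - prefix2[k]
        sse = (lo_ss - lo_sum**2 / k) + (hi_ss - hi_sum**2 / (n - k))
        if sse < best[0] - 1e-12:
            best = (sse, k)
    k = best[1]
    if k >= n:
        return np.inf, float(srt.mean()), float(srt.mean())
    lo_mean = float(prefix[k] / k)
    hi_mean = float((prefix[n] - prefix[k]) / (n - k))
    threshold = (srt[k - 1] + srt[k]) / 2.0
    return float(threshold), lo_mean, hi_mean


def call_adt_positive(
    clr_adt: np.ndarray,
    lane_ids,
    tag_ids: list[str] | None = None,
    min_cells: int = 10,
    min_separation: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Call cells positive per tag via a per-lane two-group split of CLR values.

    For each (tag, lane) the 1-D values are split into two clusters (exact
    two-means); cells in the higher-mean cluster are positive. Lanes with
    fewer than ``min_cells`` cells, or whose cluster-mean separation falls
    below ``min_separation`` CLR units, are called all-negative with a warning.
    Returns the boolean cells x tags matrix and a per-(tag, lane) info table.
    """
    x = np.asarray(clr_adt, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite CLR values")
    lane_ids = np.asarray(lane_ids)
    if tag_ids is None:
        tag_ids = [f"tag{j}" for j in range(x.shape[1])]
    positive = np.zeros_like(x, dtype=bool)
    info = []
    for lane in pd.unique(lane_ids):
        rows = np.flatnonzero(lane_ids == lane)
        for j, tag in enumerate(tag_ids):
            vals = x[rows, j]
            if len(rows) < min_cells:
                warnings.warn(f"lane {lane!r}: fewer than {min_cells} cells")
                sep, thr = 0.0, np.inf
            else:
                thr, lo, hi = _split_1d_2means(vals)
                sep = hi - lo
                if sep < min_separation:
                    warnings.warn(
                        f"lane {lane!r} tag {tag!r}: separation {sep:.2f} below floor"
                    )
                    thr = np.inf
                else:
                    positive[rows[vals > thr], j] = True
            info.append(
                {
                    "tag": tag,
                    "lane": lane,
                    "n_cells": len(rows),
                    "threshold": thr,
                    "separation": sep,
                    "frac_positive": positive[rows, j].mean() if len(rows) else 0.0,
                }
            )
    return positive, pd.DataFrame(info)


def positive_fractions_by_group(positive: np.ndarray, group_labels) -> pd.DataFrame:
    """Fraction of positive cells per (group, tag column)."""
    labels = pd.Series(list(group_labels))
    rows = []
    for g in pd.unique(labels):
        mask = (labels == g).to_numpy()
        for j in range(positive.shape[1]):
            rows.append(
                {"group": g, "tag_index": j, "frac_positive": positive[mask, j].mean()}
            )
    return pd.DataFrame(rows)
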