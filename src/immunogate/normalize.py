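"""Expression normalization: log library-size scaling, z-scaling,
dispersion-based variable-gene selection, and per-lane CLR for ADT counts.

All routines operate on plain numpy arrays (cells x genes) so they compose
freely; zero counts map to zero normalized values throughout.
"""

from __future__ import annotations

import fnmatch
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ValidationError

SCALE_FACTOR = 10_000


def _dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def lognormalize(
    counts, scale_factor: float = SCALE_FACTOR, cell_ids: list[str] | None = None
) -> np.ndarray:
    """Library-size normalize and log transform: ``ln(1 + sf * x / T_cell)``.

    Every cell must have a positive total count; offending cells are named in
    the error. Preserves the zero pattern and within-cell ordering of genes.
    """
    x = _dense(counts)
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        name = cell_ids[bad] if cell_ids is not None else f"index {bad}"
        raise ValidationError(f"cell {name} has zero total count")
    return np.log1p(scale_factor * x / totals[:, None])


def zscale(values: np.ndarray, clip: float = 10.0, ddof: int = 1) -> np.ndarray:
    """Per-gene z-scores over cells (sample SD by default), clipped to ±clip.

    Genes with zero variance map to all zeros. Requires at least two cells.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValidationError("z-scaling requires at least two cells")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    z[:, sd == 0] = 0.0
    return np.clip(z, -clip, clip)


def load_exclusion_patterns(path=None) -> list[str]:
    """Read the variable-gene exclusion list: one glob or symbol per line,
    ``#`` comments. Defaults to the packaged list (class-I MHC and ribosomal
    patterns)."""
    if path is None:
        text = (
            resources.files("immunogate.data")
            .joinpath("exclude_patterns.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    patterns = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(line)
    return patterns


def _excluded_mask(gene_ids: list[str], patterns: list[str]) -> np.ndarray:
    out = np.zeros(len(gene_ids), dtype=bool)
    for pat in patterns:
        out |= np.array(
            [fnmatch.fnmatchcase(g, pat) or g == pat for g in gene_ids]
        )
    return out


def select_variable_genes(
    normalized: np.ndarray,
    gene_ids: list[str],
    cutoff: float = 0.5,
    n_top: int | None = None,
    exclude_patterns: list[str] | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean/dispersion variable-gene selection with an exclusion list.

    Dispersion is ``ln(variance/mean)`` of the exp-normalized (linear per-10k)
    expression; genes are cut into ``n_bins`` equal-occupancy bins of log-mean
    and the dispersion z-scored within each bin. Selected genes have standardized
    dispersion >= ``cutoff`` and are not excluded; if ``n_top`` is given, the
    top ``n_top`` by standardized dispersion (after exclusion) are selected
    instead. Excluded genes remain in the matrix — exclusion only affects
    selection.
    """
    if normalized.shape[0] < 2:
        raise ValidationError("variable-gene selection requires >= 2 cells")
    y = np.expm1(np.asarray(normalized, dtype=float))
    mean = y.mean(axis=0)
    var = y.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, np.log(np.maximum(var, 1e-300) / mean), 0.0)
    disp[var == 0] = -np.inf  # constant genes can never be selected

    # standardize dispersion within equal-occupancy bins of log-mean
    log_mean = np.log1p(mean)
    finite = np.isfinite(disp)
    disp_std = np.full(len(gene_ids), -np.inf)
    if finite.any():
        bins = pd.qcut(
            pd.Series(log_mean).rank(method="first"),
            q=min(n_bins, len(gene_ids)),
            labels=False,
            duplicates="drop",
        )
        df = pd.DataFrame({"bin": bins, "disp": np.where(finite, disp, np.nan)})
        grouped = df.groupby("bin")["disp"]
        mu_b = grouped.transform("mean")
        sd_b = grouped.transform("std")
        z = (df["disp"] - mu_b) / sd_b
        z = z.fillna(0.0).to_numpy()
        disp_std = np.where(finite, z, -np.inf)

    excluded = _excluded_mask(
        gene_ids, exclude_patterns if exclude_patterns is not None else []
    )
    if excluded.all():
        raise ValidationError("all genes excluded from variable-gene selection")

    eligible = ~excluded & np.isfinite(disp_std)
    if n_top is not None:
        order = np.argsort(-np.where(eligible, disp_std, -np.inf), kind="stable")
        selected = np.zeros(len(gene_ids), dtype=bool)
        selected[order[: min(n_top, int(eligible.sum()))]] = True
        selected &= eligible
    else:
        selected = eligible & (disp_std >= cutoff)

    return pd.DataFrame(
        {
            "gene": gene_ids,
            "mean": mean,
            "dispersion": disp,
            "dispersion_std": np.where(np.isfinite(disp_std), disp_std, np.nan),
            "excluded": excluded,
            "selected": selected,
        }
    )


def _clr_vector(x: np.ndarray) -> np.ndarray:
    # geometric mean of (1 + x) over positive entries, divided by full length
    logs = np.log1p(x[x > 0])
    g = np.exp(logs.sum() / len(x)) if len(x) else 1.0
    return np.log1p(x / g)


def clr_normalize_adt(
    adt_counts: np.ndarray, lane_ids, margin: str = "feature"
) -> np.ndarray:
    """Centered log-ratio normalization of ADT counts, independently per lane.

    ``margin="feature"`` transforms each tag's vector across the cells of a
    lane (the default, reducing between-lane antibody/batch effects);
    ``margin="cell"`` transforms each cell's vector across tags. The transform
    of a vector x is ``ln(1 + x_i / g(x))`` with
    ``g(x) = exp(mean over the full vector length of ln(1 + x_j), summed over
    positive entries)``. An all-zero vector maps to zeros.
    """
    x = _dense(adt_counts)
    lane_ids = np.asarray(lane_ids)
    if lane_ids.shape[0] != x.shape[0]:
        raise ValidationError("lane labels do not cover all cells")
    if pd.isna(lane_ids).any():
        raise ValidationError("cell with unknown lane id")
    if margin not in ("feature", "cell"):
        raise ValidationError(f"unknown CLR margin {margin!r}")

    out = np.zeros_like(x)
    for lane in pd.unique(lane_ids):
        rows = np.flatnonzero(lane_ids == lane)
        block = x[rows]
        if margin == "feature":
            for j in range(block.shape[1]):
                out[rows, j] = _clr_vector(block[:, j])
        else:
            for i, r in enumerate(rows):
                out[r] = _clr_vector(block[i])
    return out
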