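"""Per-cell saturation and droplet quality-control filters.

Saturation is ``1 - UMIs/reads``: the fraction of sequencing reads that
re-sampled an already-seen molecule. It measures how completely each cell's
molecule pool was sampled and, unlike fixed count cutoffs, adapts across cell
types with very different RNA content. Cells are kept when their UMI total and
detected-feature count fall inside inclusive ranges and their RNA (and, when
present, ADT) saturation strictly exceeds a floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import CountBundle
from .exceptions import ValidationError

RULES = ("umi_min", "umi_max", "features_min", "features_max", "rna_sat", "adt_sat")


@dataclass(frozen=True)
class QCThresholds:
    """Filter bounds. Count ranges are inclusive; saturation floors are strict."""

    umi_min: int = 0
    umi_max: int = 20_000
    features_min: int = 200
    features_max: int = 5_000
    rna_saturation_min: float = 0.35
    adt_saturation_min: float = 0.10

    def __post_init__(self) -> None:
        if self.umi_min > self.umi_max or self.features_min > self.features_max:
            raise ValidationError("QC range minimum exceeds maximum")
        for s in (self.rna_saturation_min, self.adt_saturation_min):
            if not (0.0 <= s < 1.0):
                raise ValidationError("saturation bounds must lie in [0, 1)")


@dataclass
class QCReport:
    """Per-cell QC outcome plus per-rule failure tallies."""

    per_cell: pd.DataFrame  # columns: cell_id, umis, features, rna_saturation,
    #          adt_saturation, passed, first_fail, fail_reasons
    rule_counts: dict[str, int]

    @property
    def n_pass(self) -> int:
        return int(self.per_cell["passed"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.per_cell["passed"]).sum())


def compute_saturation(umis, reads):
    """``1 - umis/reads`` for scalars or aligned arrays.

    Requires ``reads > 0`` and ``0 <= umis <= reads``; the result lies in [0, 1).
    """
    umis_a = np.asarray(umis, dtype=float)
    reads_a = np.asarray(reads, dtype=float)
    if np.any(reads_a <= 0):
        raise ValidationError("saturation undefined for cells with zero reads")
    if np.any(umis_a < 0) or np.any(umis_a > reads_a):
        raise ValidationError("UMI count must lie in [0, reads]")
    out = 1.0 - umis_a / reads_a
    if np.isscalar(umis) and np.isscalar(reads):
        return float(out)
    return out


def apply_qc(
    bundle: CountBundle, thresholds: QCThresholds | None = None
) -> tuple[QCReport, CountBundle]:
    """Evaluate all QC rules on every cell and return (report, filtered bundle).

    Rules are evaluated in a fixed order (UMI range, feature range, RNA
    saturation, ADT saturation); the first failure is recorded as the primary
    reason while all failures are tallied. Cells without ADT data skip the ADT
    rule. If read totals are unavailable (all zero), saturation rules are
    skipped with a warning.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if bundle.n_cells == 0:
        raise ValidationError("cannot QC an empty bundle")

    umis = bundle.umis_per_cell()
    features = bundle.features_per_cell()
    n = bundle.n_cells

    have_reads = np.any(bundle.rna_reads_per_cell > 0)
    if not have_reads:
        warnings.warn("no read totals available; skipping saturation rules")
        rna_sat = np.full(n, np.nan)
    else:
        rna_sat = np.where(
            bundle.rna_reads_per_cell > 0,
            1.0 - umis / np.maximum(bundle.rna_reads_per_cell, 1),
            np.nan,
        )

    adt_sat = np.full(n, np.nan)
    if bundle.adt_counts is not None and bundle.adt_reads_per_cell is not None:
        adt_umis = bundle.adt_counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            adt_sat = np.where(
                bundle.adt_reads_per_cell > 0,
                1.0 - adt_umis / np.maximum(bundle.adt_reads_per_cell, 1),
                np.nan,
            )

    checks = {
        "umi_min": umis < thresholds.umi_min,
        "umi_max": umis > thresholds.umi_max,
        "features_min": features < thresholds.features_min,
        "features_max": features > thresholds.features_max,
        "rna_sat": (
            ~np.isnan(rna_sat) & (rna_sat <= thresholds.rna_saturation_min)
            if have_reads
            else np.zeros(n, dtype=bool)
        ),
        "adt_sat": ~np.isnan(adt_sat) & (adt_sat <= thresholds.adt_saturation_min),
    }

    first_fail = np.array([""] * n, dtype=object)
    reasons = [[] for _ in range(n)]
    for rule in RULES:
        failing = checks[rule]
        for i in np.flatnonzero(failing):
            reasons[i].append(rule)
            if first_fail[i] == "":
                first_fail[i] = rule
    passed = np.array([len(r) == 0 for r in reasons])

    per_cell = pd.DataFrame(
        {
            "cell_id": bundle.cell_ids,
            "umis": umis,
            "features": features,
            "rna_saturation": rna_sat,
            "adt_saturation": adt_sat,
            "passed": passed,
            "first_fail": first_fail,
            "fail_reasons": [";".join(r) for r in reasons],
        }
    )
    rule_counts = {rule: int(checks[rule].sum()) for rule in RULES}
    return QCReport(per_cell=per_cell, rule_counts=rule_counts), bundle.subset_cells(
        passed
    )
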