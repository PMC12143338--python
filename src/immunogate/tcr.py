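"""TCR contig filtering, clonotype grouping and clonality classification.

Raw V(D)J contig calls are filtered with the chimera rules used for macaque
TCR data: a contig must carry a CDR3, be full length, and have called V, J and
constant segments whose locus prefixes agree (TRA/TRB/TRG/TRD). Two chimeric
combinations are biologically expected and kept — TRDV paired with TRAC
(classified as TRA) and TRAV paired with TRDC (classified as TRD) — with the
chain always reassigned from the constant-region locus.

Clonotypes are keyed by (locus, CDR3 amino-acid sequence) by default and
classified as ``singleton`` (one cell), ``expanded`` (multiple cells in one
subject) or ``public`` (seen in more than one subject), with precedence
public > expanded > singleton.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

LOCI = ("TRA", "TRB", "TRG", "TRD")

REQUIRED_CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "cdr3",
    "cdr3_nt",
    "full_length",
    "productive",
    "umis",
]

CONTIG_CSV_COLUMNS = [
    "barcode",
    "is_cell",
    "contig_id",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
]


@dataclass
class ContigRecord:
    """One V(D)J contig call for one cell. ``None`` marks an absent segment."""

    barcode: str
    subject_id: str | None
    chain: str | None
    v_gene: str | None
    d_gene: str | None
    j_gene: str | None
    c_gene: str | None
    cdr3_aa: str | None
    cdr3_nt: str | None
    full_length: bool
    productive: bool
    umis: int


def _absent(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"none", "nan", "na"}:
        return None
    return s


def _flag(value) -> bool:
    return str(value).strip().lower() in {"true", "t", "1", "yes"}


def read_contigs(
    path: str | Path, subject_map: dict[str, str] | str | Path | None = None
) -> list[ContigRecord]:
    """Parse a cellranger-vdj-style contig annotation CSV into records.

    Missing values are mapped to ``None`` (an explicit "absent" marker); no
    filtering happens here. ``subject_map`` may be a dict or a path to a
    two-column TSV mapping barcode -> subject_id.
    """
    path = Path(path)
    if isinstance(subject_map, (str, Path)):
        sm = pd.read_csv(subject_map, sep="\t", header=None, dtype=str)
        subject_map = dict(zip(sm.iloc[:, 0], sm.iloc[:, 1]))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"contig CSV lacks required columns: {missing}")
        records = []
        for row in reader:
            bc = str(row["barcode"]).strip()
            umis = _absent(row.get("umis"))
            records.append(
                ContigRecord(
                    barcode=bc,
                    subject_id=(subject_map or {}).get(bc),
                    chain=_absent(row.get("chain")),
                    v_gene=_absent(row.get("v_gene")),
                    d_gene=_absent(row.get("d_gene")),
                    j_gene=_absent(row.get("j_gene")),
                    c_gene=_absent(row.get("c_gene")),
                    cdr3_aa=_absent(row.get("cdr3")),
                    cdr3_nt=_absent(row.get("cdr3_nt")),
                    full_length=_flag(row.get("full_length")),
                    productive=_flag(row.get("productive")),
                    umis=int(umis) if umis is not None else 0,
                )
            )
    return records


def write_contigs(records: list[ContigRecord], path: str | Path) -> None:
    """Write records in the cellranger-vdj-compatible CSV schema."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONTIG_CSV_COLUMNS)
        for i, r in enumerate(records):
            writer.writerow(
                [
                    r.barcode,
                    "true",
                    f"{r.barcode}_contig_{i}",
                    "true",
                    r.chain or "",
                    r.v_gene or "",
                    r.d_gene or "",
                    r.j_gene or "",
                    r.c_gene or "",
                    "true" if r.full_length else "false",
                    "true" if r.productive else "false",
                    r.cdr3_aa or "",
                    r.cdr3_nt or "",
                    r.umis * 3,
                    r.umis,
                ]
            )


def segment_locus(symbol: str | None, position: str) -> str | None:
    """Return the TR locus of a segment symbol (e.g. ``TRBV6`` -> ``TRB``).

    ``position`` is the expected segment letter (V/D/J/C). Returns ``None``
    for unparseable symbols.
    """
    if symbol is None or len(symbol) < 4:
        return None
    locus, seg = symbol[:3], symbol[3]
    if locus not in LOCI or seg != position:
        return None
    return locus


# Permitted chimeric (V locus, C locus) pairs; kept chain follows the C locus.
_CHIMERA_EXCEPTIONS = {("TRD", "TRA"), ("TRA", "TRD")}


def filter_contigs(
    records: list[ContigRecord],
) -> tuple[list[ContigRecord], dict[str, int]]:
    """Apply the contig quality and chimera rules.

    Drop reasons (first failing rule recorded, tallies exhaustive):
    ``no_cdr3``, ``not_full_length``, ``missing_segment`` (V, J or C absent),
    ``unparseable`` (a present segment without a TR-locus prefix), and
    ``chimeric`` (V/J/C loci disagree outside the permitted TRDV/TRAC and
    TRAV/TRDC pairs). Kept records have their chain reassigned from the
    constant-region locus.
    """
    kept: list[ContigRecord] = []
    drops = {
        "no_cdr3": 0,
        "not_full_length": 0,
        "missing_segment": 0,
        "unparseable": 0,
        "chimeric": 0,
    }
    for r in records:
        if r.cdr3_aa is None:
            drops["no_cdr3"] += 1
            continue
        if not r.full_length:
            drops["not_full_length"] += 1
            continue
        if r.v_gene is None or r.j_gene is None or r.c_gene is None:
            drops["missing_segment"] += 1
            continue
        v = segment_locus(r.v_gene, "V")
        j = segment_locus(r.j_gene, "J")
        c = segment_locus(r.c_gene, "C")
        if v is None or j is None or c is None:
            drops["unparseable"] += 1
            continue
        if v == j == c:
            kept.append(replace(r, chain=c))
        elif (v, c) in _CHIMERA_EXCEPTIONS and j in (v, c):
            kept.append(replace(r, chain=c))
        else:
            drops["chimeric"] += 1
    return kept, drops


def best_records_per_cell(records: list[ContigRecord]) -> list[ContigRecord]:
    """Keep the highest-UMI record per (barcode, chain); stable on ties."""
    best: dict[tuple[str, str | None], ContigRecord] = {}
    for r in records:
        key = (r.barcode, r.chain)
        if key not in best or r.umis > best[key].umis:
            best[key] = r
    return list(best.values())


def group_clonotypes(
    records: list[ContigRecord], key: str = "locus_cdr3"
) -> pd.DataFrame:
    """Group kept contigs into cross-subject clonotypes.

    ``key`` is ``locus_cdr3`` (default: chain locus + CDR3 amino acids) or
    ``vj_cdr3`` (additionally includes the V and J segments). Cells with
    multiple kept records of one chain contribute their highest-UMI record.
    Rows are ordered by descending total cell count, then key.
    """
    records = best_records_per_cell(records)
    rows: dict[str, dict] = {}
    for r in records:
        if key == "vj_cdr3":
            k = f"{r.chain}:{r.v_gene}:{r.j_gene}:{r.cdr3_aa}"
        else:
            k = f"{r.chain}:{r.cdr3_aa}"
        entry = rows.setdefault(
            k,
            {"clonotype": k, "locus": r.chain, "cdr3_aa": r.cdr3_aa, "cells": {}},
        )
        subject = r.subject_id if r.subject_id is not None else "unknown"
        entry["cells"].setdefault(subject, set()).add(r.barcode)
    out = []
    for entry in rows.values():
        per_subject = {s: len(bcs) for s, bcs in sorted(entry["cells"].items())}
        out.append(
            {
                "clonotype": entry["clonotype"],
                "locus": entry["locus"],
                "cdr3_aa": entry["cdr3_aa"],
                "subject_counts": per_subject,
                "n_subjects": len(per_subject),
                "total_cells": sum(per_subject.values()),
            }
        )
    table = pd.DataFrame(
        out,
        columns=[
            "clonotype",
            "locus",
            "cdr3_aa",
            "subject_counts",
            "n_subjects",
            "total_cells",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["total_cells", "clonotype"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def classify_clonality(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``clonality`` column: public > expanded > singleton."""
    table = table.copy()

    def _cls(row) -> str:
        if row["n_subjects"] >= 2:
            return "public"
        if row["total_cells"] >= 2:
            return "expanded"
        return "singleton"

    table["clonality"] = (
        table.apply(_cls, axis=1) if len(table) else pd.Series(dtype=object)
    )
    return table


def top_expanded(table: pd.DataFrame, n: int = 25, locus: str = "TRB") -> pd.DataFrame:
    """The ``n`` most expanded clonotypes of one locus.

    Sorted by descending total cells; ties broken by CDR3 lexicographically.
    """
    sub = table[table["locus"] == locus].copy()
    sub = sub.sort_values(["total_cells", "cdr3_aa"], ascending=[False, True])
    return sub.head(n).reset_index(drop=True)


CD3_GENES = ("CD3D", "CD3E", "CD3G")
CD16_GENES = ("FCGR3", "FCGR3A")


def chain_sets_per_cell(records: list[ContigRecord]) -> dict[str, set[str]]:
    """Map barcode -> set of chain loci among kept contigs."""
    sets: dict[str, set[str]] = {}
    for r in best_records_per_cell(records):
        if r.chain is not None:
            sets.setdefault(r.barcode, set()).add(r.chain)
    return sets


def categorize_cells_tcr(
    cell_ids: list[str],
    chain_sets: dict[str, set[str]],
    cd3_positive: np.ndarray,
    cd16_positive: np.ndarray,
) -> pd.Series:
    """Six-way categorization from TCR chain presence and CD3/CD16 RNA.

    ``abT`` (TRA/TRB chains), ``gdT`` (TRG/TRD), ``abT+gdT`` (both),
    ``TCRneg_CD3pos``, ``NK_like`` (TCR-, CD3-, CD16+), and
    ``TCRneg_CD3neg_CD16neg``.
    """
    cd3_positive = np.asarray(cd3_positive, dtype=bool)
    cd16_positive = np.asarray(cd16_positive, dtype=bool)
    out = []
    for i, cid in enumerate(cell_ids):
        chains = chain_sets.get(cid, set())
        ab = bool(chains & {"TRA", "TRB"})
        gd = bool(chains & {"TRG", "TRD"})
        if ab and gd:
            out.append("abT+gdT")
        elif ab:
            out.append("abT")
        elif gd:
            out.append("gdT")
        elif cd3_positive[i]:
            out.append("TCRneg_CD3pos")
        elif cd16_positive[i]:
            out.append("NK_like")
        else:
            out.append("TCRneg_CD3neg_CD16neg")
    return pd.Series(out, index=list(cell_ids), name="tcr_category")


def rna_positive(counts, gene_ids: list[str], genes: tuple[str, ...]) -> np.ndarray:
    """Per-cell flag: any of ``genes`` has count > 0."""
    idx = [gene_ids.index(g) for g in genes if g in gene_ids]
    if not idx:
        return np.zeros(counts.shape[0], dtype=bool)
    sub = counts[:, idx]
    if hasattr(sub, "toarray"):
        sub = sub.toarray()
    return np.asarray(sub > 0).any(axis=1)
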