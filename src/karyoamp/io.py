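"""TSV/JSON input and output for records, profiles, matrices and flags."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .karyotype import CytogeneticProfile, KaryotypeRecord, chrom_sort_key

RECORD_COLUMNS = ("cell_line_id", "source", "karyotype_text", "validation_source")

#: Fixed column order of the profile table.
PROFILE_COLUMNS = (
    "cell_line_id",
    "modal_number",
    "modal_range_low",
    "modal_range_high",
    "ploidy_class",
    "percent_polyploidy",
    "sex_complement",
    "dmin_min",
    "dmin_max",
    "hsr_count",
    "marker_min",
    "marker_max",
    "chrom_gains",
    "chrom_losses",
    "derivative_chroms",
    "translocation_chroms",
    "structural_variant_total",
    "unparsed_token_count",
)


def read_records_tsv(path: str | Path) -> list[KaryotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records TSV missing columns: {sorted(missing)}")
    return [
        KaryotypeRecord(
            cell_line_id=row.cell_line_id,
            source=row.source,
            raw_text=row.karyotype_text,
            validation_source=row.validation_source,
        )
        for row in df.itertuples()
    ]


def write_records_tsv(records: Iterable[KaryotypeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_line_id": r.cell_line_id,
                "source": r.source,
                "karyotype_text": r.raw_text,
                "validation_source": r.validation_source,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _join_chroms(chroms: Iterable[str]) -> str:
    return ";".join(sorted(chroms, key=chrom_sort_key))


def profiles_to_frame(profiles: Sequence[CytogeneticProfile], cell_ids: Sequence[str]) -> pd.DataFrame:
    """One row per cell line, fixed column order; sets serialised ';'-joined."""
    rows = []
    for cid, p in zip(cell_ids, profiles):
        rows.append(
            {
                "cell_line_id": cid,
                "modal_number": p.modal_number if p.modal_number is not None else "",
                "modal_range_low": p.modal_range[0] if p.modal_range else "",
                "modal_range_high": p.modal_range[1] if p.modal_range else "",
                "ploidy_class": p.ploidy_class,
                "percent_polyploidy": p.percent_polyploidy,
                "sex_complement": p.sex_complement,
                "dmin_min": p.dmin_range[0],
                "dmin_max": p.dmin_range[1],
                "hsr_count": p.hsr_count,
                "marker_min": p.marker_range[0],
                "marker_max": p.marker_range[1],
                "chrom_gains": ";".join(f"{c}:{n}" for c, n in sorted(p.chrom_gains.items(), key=lambda kv: chrom_sort_key(kv[0]))),
                "chrom_losses": ";".join(f"{c}:{n}" for c, n in sorted(p.chrom_losses.items(), key=lambda kv: chrom_sort_key(kv[0]))),
                "derivative_chroms": _join_chroms(p.derivative_chroms),
                "translocation_chroms": ";".join(
                    f"{a}-{b}" for a, b in sorted(p.translocation_chroms, key=lambda pr: (chrom_sort_key(pr[0]), chrom_sort_key(pr[1])))
                ),
                "structural_variant_total": p.structural_variant_total,
                "unparsed_token_count": p.unparsed_token_count,
            }
        )
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Gene × cell matrix: header row of cell ids, first column gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_flags_tsv(path: str | Path) -> dict[str, bool]:
    """Two-column (cell_id, flag) table of external ecDNA-caller calls."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("flags TSV needs (cell_id, flag) columns")
    cells = df.iloc[:, 0].astype(str)
    flags = df.iloc[:, 1].astype(str).str.lower().isin(("1", "true", "yes"))
    return dict(zip(cells, flags))


def summarize_annotations(df: pd.DataFrame) -> dict[str, int]:
    """Count annotation classes in a curated label table.

    Expects ``ecdna`` and ``hsr`` columns holding positive/negative/unknown.
    Returns ecDNA+/ecDNA−/HSR+ counts and the total number of annotated
    cell lines (rows with at least one non-unknown label).
    """
    for col in ("ecdna", "hsr"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    annotated = (df["ecdna"] != "unknown") | (df["hsr"] != "unknown")
    return {
        "ecdna_positive": int((df["ecdna"] == "positive").sum()),
        "ecdna_negative": int((df["ecdna"] == "negative").sum()),
        "hsr_positive": int((df["hsr"] == "positive").sum()),
        "total_annotated": int(annotated.sum()),
    }
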