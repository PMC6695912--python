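"""Rendering of result tables.

Tables mirror the study's reporting layout: per-motion accuracies as
(feature set x motion) rows by classifier columns with the best cell per
row marked, vote tables as all/top/weighted rows per feature set, and a QC
summary of segmentation flags.  Rendering only formats stored frames; it
never recomputes a number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pipeline import ReportBundle


def mark_best(table: pd.DataFrame, fmt: str = "{:.1f}") -> pd.DataFrame:
    """Format a numeric table, wrapping the row-wise maximum in asterisks."""
    out = table.copy().astype(object)
    for ix, row in table.iterrows():
        vals = pd.to_numeric(row, errors="coerce")
        best = vals.idxmax() if vals.notna().any() else None
        for col in table.columns:
            cell = fmt.format(row[col]) if pd.notna(row[col]) else ""
            out.loc[ix, col] = f"*{cell}*" if col == best else cell
    return out


def render_tables(bundle: ReportBundle, out_dir: str | Path,
                  formats: tuple[str, ...] = ("csv", "txt")) -> list[Path]:
    """Write the bundle's tables as CSV and aligned plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "per_motion_accuracy": bundle.per_motion_accuracy,
        "vote_accuracy": bundle.vote_accuracy,
        "qc_summary": bundle.qc_summary,
    }
    if bundle.individual_ranking is not None:
        tables["individual_ranking"] = bundle.individual_ranking
    for name, table in tables.items():
        if "csv" in formats:
            p = out / f"{name}.csv"
            table.to_csv(p)
            written.append(p)
        if "txt" in formats:
            p = out / f"{name}.txt"
            if name in ("per_motion_accuracy", "vote_accuracy") and len(table):
                p.write_text(mark_best(table).to_string() + "\n")
            else:
                p.write_text(table.to_string() + "\n")
            written.append(p)
    return written


def qc_counts(qc: pd.DataFrame) -> pd.Series:
    """Counts of trials per QC flag (empty flag = clean)."""
    flags = qc["flags"].fillna("").replace("", "clean")
    return flags.value_counts()
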