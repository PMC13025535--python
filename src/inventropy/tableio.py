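"""Delimited-table input and report output.

Input is a headered CSV/TSV; selected columns are parsed as finite
reals, and rows with missing or non-numeric values in any selected
column are dropped (listwise deletion) with a logged count. Reports
serialize to TSV or JSON with full float precision (17 significant
digits), so write-then-read round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import ExperimentReport

__all__ = ["ColumnTable", "read_table", "write_report", "read_report_json"]

logger = logging.getLogger("inventropy")


@dataclass
class ColumnTable:
    """Named, equal-length numeric columns."""

    names: list[str]
    columns: np.ndarray  # shape (n_rows, len(names))

    @property
    def n_rows(self) -> int:
        return self.columns.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.columns[:, self.names.index(name)]


def read_table(path, delimiter: str | None = None,
               select: list[str] | None = None) -> ColumnTable:
    """Read selected numeric columns from a delimited text file.

    ``delimiter=None`` auto-detects (TSV by extension, sniffed
    otherwise). Rows containing non-numeric or missing values in the
    selected columns are dropped with a logged count.
    """
    path = Path(path)
    if delimiter is None:
        # extension first; csv.Sniffer misfires on single-column files
        suffix = path.suffix.lower()
        if suffix in (".tsv", ".tab"):
            delimiter = "\t"
        elif suffix in (".csv", ".txt"):
            delimiter = ","
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"unparseable file {path}: {exc}") from exc
    if select is None:
        select = list(df.columns)
    missing = [c for c in select if c not in df.columns]
    if missing:
        raise ValueError(f"unknown column(s) {missing}; "
                         f"available: {list(df.columns)}")
    sub = df[select].apply(pd.to_numeric, errors="coerce")
    sub = sub.replace([np.inf, -np.inf], np.nan)
    keep = sub.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing/non-numeric values "
                       "in %s", dropped, select)
    sub = sub[keep]
    if sub.empty:
        raise ValueError(f"zero usable rows in {path} for columns {select}")
    return ColumnTable(names=list(select),
                       columns=sub.to_numpy(dtype=float))


def _report_payload(report: ExperimentReport) -> dict:
    return {"design": report.design, "config_echo": report.config_echo,
            "summary": report.summary, "rows": report.rows}


def write_report(obj, path, format: str = "tsv") -> None:
    """Write an ExperimentReport or a labeled MI matrix to disk.

    ``obj`` is either an :class:`ExperimentReport` or a pandas DataFrame
    (e.g. a symmetric MI matrix with column labels on both axes).
    Numeric fields keep 17 significant digits in TSV; JSON uses native
    floats (repr round-trips).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    try:
        if isinstance(obj, ExperimentReport):
            if fmt == "json":
                path.write_text(json.dumps(_report_payload(obj), indent=1))
            else:
                obj.to_dataframe().to_csv(path, sep="\t", index=False,
                                          float_format="%.17g")
        elif isinstance(obj, pd.DataFrame):
            if fmt == "json":
                path.write_text(json.dumps(
                    {"index": list(obj.index), "columns": list(obj.columns),
                     "values": obj.to_numpy().tolist()}, indent=1))
            else:
                obj.to_csv(path, sep="\t", float_format="%.17g")
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc


_REPORT_KEYS = {"design": str, "config_echo": dict, "summary": dict,
                "rows": list}
_ROW_KEYS = {"condition": str, "mean": (int, float), "sd": (int, float),
             "n": int, "replicates": int, "k_or_bins": int, "seed": int}


def read_report_json(path) -> ExperimentReport:
    """Read back a JSON report, validating its schema."""
    data = json.loads(Path(path).read_text())
    for key, typ in _REPORT_KEYS.items():
        if key not in data or not isinstance(data[key], typ):
            raise ValueError(f"report JSON missing or mistyped field {key!r}")
    for row in data["rows"]:
        for key, typ in _ROW_KEYS.items():
            if key not in row or not isinstance(row[key], typ):
                raise ValueError(f"report row missing or mistyped {key!r}")
    return ExperimentReport(design=data["design"], rows=data["rows"],
                            config_echo=data["config_echo"],
                            summary=data.get("summary", {}))
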