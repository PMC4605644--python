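"""Reading and writing the plain-text formats of the pipeline.

Expression matrices are TSV (rows = features, first column feature ids,
header = sample ids); sample sheets are CSV with columns sample_id, group,
batch. Values are parsed dot-decimal regardless of locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


class ParseError(ValueError):
    pass


def read_expression_tsv(path) -> pd.DataFrame:
    """Parse a feature-by-sample intensity matrix.

    Rejects duplicate feature/sample ids, ragged rows and non-numeric cells,
    reporting the offending line where possible.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dupes:
        raise ParseError(f"duplicated sample column header(s): {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed TSV {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicated feature id(s): {dup}")
    try:
        values = df.astype(float)
    except ValueError:
        for lineno, (fid, row) in enumerate(df.iterrows(), start=2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell {cell!r} at line {lineno} (feature {fid!r})"
                    ) from None
        raise
    if values.isna().to_numpy().any():
        na_rows = values.index[values.isna().any(axis=1)].tolist()
        raise ParseError(f"missing cells in rows {na_rows} (ragged file?)")
    values.index.name = "feature_id"
    values.attrs["stage"] = "raw"
    return values


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "batch"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet missing column(s): {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ParseError("duplicated sample_id in sample sheet")
    return sheet


def check_matrix_sheet(matrix: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Every matrix sample must appear exactly once in the sheet."""
    sheet_ids = set(sheet["sample_id"])
    missing = [s for s in matrix.columns if s not in sheet_ids]
    if missing:
        raise ParseError(f"samples missing from sheet: {missing[:5]}")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
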