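"""Plain-text I/O: expression/call TSVs, metadata CSV, annotation, GMT.

All writes are atomic (temp file + rename) so a crashed run never leaves
a truncated table behind.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from pathlib import Path

import pandas as pd


def _atomic_write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_expression(path: str | Path) -> pd.DataFrame:
    """Probe x sample TSV with probe ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        import numpy as np

        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError("missing values in expression matrix")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate probe or sample ids")
    return numeric


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    _atomic_write(df, Path(path), sep="\t", index_label="probe_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"sample_id", "region", "age_months", "animal_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    _atomic_write(meta, Path(path), index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = ~calls.isin(["P", "M", "A"])
    if bad.to_numpy().any():
        raise ValueError("detection calls must be P, M or A")
    return calls


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    _atomic_write(calls, Path(path), sep="\t", index_label="probe_id")


def read_annotation(path: str | Path) -> pd.Series:
    """Two-column TSV probe_id, gene_symbol (blank symbol = unmapped)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise ValueError("annotation needs probe_id and gene_symbol columns")
    return df.set_index("probe_id")["gene_symbol"]


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    _atomic_write(annot, Path(path), sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene lists: name <tab> description <tab> symbol...; duplicate
    symbols within a line are collapsed with a warning."""
    lists: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: need name, desc, genes")
        name, _desc, *genes = parts
        genes = [g.strip().upper() for g in genes if g.strip()]
        if len(genes) != len(set(genes)):
            warnings.warn(
                f"GMT line {lineno} ({name}): {len(genes) - len(set(genes))} "
                "duplicate symbols collapsed"
            )
        lists[name] = set(genes)
    return lists


def write_gmt(lists: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            for name in sorted(lists):
                fh.write("\t".join([name, description, *sorted(lists[name])]) + "\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True,
                index_label: str | None = None) -> None:
    _atomic_write(df, Path(path), sep="\t", index=index, index_label=index_label)
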