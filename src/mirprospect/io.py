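"""Readers and writers for the plain-text interchange formats.

* expression TSV — first column ``miRNA`` (row ids), optional ``probe_group``
  column for raw replicate-level matrices, remaining columns one per sample;
* annotation CSV/TSV — one row per sample with the clinical covariates;
* GMT — standard tab-separated category format (name, description, members);
* truth TSV — planted markers with their signed effect sizes.

All writers produce byte-deterministic files; all readers validate structure
and report offending identifiers or line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import StructuralError
from .matrix import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_truth",
    "write_truth",
]


def write_expression(mat: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = mat.values.copy()
    df.insert(0, "miRNA", df.index)
    if mat.probe_group is not None:
        df.insert(1, "probe_group", mat.probe_group.to_numpy())
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_expression(path: str | Path, state: str = "raw") -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "miRNA":
        raise StructuralError(f"{path}: first column must be 'miRNA', got {header[0]!r}")
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise StructuralError(f"{path}: duplicated columns {dup}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df = df.set_index("miRNA")
    probe_group = None
    if "probe_group" in df.columns:
        probe_group = df.pop("probe_group")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise StructuralError(f"{path}: duplicate miRNA ids {dups[:5]}")
    return ExpressionMatrix(values=df, state=state, probe_group=probe_group)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    ann.to_csv(path, sep=sep, index=False, lineterminator="\n")
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    ann = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "sample_id" not in ann.columns:
        raise StructuralError(f"{path}: annotation needs a 'sample_id' column")
    if ann["sample_id"].duplicated().any():
        dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise StructuralError(f"{path}: duplicate sample ids {dups[:5]}")
    return ann


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name -> member-list mapping."""
    path = Path(path)
    categories: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise StructuralError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0]
            if name in categories:
                raise StructuralError(f"{path}:{lineno}: duplicate category name {name!r}")
            categories[name] = [m for m in fields[2:] if m]
    return categories


def write_gmt(
    categories: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in categories.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "signed_d"):
        if col not in truth.columns:
            raise StructuralError(f"{path}: truth table needs a '{col}' column")
    return truth
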