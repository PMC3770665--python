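"""File I/O: TSV matrices, annotation tables, GMT gene-set files, and
reading/writing simulated datasets."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection

__all__ = [
    "read_expression_tsv",
    "write_table",
    "read_annotations_tsv",
    "read_gmt",
    "write_gmt",
    "write_dataset",
    "read_dataset",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample TSV matrix (first column probe id, header row).

    Rejects empty files, ragged rows, non-numeric cells (named by row and
    column in the error) and duplicate probe ids.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate probe ids {dupes!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row][bad.loc[row]].index[0]
        cell = raw.loc[row, col]
        detail = "missing value (ragged row?)" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise ValueError(f"{path}: {detail} at row {row!r}, column {col!r}")
    return numeric.astype(float)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with its index as the first column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")


def read_annotations_tsv(path: str | Path) -> pd.Series:
    """Read a two-column probe-id -> gene-symbol TSV (with header)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly two columns, got {frame.shape[1] + 1}")
    if frame.index.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    return frame.iloc[:, 0].rename("symbol")


def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a GMT file into (set name, members) pairs.

    Each line is tab-separated: name, description, members...  Members are
    deduplicated preserving order; lines with fewer than three fields,
    duplicate set names and member-less sets are rejected.  The description
    field is read and discarded.
    """
    path = Path(path)
    sets: list[tuple[str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            members = list(dict.fromkeys(m for m in fields[2:] if m.strip()))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append((name, members))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(
    sets: list[tuple[str, list[str]]] | GeneSetCollection,
    path: str | Path,
    description: str = "na",
) -> None:
    """Write gene sets in GMT format."""
    if isinstance(sets, GeneSetCollection):
        sets = [(name, list(members)) for name, members in sets.sets.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for name, members in sets:
            handle.write("\t".join([name, description, *members]) + "\n")


def write_dataset(dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a RawDataset's intensities, detection p-values, annotations and
    (if present) truth table as TSV files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    dataset.intensities.to_csv(paths["intensities"], sep="\t")
    dataset.detection_p.to_csv(paths["detection_p"], sep="\t")
    dataset.annotations.to_frame().to_csv(paths["annotations"], sep="\t")
    if dataset.truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        dataset.truth.to_csv(paths["truth"], sep="\t")
    return paths


def read_dataset(
    intensities: str | Path, detection_p: str | Path, annotations: str | Path
):
    """Load a raw dataset from its three TSV files."""
    from .synthetic import RawDataset  # deferred to avoid an import cycle

    intens = read_expression_tsv(intensities)
    detect = read_expression_tsv(detection_p)
    if intens.shape != detect.shape:
        raise ValueError(
            f"intensities {intens.shape} and detection p-values {detect.shape} disagree"
        )
    if np.any(detect.to_numpy() < 0) or np.any(detect.to_numpy() > 1):
        raise ValueError("detection p-values must lie in [0, 1]")
    annot = read_annotations_tsv(annotations)
    return RawDataset(
        intensities=intens, detection_p=detect, annotations=annot, truth=None
    )
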