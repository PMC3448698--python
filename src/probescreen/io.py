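"""Readers and writers for the pipeline's tab-separated file formats.

Formats
-------
probe matrix TSV   header ``probe_id<TAB>sample1...sampleN``, one probe/row
probe map TSV      ``probe_id<TAB>probeset_id``
sample sheet TSV   ``sample_id<TAB>group``
truth TSV          per-probe-set ground-truth labels from the simulator
annotation TSV     ``probeset_id<TAB>term`` pairs, '#' comments allowed

Floats are written with 12 significant digits so that a write/read
round-trip reproduces values to 12 significant digits.
"""

from __future__ import annotations

import os

import pandas as pd

from .containers import ProbeLevelMatrix

FLOAT_FMT = "%.12g"

__all__ = [
    "read_probe_matrix",
    "write_probe_matrix",
    "read_probe_map",
    "write_probe_map",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_level_matrix",
    "write_probe_level_matrix",
    "read_table",
    "write_table",
    "from_cel_files",
]


def read_probe_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    return df


def write_probe_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _read_two_column(path, col0: str, col1: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in (col0, col1):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.set_index(col0)[col1]


def read_probe_map(path) -> pd.Series:
    return _read_two_column(path, "probe_id", "probeset_id")


def write_probe_map(probe_map: pd.Series, path) -> None:
    df = probe_map.rename("probeset_id").rename_axis("probe_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.Series:
    return _read_two_column(path, "sample_id", "group")


def write_sample_sheet(sample_groups: pd.Series, path) -> None:
    df = sample_groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_probe_level_matrix(matrix_path, probe_map_path, sample_sheet_path) -> ProbeLevelMatrix:
    """Load and cross-validate the three probe-level input files."""
    return ProbeLevelMatrix(
        intensities=read_probe_matrix(matrix_path),
        probe_map=read_probe_map(probe_map_path),
        sample_groups=read_sample_sheet(sample_sheet_path),
    )


def write_probe_level_matrix(data: ProbeLevelMatrix, out_dir, prefix: str = "") -> dict:
    paths = {
        "matrix": os.path.join(out_dir, f"{prefix}probe_matrix.tsv"),
        "probe_map": os.path.join(out_dir, f"{prefix}probe_map.tsv"),
        "samples": os.path.join(out_dir, f"{prefix}samples.tsv"),
    }
    write_probe_matrix(data.intensities, paths["matrix"])
    write_probe_map(data.probe_map, paths["probe_map"])
    write_sample_sheet(data.sample_groups, paths["samples"])
    return paths


def read_table(path, index_col=0) -> pd.DataFrame:
    """Generic indexed TSV reader (expression/result tables)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index_name=None) -> None:
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def from_cel_files(*paths):
    """Converter stub for vendor binary array files.

    Probe-level input is expected as the TSV formats of this module; binary
    CEL/CDF parsing is delegated to upstream tooling (e.g. ``apt-cel-extract``
    or Bioconductor's *affy* ``exprs(ReadAffy(...))`` exports) whose output is
    then saved as the probe matrix / probe map TSVs.
    """
    raise NotImplementedError(
        "binary CEL parsing is out of scope; export probe-level TSVs with "
        "upstream tooling and use read_probe_level_matrix()"
    )
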