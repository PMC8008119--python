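"""TSV / Newick / JSON readers and writers.

All tables are tab-delimited UTF-8 with "." decimal; trees are Newick; run
summaries are JSON. Readers and writers are exact inverses on valid data and
writers are deterministic (stable column order, fixed float formatting) so a
re-run with the same seed produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .core import OtuTable, Phylogeny, SampleMetadata
from .errors import RaggedTableError

FLOAT_FMT = "%.10g"


def read_otu_table(path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a sample x OTU count TSV.

    ``orientation`` declares whether samples are rows or columns in the file;
    the in-memory convention is always samples-as-rows.
    """
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_as_columns":
        df = df.T
    return OtuTable(df)


def write_otu_table(table: OtuTable, path, orientation: str = "samples_as_rows") -> None:
    df = table.to_dataframe()
    if orientation == "samples_as_columns":
        df = df.T
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def _check_rectangular(path) -> None:
    widths = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                widths.add(line.rstrip("\n").count("\t"))
    if len(widths) > 1:
        raise RaggedTableError(f"{path}: rows have unequal numbers of fields")


def read_newick(path, require_lengths: bool = True) -> Phylogeny:
    text = Path(path).read_text(encoding="utf-8")
    return Phylogeny.from_newick(text, require_lengths=require_lengths)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index.astype(str)))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_report_tables(objects: dict, out_dir, summary: dict | None = None) -> list[str]:
    """Write one TSV per result table plus a JSON run summary.

    ``objects`` maps name -> DataFrame (or Series); ``summary`` collects
    inputs, seeds, parameters and versions. Returns the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(objects):
        obj = objects[name]
        if isinstance(obj, pd.Series):
            obj = obj.to_frame(name)
        path = out / f"{name}.tsv"
        obj.to_csv(path, sep="\t", float_format=FLOAT_FMT)
        written.append(str(path))
    from . import __version__

    payload = {"package_version": __version__, **(summary or {})}
    spath = out / "run_summary.json"
    spath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(str(spath))
    return written
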