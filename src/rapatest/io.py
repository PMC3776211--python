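"""Plain-text columnar I/O for every pipeline format.

All artefacts are diffable CSV/TSV/JSON with explicit headers: cohort
tables, LDH plate and standards CSVs, DNA-content histogram CSVs,
expression TSVs with a sample-group CSV, one-symbol-per-line gene lists and
result JSONs.  Readers validate headers and ids and raise errors naming the
file and the offending column/row; both LF and CRLF line endings are
accepted (pandas' readers are dialect-tolerant).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcycle import DNAHistogram
from .cohort import Cohort, Subject
from .ldh import Condition

__all__ = [
    "read_cohort", "write_cohort", "read_plate", "write_plate",
    "read_standards", "write_standards", "read_histogram", "write_histogram",
    "read_expression", "write_expression", "read_groups", "write_groups",
    "read_gene_list", "write_gene_list", "write_json", "read_json",
    "write_cohort_bundle", "file_checksum",
]


class FormatError(ValueError):
    """Malformed input file; message names the file and location."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} "
                          f"(found {list(df.columns)})")


# ---- cohort table --------------------------------------------------------

def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "age", "diagnosis", "apoe4"], path)
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path}: duplicate subject ids {dupes}")
    df["apoe4"] = df["apoe4"].astype(bool)
    for _, row in df.iterrows():  # validates ranges via the domain type
        Subject(id=str(row["id"]), age=int(row["age"]),
                diagnosis=str(row["diagnosis"]), apoe4=bool(row["apoe4"]))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---- LDH plates ----------------------------------------------------------

def read_plate(path) -> dict:
    """Plate CSV (condition, replicate, absorbance) -> {Condition: [abs...]}."""
    df = pd.read_csv(path)
    _require_columns(df, ["condition", "replicate", "absorbance"], path)
    out: dict = {}
    for cond, grp in df.groupby("condition"):
        try:
            c = Condition(cond)
        except ValueError as e:
            raise FormatError(f"{path}: unknown condition {cond!r}") from e
        vals = grp.sort_values("replicate")["absorbance"].astype(float).tolist()
        out[c] = vals
    return out


def write_plate(plate: dict, path) -> None:
    rows = [{"condition": cond.value, "replicate": i + 1, "absorbance": a}
            for cond, reps in plate.items() for i, a in enumerate(reps)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_standards(path) -> list:
    df = pd.read_csv(path)
    _require_columns(df, ["cells", "absorbance"], path)
    return list(zip(df["cells"].astype(float), df["absorbance"].astype(float)))


def write_standards(standards, path) -> None:
    pd.DataFrame(standards, columns=["cells", "absorbance"]).to_csv(path, index=False)


# ---- DNA histograms ------------------------------------------------------

def read_histogram(path) -> DNAHistogram:
    df = pd.read_csv(path)
    _require_columns(df, ["channel_midpoint", "count"], path)
    if not df["count"].map(lambda v: float(v) == int(v)).all():
        raise FormatError(f"{path}: non-integer event counts")
    return DNAHistogram(channel_midpoints=df["channel_midpoint"].to_numpy(float),
                        counts=df["count"].to_numpy(float))


def write_histogram(hist: DNAHistogram, path) -> None:
    pd.DataFrame({"channel_midpoint": hist.channel_midpoints,
                  "count": hist.counts.astype(int)}).to_csv(path, index=False)


# ---- expression ----------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene rows {dupes[:5]}")
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric cells in columns {non_numeric}")
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "group"], path)
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")["group"]


def write_groups(groups: pd.DataFrame, path) -> None:
    groups.to_csv(path, index=False)


# ---- gene lists / JSON ---------------------------------------------------

def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable,
                                     sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---- cohort bundle export ------------------------------------------------

def write_cohort_bundle(cohort: Cohort, outdir) -> dict:
    """Write a full synthetic cohort to disk; returns the path map.

    Layout: ``cohort.csv``, ``standards.csv``, ``truth.json`` plus one plate
    CSV and two histogram CSVs per subject under ``plates/`` and ``hists/``.
    """
    out = Path(outdir)
    (out / "plates").mkdir(parents=True, exist_ok=True)
    (out / "hists").mkdir(parents=True, exist_ok=True)
    write_cohort(cohort.table(), out / "cohort.csv")
    paths = {"cohort": out / "cohort.csv", "plates": {}, "hists": {}}
    first = next(iter(cohort.assays.values()))
    write_standards(first.standards, out / "standards.csv")
    paths["standards"] = out / "standards.csv"
    truth = {}
    for sid, assay in cohort.assays.items():
        ppath = out / "plates" / f"{sid}.csv"
        write_plate(assay.plate, ppath)
        hu = out / "hists" / f"{sid}_untreated.csv"
        ht = out / "hists" / f"{sid}_rapamycin.csv"
        write_histogram(assay.hist_untreated, hu)
        write_histogram(assay.hist_treated, ht)
        paths["plates"][sid] = ppath
        paths["hists"][sid] = (hu, ht)
        truth[sid] = {k: v for k, v in assay.truth.items()}
    write_json(truth, out / "truth.json")
    paths["truth"] = out / "truth.json"
    return paths


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
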