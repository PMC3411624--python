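"""Tab-delimited readers and writers for probe matrices, summaries and JED tables.

One fixed dialect everywhere, for reproducibility: tab-separated UTF-8 text,
'.' decimal point, no thousands separators, floats serialized at 10
significant digits, deterministic row order.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, JackknifeSet, ProbeLevelMatrix, reset_negative_summaries
from .jed import JED_COLUMNS

__all__ = [
    "read_probe_matrix",
    "write_probe_matrix",
    "read_summary_matrix",
    "write_summary_matrix",
    "read_jackknife_set",
    "write_jackknife_set",
    "read_jed_table",
    "write_jed_table",
]

FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_probe_matrix(path: str) -> ProbeLevelMatrix:
    """Read probe-level TSV: header ``probeset_id, probe_id, <array>...``.

    Rejects duplicate probe identifiers, ragged rows and non-numeric cells,
    naming the offending probe or (row, column) coordinate.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "probeset_id" or header[1] != "probe_id":
        raise ValueError(
            f"{path}: malformed header (expected 'probeset_id\\tprobe_id\\t<arrays...>')"
        )
    arrays = header[2:]
    probesets, probes, rows = [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        probesets.append(cells[0])
        probes.append(cells[1])
        row = []
        for k, cell in enumerate(cells[2:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, "
                    f"column {arrays[k]!r}"
                ) from None
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    idx = pd.Index(probes, name="probe_id")
    if idx.duplicated().any():
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")
    intensities = pd.DataFrame(rows, index=idx, columns=arrays)
    probeset_map = pd.Series(probesets, index=idx, name="probeset_id")
    return ProbeLevelMatrix(intensities=intensities, probeset_map=probeset_map)


def write_probe_matrix(data: ProbeLevelMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probeset_id\tprobe_id\t" + "\t".join(data.array_ids) + "\n")
        for probe, row in data.intensities.iterrows():
            fh.write(
                data.probeset_map[probe]
                + "\t"
                + str(probe)
                + "\t"
                + "\t".join(_fmt(v) for v in row)
                + "\n"
            )


def write_summary_matrix(em: ExpressionMatrix, path: str, raw: bool = False) -> None:
    """Write a gene x array summary matrix with a method-tag comment header.

    With ``raw`` set, the pre-reset values are written instead of the
    post-reset ones.
    """
    mat = em.raw_summaries if raw else em.summaries
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={em.method_tag}\n")
        fh.write("gene\t" + "\t".join(em.array_ids) + "\n")
        for gene, row in mat.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_summary_matrix(path: str) -> ExpressionMatrix:
    """Read a summary TSV (values are treated as raw; the reset rule is applied)."""
    method_tag = "external"
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and lines[0].startswith("#"):
        comment = lines.pop(0).lstrip("# ")
        if comment.startswith("method="):
            method_tag = comment[len("method=") :]
    if not lines:
        raise ValueError(f"{path}: empty summary file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "gene":
        raise ValueError(f"{path}: malformed header (expected 'gene\\t<arrays...>')")
    arrays = header[1:]
    genes, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        genes.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError:
            raise ValueError(f"{path}: non-numeric value at line {lineno}") from None
    raw = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=arrays)
    return reset_negative_summaries(raw, method_tag=method_tag)


def write_jackknife_set(jk: JackknifeSet, directory: str, prefix: str = "summaries") -> None:
    """Write a jackknife set as raw-summary TSVs: full plus one file per excluded array."""
    os.makedirs(directory, exist_ok=True)
    write_summary_matrix(jk.full, os.path.join(directory, f"{prefix}_full.tsv"), raw=True)
    for j, em in jk.loo.items():
        write_summary_matrix(em, os.path.join(directory, f"{prefix}_drop_{j}.tsv"), raw=True)


def read_jackknife_set(full_path: str, loo_paths: Mapping[str, str]) -> JackknifeSet:
    """Assemble a JackknifeSet from external summary TSVs.

    ``loo_paths`` maps each excluded array label to the file holding that
    leave-one-out run.  This is the entry point for computing JED on
    summaries produced by any outside preprocessing tool.
    """
    full = read_summary_matrix(full_path)
    loo = {j: read_summary_matrix(p) for j, p in loo_paths.items()}
    return JackknifeSet(full=full, loo=loo, method_tag=full.method_tag)


def write_jed_table(table: pd.DataFrame, path: str, suppress_diagonal: bool = False) -> None:
    """Write a long-format JED table; row order is (gene, array_i, array_j)."""
    if table.empty:
        raise ValueError("refusing to write an empty JED table")
    t = table
    if suppress_diagonal:
        t = t[t["array_i"] != t["array_j"]]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(JED_COLUMNS) + "\n")
        for _, row in t.iterrows():
            fh.write(
                f"{row['gene']}\t{row['array_i']}\t{row['array_j']}\t"
                f"{_fmt(row['jed'])}\t{int(row['sign_changes'])}\t{_fmt(row['distance'])}\n"
            )


def read_jed_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "array_i": str, "array_j": str})
    missing = [c for c in JED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing JED table columns {missing}")
    return table[JED_COLUMNS]
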