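"""Readers and writers for the pipeline's fixed file contracts.

Feature matrices are TSV (header row = sample IDs, first column =
feature ID, UTF-8, "." decimal); sample sheets and long tables are CSV.
Writers use repr-precision floats so a write/read round trip is
lossless and byte-deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SyntheticTruth

MATRIX_KW = dict(sep="\t", float_format="%.17g")


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, **MATRIX_KW)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    return pd.read_csv(path, sep=sep)


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def write_inputs(outdir, expr=None, samples=None, metabolites=None,
                 hormones=None, weights=None, viability=None,
                 survival=None, truth: SyntheticTruth | None = None) -> dict:
    """Write whichever inputs are given to their contract filenames.

    Returns ``{name: path}`` for everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if expr is not None:
        write_matrix(expr, outdir / "expression.tsv")
        written["expression"] = str(outdir / "expression.tsv")
    if samples is not None:
        write_table(samples, outdir / "samples.csv")
        written["samples"] = str(outdir / "samples.csv")
    if metabolites is not None:
        write_matrix(metabolites, outdir / "metabolites.tsv")
        written["metabolites"] = str(outdir / "metabolites.tsv")
    if hormones is not None:
        write_table(hormones, outdir / "hormones.csv")
        written["hormones"] = str(outdir / "hormones.csv")
    if weights is not None:
        write_table(weights, outdir / "weights.csv")
        written["weights"] = str(outdir / "weights.csv")
    if viability is not None:
        write_table(viability, outdir / "viability.csv")
        written["viability"] = str(outdir / "viability.csv")
    if survival is not None:
        write_table(survival, outdir / "survival.csv")
        written["survival"] = str(outdir / "survival.csv")
    if truth is not None:
        write_truth(truth, outdir / "truth.json")
        written["truth"] = str(outdir / "truth.json")
    return written


def read_inputs(indir) -> dict:
    """Read the pipeline inputs present in a directory."""
    indir = Path(indir)
    names = {
        "expression": ("expression.tsv", read_matrix),
        "samples": ("samples.csv", read_table),
        "metabolites": ("metabolites.tsv", read_matrix),
        "hormones": ("hormones.csv", read_table),
        "weights": ("weights.csv", read_table),
        "viability": ("viability.csv", read_table),
        "survival": ("survival.csv", read_table),
    }
    out = {}
    for key, (fname, reader) in names.items():
        p = indir / fname
        if p.exists():
            out[key] = reader(p)
    return out
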