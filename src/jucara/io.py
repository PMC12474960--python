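"""Readers and writers for the package's plain-text interchange formats.

* phenotypes — long CSV with header
  ``genotype,group,replicate,elevation,eval_time,trait,value``;
* SSR genotypes — CSV with a genotype column followed by two allele-size
  columns per locus (``<locus>.a,<locus>.b``), missing coded NA or 0;
* distance matrices — square labeled CSV and lower-triangle PHYLIP dist;
* dendrograms — newick with branch lengths from fusion heights;
* truth records — flat ``key = value`` text.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from jucara.divergence import DistanceMatrix
from jucara.simulate import PHENOTYPE_COLUMNS

_KEY_COLS = ["genotype", "replicate", "trait", "eval_time"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype table, validating keys and numerics."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns {missing}")
    dup = df.duplicated(subset=_KEY_COLS, keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"duplicate (genotype,replicate,trait,eval_time) rows at lines {lines}")
    raw = df["value"].replace({"": np.nan, "NA": np.nan, "nan": np.nan})
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"malformed numeric value {raw[bad].iloc[0]!r} at line {line}")
    out = df.copy()
    out["value"] = values
    out["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    out["eval_time"] = pd.to_numeric(df["eval_time"], errors="coerce").astype("Int64")
    return out


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ssr(path: str | Path) -> pd.DataFrame:
    """Read an SSR genotype table (two allele columns per locus).

    Allele calls are unordered; ``NA``, ``0`` and empty cells are missing.
    A genotype with all calls missing is retained with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "genotype":
        raise ValueError("first column of an SSR file must be 'genotype'")
    allele_cols = list(df.columns[1:])
    if len(allele_cols) % 2 != 0:
        raise ValueError(f"odd number of allele columns ({len(allele_cols)})")
    out = df.set_index("genotype")
    for col in allele_cols:
        vals = out[col].replace({"": np.nan, "NA": np.nan, "0": np.nan})
        out[col] = pd.to_numeric(vals, errors="raise").astype(float)
    # canonical order within each call: smaller allele first
    for k in range(0, len(allele_cols), 2):
        a, b = allele_cols[k], allele_cols[k + 1]
        locus = a.rsplit(".", 1)[0] if a.endswith(".a") else a
        lo = out[[a, b]].min(axis=1)
        hi = out[[a, b]].max(axis=1)
        out[a], out[b] = lo, hi
        if not (a.endswith(".a") and b.endswith(".b")):
            out = out.rename(columns={a: f"{locus}.a", b: f"{locus}.b"})
    empty = out.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"genotypes with no scored locus retained: {list(out.index[empty])}",
            stacklevel=2,
        )
    return out


def write_ssr(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.insert(0, "genotype", out.index)
    out.to_csv(path, index=False, na_rep="NA")


def read_distance_csv(path: str | Path, kind: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(float), kind=kind)


def write_distance_csv(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path)


def write_phylip_dist(D: DistanceMatrix, path: str | Path) -> None:
    """Lower-triangle PHYLIP distance format."""
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, lbl in enumerate(D.labels):
            row = " ".join(f"{D.values[i, j]:.6f}" for j in range(i))
            fh.write(f"{lbl:<10s} {row}".rstrip() + "\n")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_truth(flat: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in flat.items():
            fh.write(f"{key} = {val:.12g}\n")


def read_truth(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = float(val)
    return out
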