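"""Readers and writers for the pipeline's plain-text formats.

All interchange formats are tab-separated text or JSON:

* growth TSV        -- strain, condition, replicate, time_h, od600
* edge TSV          -- protein1, protein2, experimental, combined_score
* per-cell TSV      -- strain, condition, cell_id, gfp, rfp, compartment
* GMT               -- set name, description, tab-separated members
* gene lists        -- one identifier per line
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GROWTH_COLUMNS = ["strain", "condition", "replicate", "time_h", "od600"]
EDGE_COLUMNS = ["protein1", "protein2", "experimental", "combined_score"]
CELL_COLUMNS = ["strain", "condition", "cell_id", "gfp", "rfp", "compartment"]


def read_growth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table {path} lacks columns: {sorted(missing)}")
    return df


def write_growth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GROWTH_COLUMNS)


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge table {path} lacks columns: {sorted(missing)}")
    return df


def write_edge_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EDGE_COLUMNS)


def read_cell_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"per-cell table {path} lacks columns: {sorted(missing)}")
    return df


def write_cell_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CELL_COLUMNS)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection into ``{set_name: members}``.

    The description column (second field) is ignored on read.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, >=1 member")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = sorted(sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj: object, path: str | Path) -> None:
    """JSON writer with stable key order (reproducible bytes)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj: object) -> object:
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
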