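"""Readers and writers for the plain-text interchange formats.

Tables travel as tab-separated files with a header row; gene sets as
GMT (name, description, then one gene per field); term lists as
newline-delimited files. Schemas are documented in docs/formats.md.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import DataError


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "", *genes]) + "\n")


def read_term_list(path) -> list[str]:
    return [t.strip() for t in Path(path).read_text().splitlines() if t.strip()]
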