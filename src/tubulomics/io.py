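"""Tab-separated and FASTA input/output.

All tables are UTF-8 TSV with a single header row; missing values are empty
fields. Matrices carry their row-label column first (``protein_id`` for
intensity matrices).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a flat TSV table (one row per record)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_matrix(path: str | Path, index_col: str = "protein_id") -> pd.DataFrame:
    """Read a labelled matrix TSV (first column is the row index)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.index.name = out.index.name or "id"
    out.to_csv(path, sep="\t", na_rep="")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {record id: sequence}.

    The record id is the first whitespace-separated token of the header.
    """
    sequences: dict[str, str] = {}
    name, chunks = None, []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def read_marker_map(path: str | Path) -> pd.Series:
    """Read a protein -> cell class TSV (columns protein_id, cell_class)."""
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "cell_class"} <= set(df.columns):
        raise ValueError("marker map needs columns protein_id and cell_class")
    if df["protein_id"].duplicated().any():
        raise ValueError("marker map assigns some protein to more than one class")
    return df.set_index("protein_id")["cell_class"]


def read_groups(path: str | Path) -> pd.Series:
    """Read a sample -> group (WT/KO) TSV (columns sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("group table needs columns sample_id and group")
    return df.set_index("sample_id")["group"]
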