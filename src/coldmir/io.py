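"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with a mandatory header row; written files start with
``#``-prefixed provenance comments (tool version, seed, parameters) that
readers skip. UTRs travel as FASTA. Malformed rows are reported with their
line position in the file.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .response import TargetMap

__all__ = [
    "read_counts",
    "write_counts",
    "read_expression",
    "write_expression",
    "read_targets",
    "write_targets",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_gene_status",
    "provenance_header",
]


def provenance_header(seed: int | None = None, **params) -> str:
    from . import __version__

    parts = [f"# coldmir {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    for k, v in params.items():
        parts.append(f"# {k}: {v}")
    return "\n".join(parts) + "\n"


def _read_tsv(path: str | os.PathLike, required: Iterable[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | os.PathLike, header: str = "", index: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """miRNA count table: mirna_id, count_nc, count_wc (+ optional columns)."""
    df = _read_tsv(path, ["mirna_id", "count_nc", "count_wc"])
    for col in ("count_nc", "count_wc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0)]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} has invalid (non-numeric or negative) "
                f"values at data row(s) {[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = vals.astype(int)
    if df["mirna_id"].duplicated().any():
        dup = df.loc[df["mirna_id"].duplicated(), "mirna_id"].iloc[0]
        raise ValueError(f"{path}: duplicate mirna_id {dup!r}")
    return df


def write_counts(df: pd.DataFrame, path: str | os.PathLike, header: str = "") -> None:
    _write_tsv(df, path, header)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Expression matrix: gene_id index, NC*/WC* sample columns."""
    df = _read_tsv(path, ["gene_id"])
    df = df.set_index("gene_id")
    samples = [c for c in df.columns if c.startswith(("NC", "WC"))]
    if not samples:
        raise ValueError(f"{path}: no NC*/WC* sample columns found")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df[samples].astype(float)


def write_expression(df: pd.DataFrame, path: str | os.PathLike, header: str = "") -> None:
    _write_tsv(df.rename_axis("gene_id"), path, header, index=True)


def read_targets(path: str | os.PathLike) -> TargetMap:
    """Two-column target map: mirna_id, gene_id."""
    df = _read_tsv(path, ["mirna_id", "gene_id"])
    return TargetMap.from_pairs(zip(df["mirna_id"], df["gene_id"]))


def write_targets(tm: TargetMap, path: str | os.PathLike, header: str = "") -> None:
    _write_tsv(tm.to_frame(), path, header)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        str(path),
        "fasta",
    )


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """GAF-like TSV (gene_id, term) → gene → set of term labels."""
    df = _read_tsv(path, ["gene_id", "term"])
    if len(df) == 0:
        raise ValueError(f"{path}: empty annotation file")
    ann: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term"]):
        ann.setdefault(str(g), set()).add(str(t))
    return ann


def write_annotations(ann: Mapping[str, Iterable[str]], path: str | os.PathLike, header: str = "") -> None:
    rows = [(g, t) for g in sorted(ann) for t in sorted(ann[g])]
    _write_tsv(pd.DataFrame(rows, columns=["gene_id", "term"]), path, header)


def read_gene_status(path: str | os.PathLike) -> pd.DataFrame:
    """Per-gene differential status: gene_id, direction ∈ {up, down, none}."""
    df = _read_tsv(path, ["gene_id", "direction"])
    bad = df.index[~df["direction"].isin(["up", "down", "none"])]
    if len(bad):
        raise ValueError(
            f"{path}: invalid direction at data row(s) {[int(i) + 2 for i in bad[:5]]} "
            "(expected up/down/none)"
        )
    return df
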