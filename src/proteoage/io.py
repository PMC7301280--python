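"""Readers and writers for the pipeline's on-disk formats.

Canonical tabular dialect is TSV (UTF-8, "." decimal): matrices are written
features x samples with the feature id in the first column. Gene-set
catalogs use the standard GMT format, sequences FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ComplexCatalog, FishSurvival, OmicsMatrix, SECMatrix

log = logging.getLogger(__name__)

#: column order for PSM tables on disk
PSM_COLUMNS = [
    "psm_id",
    "peptide_sequence",
    "protein_group_id",
    "is_unique_peptide",
    "search_score",
    "precursor_intensity",
    "is_reverse",
    "is_contaminant",
    "run_id",
]


def read_matrix(path, kind: str = "intensity", meta_path=None) -> OmicsMatrix:
    """Read a features x samples TSV; header row holds sample ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty matrix file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
                raise ValueError(f"{path}: non-numeric cell in column {col!r}, line {line}")
        df = df.apply(pd.to_numeric)
    meta = None
    if meta_path is not None:
        meta = read_sample_metadata(meta_path)
    return OmicsMatrix(df, kind=kind, meta=meta)


def write_matrix(matrix: OmicsMatrix, path, stage: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage:
            fh.write(f"# stage={stage} kind={matrix.kind}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id")


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if meta.index.has_duplicates:
        raise ValueError(f"{path}: duplicated sample id")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> ComplexCatalog:
    """Read a GMT file: per line name, description, then member ids."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = parts
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return ComplexCatalog(sets, descriptions)


def write_gmt(catalog: ComplexCatalog, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in catalog.items():
            desc = catalog.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; id is the header up to whitespace."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM TSV; reporter channels are columns reporter_1..reporter_K."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: PSM table missing columns {missing}")
    if not reporter_columns(df):
        raise ValueError(f"{path}: no reporter_<i> columns found")
    return df


def write_psm_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def reporter_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("reporter_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def read_survival(path) -> FishSurvival:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return FishSurvival(df)


def write_survival(surv: FishSurvival, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    surv.table.to_csv(path, sep="\t", index_label="fish_id")


def read_sec_matrix(path, condition: str = "", replicate: str = "") -> SECMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.columns = [int(str(c).removeprefix("fraction_")) for c in df.columns]
    return SECMatrix(df, condition=condition, replicate=replicate)


def write_sec_matrix(sec: SECMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = sec.data.copy()
    out.columns = [f"fraction_{c}" for c in out.columns]
    out.to_csv(path, sep="\t", index_label="protein_id")
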