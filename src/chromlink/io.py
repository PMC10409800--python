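"""Readers and writers for the pipeline's text formats.

Coordinates are 0-based half-open throughout. Supported dialects: BED3, BED6,
narrowPeak (10 columns; the qValue column is -log10 FDR and is converted back
as fdr = 10**(-qValue)) and the 7-column caller-call TSV (chrom, start, end,
name, score, caller, fdr).
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import GeneModel

_DIALECT_FIELDS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "calls7": 7}


class ParseError(ValueError):
    pass


def parse_bed_record(line: str, dialect: str = "bed6", line_number: int | None = None) -> dict:
    """Parse one tab-separated interval record into a dict.

    Raises ``ParseError`` (with the line number when given) on a wrong field
    count, non-integer coordinates or start >= end.
    """
    if dialect not in _DIALECT_FIELDS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    want = _DIALECT_FIELDS[dialect]
    if len(fields) != want:
        raise ParseError(f"expected {want} fields for {dialect}, got {len(fields)}{where}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"non-integer coordinates{where}: {fields[1]!r}, {fields[2]!r}") from exc
    if start >= end:
        raise ParseError(f"invalid interval start >= end ({start} >= {end}){where}")
    rec = {"chrom": fields[0], "start": start, "end": end}
    if dialect == "bed6":
        rec.update(name=fields[3], score=_score(fields[4], where), strand=fields[5] or ".")
    elif dialect == "narrowPeak":
        rec.update(name=fields[3], score=_score(fields[4], where), strand=fields[5] or ".")
        rec["fdr"] = 10.0 ** (-float(fields[8]))
    elif dialect == "calls7":
        rec.update(name=fields[3], score=_score(fields[4], where),
                   caller=fields[5], fdr=float(fields[6]))
    return rec


def _score(field: str, where: str) -> float:
    try:
        return float(field) if field not in (".", "") else 0.0
    except ValueError as exc:
        raise ParseError(f"bad score field {field!r}{where}") from exc


def read_bed(path: str | Path, dialect: str = "bed3") -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            records.append(parse_bed_record(line, dialect, line_number=i))
    return pd.DataFrame(records)


def read_peak_calls(path: str | Path, dialect: str = "calls7", replicate: int = 1) -> pd.DataFrame:
    """Peak calls for one replicate; narrowPeak callers default to the name prefix."""
    df = read_bed(path, dialect)
    df["replicate"] = replicate
    if "caller" not in df.columns:
        df["caller"] = "caller_A"
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError("duplicate gene ids in count matrix")
    if (df.to_numpy() < 0).any():
        raise ParseError("negative counts")
    return df


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def read_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"exons": str})
    genes = []
    for r in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in (r.exons.split(",") if isinstance(r.exons, str) and r.exons else [])
        )
        genes.append(GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand, exons))
    return genes


def write_reproducible_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Reproducible peaks as BED6; score column carries the minimum FDR."""
    rep = peaks[peaks["reproducible"]]
    out = pd.DataFrame({
        "chrom": rep["chrom"], "start": rep["start"], "end": rep["end"],
        "name": [f"peak_{i}" for i in range(len(rep))],
        "score": rep["min_fdr"], "strand": ".",
    })
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def write_manifest(path: str | Path, **payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
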