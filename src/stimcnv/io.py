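"""Format parsers and writers: BED peaks, GFF3 genes, TSV/CSV tables.

Coordinate conventions: BED is 0-based half-open and used natively; GFF3 is
1-based closed and converted on read (start−1, end) / on write (start+1).
The BED dialect used for peaks carries the fold enrichment in column 5
(the score column); a 2-column extension (chrom, start, end, name, fold)
written by MACS-style pipelines parses identically.

Parsers raise :class:`~stimcnv.errors.InputError` naming the first malformed
line; nothing is silently coerced.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import InputError
from .genomics import GeneModel, GenomicInterval, PeakCall

__all__ = [
    "read_peaks",
    "write_peaks_bed",
    "read_genes",
    "write_genes_gff3",
    "read_table",
    "write_table",
    "read_growth_curve",
    "write_growth_curve",
]

PathLike = Union[str, Path]


def read_peaks(path: PathLike, dialect: str = "bed5") -> list[PeakCall]:
    """Read peak calls from a BED-like file (fold enrichment in column 5)."""
    if dialect != "bed5":
        raise InputError(f"unknown peak dialect {dialect!r}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise InputError(
                    f"{path}:{lineno}: expected >= 5 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, fold_s = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
                fold = float(fold_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            try:
                peaks.append(PeakCall(GenomicInterval(chrom, start, end), fold))
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: Sequence[PeakCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i + 1}\t{p.fold_enrichment:g}\n"
            )


def read_genes(path: PathLike, feature_type: str = "CDS") -> list[GeneModel]:
    """Read gene models (CDS features) from a GFF3 file.

    Gene identifiers come from the ``gene_id`` or ``ID`` attribute.
    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                )
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            if start1 < 1 or end1 < start1:
                raise InputError(
                    f"{path}:{lineno}: bad 1-based coordinates {start1}..{end1}"
                )
            attr_map = {}
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk and "=" in chunk:
                    k, v = chunk.split("=", 1)
                    attr_map[k] = v
            gene_id = attr_map.get("gene_id") or attr_map.get("ID")
            if not gene_id:
                raise InputError(f"{path}:{lineno}: no gene_id/ID attribute")
            try:
                genes.append(
                    GeneModel(gene_id, GenomicInterval(seqid, start1 - 1, end1, strand))
                )
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            cds = g.cds
            fh.write(
                f"{cds.chrom}\tstimcnv\tCDS\t{cds.start + 1}\t{cds.end}\t.\t"
                f"{cds.strand}\t0\tID={g.gene_id};gene_id={g.gene_id}\n"
            )


def read_table(path: PathLike, sep: str = "\t") -> pd.DataFrame:
    """Read a TSV/CSV table with a header row."""
    try:
        return pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: PathLike, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_growth_curve(path: PathLike):
    """Read a growth curve CSV with columns time_h, od660."""
    from .population import GrowthCurve

    df = read_table(path, sep=",")
    for col in ("time_h", "od660"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return GrowthCurve(times=df["time_h"].to_numpy(), od=df["od660"].to_numpy())


def write_growth_curve(curve, path: PathLike, well_id: str = "A1") -> None:
    df = pd.DataFrame(
        {"time_h": curve.times, "od660": curve.od, "well_id": well_id}
    )
    df.to_csv(path, index=False)
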