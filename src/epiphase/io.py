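"""Readers and writers for the on-disk formats.

GFF3 is 1-based inclusive and CX reports are 1-based; both are converted
to the package's 0-based half-open convention here, at the boundary, and
converted back on write. BED is already 0-based half-open. Output tables
are written with a deterministic column and row order so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    VALID_CONTEXTS,
    FeatureRecord,
    FeatureTable,
    GenomicInterval,
    MethylomeCounts,
    NucleosomeTrack,
)

logger = logging.getLogger("epiphase.io")

CX_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "tricontext"]


def _assign_compartment(interval: GenomicInterval, pericentromeres: dict | None) -> str:
    """Compartment from a config-declared pericentromere span per chromosome."""
    if not pericentromeres:
        return "arm"
    span = pericentromeres.get(interval.chrom)
    if span is None:
        return "arm"
    lo, hi = span
    mid = interval.center
    return "pericentromeric" if lo <= mid < hi else "arm"


def read_feature_annotation(
    path: str | Path,
    fmt: str,
    pericentromeres: dict | None = None,
    chromosome_lengths: dict | None = None,
) -> FeatureTable:
    """Read a TE/gene annotation from GFF3 or BED.

    GFF3 ``start`` is 1-based inclusive and converted to 0-based half-open;
    BED intervals are taken as-is. Features are labelled pericentromeric if
    their midpoint falls in the declared span for their chromosome.

    Raises
    ------
    ValueError
        On a malformed line (with its line number) or, when
        ``chromosome_lengths`` is given, on an unknown chromosome.
    """
    fmt = fmt.upper()
    if fmt not in ("GFF3", "BED"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
                    iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                    attr = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    fid = attr.get("ID", f"feature_{lineno}")
                    kind = "TE" if ftype in ("transposable_element", "TE") else "gene"
                    superfamily = attr.get("superfamily", "")
                else:
                    if len(fields) < 3:
                        raise ValueError("expected >=3 BED columns")
                    chrom = fields[0]
                    iv = GenomicInterval(
                        chrom,
                        int(fields[1]),
                        int(fields[2]),
                        fields[5] if len(fields) > 5 else ".",
                    )
                    fid = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                    kind, superfamily = "TE", "unknown"
                    if len(fields) > 6:
                        kind = fields[6]
                    if len(fields) > 7:
                        superfamily = fields[7]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if chromosome_lengths is not None and chrom not in chromosome_lengths:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            features.append(
                FeatureRecord(
                    interval=iv,
                    id=fid,
                    kind=kind,
                    superfamily=superfamily if kind == "TE" else superfamily,
                    compartment=_assign_compartment(iv, pericentromeres),
                )
            )
    return FeatureTable(features)


def write_feature_annotation(table: FeatureTable, path: str | Path, fmt: str = "GFF3") -> None:
    fmt = fmt.upper()
    rows = []
    for f in table.sorted():
        iv = f.interval
        if fmt == "GFF3":
            ftype = "transposable_element" if f.kind == "TE" else "gene"
            attrs = f"ID={f.id}"
            if f.superfamily:
                attrs += f";superfamily={f.superfamily}"
            rows.append(
                f"{iv.chrom}\tepiphase\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
            )
        elif fmt == "BED":
            rows.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.id}\t0\t{iv.strand}\t{f.kind}\t{f.superfamily}"
            )
        else:
            raise ValueError(f"unsupported annotation format {fmt!r}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_cx_report(path: str | Path) -> MethylomeCounts:
    """Read a Bismark-style CX report (TSV, 1-based positions).

    Columns: chrom, pos, strand, count_meth, count_unmeth, context,
    tricontext. Positions are converted to 0-based and
    ``n_total = count_meth + count_unmeth``.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tricontext": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty CX report %s", path)
        return MethylomeCounts(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "pos": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=str),
                    "context": pd.Series(dtype=str),
                    "n_meth": pd.Series(dtype=np.int64),
                    "n_total": pd.Series(dtype=np.int64),
                }
            )
        )
    if bool((df["count_meth"] < 0).any()) or bool((df["count_unmeth"] < 0).any()):
        raise ValueError(f"{path}: negative counts")
    unknown = set(df["context"].unique()) - set(VALID_CONTEXTS)
    if unknown:
        raise ValueError(f"{path}: unknown context tokens {sorted(unknown)}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64) - 1,
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": df["count_meth"].astype(np.int64),
            "n_total": (df["count_meth"] + df["count_unmeth"]).astype(np.int64),
        }
    )
    return MethylomeCounts(out)


def write_cx_report(methylome: MethylomeCounts, path: str | Path) -> None:
    """Write counts back out in the 1-based CX dialect, sorted by position."""
    df = methylome.frame.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": df["strand"],
            "count_meth": df["n_meth"],
            "count_unmeth": df["n_total"] - df["n_meth"],
            "context": df["context"],
            "tricontext": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_nucleosome_centers(path: str | Path) -> NucleosomeTrack:
    """Read well-positioned nucleosome centers from BED.

    Interval records are reduced to their midpoint ``(start + end) // 2``;
    positions are sorted per chromosome and exact duplicates dropped.
    """
    track = NucleosomeTrack()
    per_chrom: dict[str, list[int]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            per_chrom.setdefault(chrom, []).append((start + end) // 2)
    for chrom, centers in per_chrom.items():
        unique = sorted(set(centers))
        n_dup += len(centers) - len(unique)
        track.add(chrom, unique)
    if n_dup:
        logger.warning("%s: deduplicated %d duplicate nucleosome centers", path, n_dup)
    return track


def write_nucleosome_centers(track: NucleosomeTrack, path: str | Path) -> None:
    lines = []
    for chrom in track.chromosomes():
        for c in track.centers[chrom]:
            lines.append(f"{chrom}\t{c}\t{c + 1}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(frame: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with header, deterministic order.

    Rows are sorted by ``sort_by`` (default: any of chrom/start/end/id
    present, in that order) with a stable sort so repeated calls are
    byte-identical.
    """
    df = frame.copy()
    if sort_by is None:
        sort_by = [c for c in ("chrom", "start", "end", "id") if c in df.columns]
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(path: str | Path, frame: pd.DataFrame, value_col: str) -> None:
    """Write chrom/start/end/value rows as bedGraph (no track line)."""
    df = frame.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{getattr(row, value_col)}\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(read_id, sequence)`` pairs with uniform maximal quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
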