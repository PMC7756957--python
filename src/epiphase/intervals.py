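"""Core genomic domain types.

All coordinates inside the package are 0-based half-open ``[start, end)``.
Conversion from 1-based formats (GFF3, CX reports) happens only at I/O
boundaries (:mod:`epiphase.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}
VALID_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must satisfy ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated feature (TE or gene) with its chromosomal compartment."""

    interval: GenomicInterval
    id: str
    kind: str  # "TE" or "gene"
    superfamily: str = ""
    compartment: str = "arm"  # "pericentromeric" or "arm"

    def __post_init__(self) -> None:
        if self.kind not in ("TE", "gene"):
            raise ValueError(f"feature kind must be TE or gene, got {self.kind!r}")
        if self.kind == "TE" and not self.superfamily:
            raise ValueError(f"TE feature {self.id!r} requires a superfamily")
        if self.compartment not in ("pericentromeric", "arm"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


class FeatureTable:
    """Ordered collection of :class:`FeatureRecord` with unique ids."""

    def __init__(self, features: Iterable[FeatureRecord] = ()) -> None:
        self._features: list[FeatureRecord] = []
        self._by_id: dict[str, FeatureRecord] = {}
        for f in features:
            self.add(f)

    def add(self, feature: FeatureRecord) -> None:
        if feature.id in self._by_id:
            raise ValueError(f"duplicate feature id {feature.id!r}")
        self._features.append(feature)
        self._by_id[feature.id] = feature

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[FeatureRecord]:
        return iter(self._features)

    def __getitem__(self, feature_id: str) -> FeatureRecord:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def ids(self) -> list[str]:
        return [f.id for f in self._features]

    def subset(self, ids: Iterable[str]) -> "FeatureTable":
        wanted = set(ids)
        return FeatureTable(f for f in self._features if f.id in wanted)

    def tes(self) -> "FeatureTable":
        return FeatureTable(f for f in self._features if f.kind == "TE")

    def genes(self) -> "FeatureTable":
        return FeatureTable(f for f in self._features if f.kind == "gene")

    def sorted(self) -> "FeatureTable":
        return FeatureTable(
            sorted(
                self._features,
                key=lambda f: (f.interval.chrom, f.interval.start, f.id),
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f.interval.chrom for f in self._features],
                "start": [f.interval.start for f in self._features],
                "end": [f.interval.end for f in self._features],
                "strand": [f.interval.strand for f in self._features],
                "id": [f.id for f in self._features],
                "kind": [f.kind for f in self._features],
                "superfamily": [f.superfamily for f in self._features],
                "compartment": [f.compartment for f in self._features],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self._features == other._features


class MethylomeCounts:
    """Per-cytosine methylation counts for one library.

    Stored as a DataFrame with columns ``chrom, pos, strand, context,
    n_meth, n_total`` (``pos`` 0-based). The column-of-arrays layout keeps
    whole-methylome operations vectorised.
    """

    COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"methylome frame missing columns {missing}")
        bad = frame["n_meth"] > frame["n_total"]
        if bool(bad.any()):
            raise ValueError("n_meth exceeds n_total for some cytosines")
        if bool((frame["n_meth"] < 0).any()):
            raise ValueError("negative methylated counts")
        unknown = set(frame["context"].unique()) - set(VALID_CONTEXTS)
        if unknown:
            raise ValueError(f"unknown methylation contexts {sorted(unknown)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def subset_context(self, context: str) -> "MethylomeCounts":
        if context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return MethylomeCounts(self.frame[self.frame["context"] == context])

    def chromosomes(self) -> list[str]:
        return sorted(self.frame["chrom"].unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeCounts):
            return NotImplemented
        a = self.frame.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
        b = other.frame.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
        return a[self.COLUMNS].equals(b[self.COLUMNS])


@dataclass
class NucleosomeTrack:
    """Per-chromosome sorted arrays of well-positioned nucleosome center positions."""

    centers: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, chrom: str, positions: Iterable[int]) -> None:
        pos = np.asarray(sorted(set(int(p) for p in positions)), dtype=np.int64)
        self.centers[chrom] = pos

    def __len__(self) -> int:
        return sum(len(v) for v in self.centers.values())

    def chromosomes(self) -> list[str]:
        return sorted(self.centers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucleosomeTrack):
            return NotImplemented
        if set(self.centers) != set(other.centers):
            return False
        return all(
            np.array_equal(self.centers[c], other.centers[c]) for c in self.centers
        )
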