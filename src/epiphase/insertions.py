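"""Split-read / discordant-read TE insertion detection.

Non-reference transposable-element insertions leave two signatures in
paired-end data: *split reads* that span the insertion junction (one part
maps to the flanking genome, the soft-clipped part to the TE) and
*discordant pairs* with one mate in a TE and its mate anchored at a
distal genomic locus. Candidate insertions must be supported by at least
one split and/or discordant read on EACH side of the junction; calls
spanning the donor TE's own coordinates or centromeric repeats are
excluded, and calls detected in more than one library are dropped so
that only sample-specific insertions remain.

Alignment here is by exact k-mer seeding and maximal exact extension — an
adequate substitute for a short-read aligner on error-free synthetic
reads — and the module boundary accepts externally produced alignments as
a DataFrame so a real aligner can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InsertionParams
from .intervals import FeatureTable, GenomicInterval
from .simulate import revcomp

logger = logging.getLogger("epiphase.insertions")

CALL_COLUMNS = [
    "library",
    "chrom",
    "start",
    "end",
    "family",
    "left_split",
    "right_split",
    "left_discordant",
    "right_discordant",
    "excluded_reason",
]


@dataclass
class Alignment:
    """One placement of a read: maximal exact match plus soft clips."""

    read_id: str
    ref: str
    ref_start: int
    ref_end: int
    strand: str  # orientation of the read against the reference
    clip_left: str  # unaligned prefix (in reference orientation)
    clip_right: str  # unaligned suffix
    score: int  # matched bases


class KmerIndex:
    """Sorted-array exact k-mer index over a set of named sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 20) -> None:
        self.k = k
        self.names = list(sequences)
        self.seqs = sequences
        kmer_parts, pos_parts, sid_parts = [], [], []
        for sid, name in enumerate(self.names):
            seq = sequences[name]
            if len(seq) < k:
                continue
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            enc = np.zeros(len(seq), dtype=np.uint64)
            enc[codes == ord("C")] = 1
            enc[codes == ord("G")] = 2
            enc[codes == ord("T")] = 3
            n = len(seq) - k + 1
            km = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                km = (km << np.uint64(2)) | enc[j : j + n]
            kmer_parts.append(km)
            pos_parts.append(np.arange(n, dtype=np.int64))
            sid_parts.append(np.full(n, sid, dtype=np.int32))
        if kmer_parts:
            kmers = np.concatenate(kmer_parts)
            order = np.argsort(kmers, kind="stable")
            self._kmers = kmers[order]
            self._pos = np.concatenate(pos_parts)[order]
            self._sid = np.concatenate(sid_parts)[order]
        else:
            self._kmers = np.array([], dtype=np.uint64)
            self._pos = np.array([], dtype=np.int64)
            self._sid = np.array([], dtype=np.int32)

    @staticmethod
    def encode_kmer(s: str) -> int:
        v = 0
        for ch in s:
            v = (v << 2) | {"A": 0, "C": 1, "G": 2, "T": 3}[ch]
        return v

    def lookup(self, kmer: str, max_hits: int = 64) -> list[tuple[str, int]]:
        v = np.uint64(self.encode_kmer(kmer))
        lo = np.searchsorted(self._kmers, v, side="left")
        hi = np.searchsorted(self._kmers, v, side="right")
        hits = [
            (self.names[self._sid[i]], int(self._pos[i])) for i in range(lo, min(hi, lo + max_hits))
        ]
        return hits


def _extend(read: str, seq: str, q: int, p: int) -> tuple[int, int, int, int]:
    """Maximal exact extension around a seed match; returns (qs, qe, ps, pe)."""
    qs, ps = q, p
    while qs > 0 and ps > 0 and read[qs - 1] == seq[ps - 1]:
        qs -= 1
        ps -= 1
    qe, pe = q, p
    n, m = len(read), len(seq)
    while qe < n and pe < m and read[qe] == seq[pe]:
        qe += 1
        pe += 1
    return qs, qe, ps, pe


def map_read(
    read_id: str, seq: str, index: KmerIndex, k: int = 20
) -> Alignment | None:
    """Best exact-seeded placement of one read (both orientations).

    Among equal-score placements exactly one is kept: lowest reference
    name in index order, then coordinate, then forward strand. Reads
    shorter than the seed are unmapped.
    """
    if len(seq) < k:
        return None
    best = None
    name_rank = {n: i for i, n in enumerate(index.names)}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        offsets = list(range(0, len(s) - k + 1, k))
        if offsets[-1] != len(s) - k:
            offsets.append(len(s) - k)
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for ref_name, p in index.lookup(s[off : off + k]):
                qs, qe, ps, pe = _extend(s, index.seqs[ref_name], off, p)
                key = (ref_name, ps - qs)
                if key in seen:
                    continue
                seen.add(key)
                score = qe - qs
                cand = (
                    -score,
                    name_rank[ref_name],
                    ps,
                    0 if strand == "+" else 1,
                    Alignment(
                        read_id=read_id,
                        ref=ref_name,
                        ref_start=ps,
                        ref_end=pe,
                        strand=strand,
                        clip_left=s[:qs],
                        clip_right=s[qe:],
                        score=score,
                    ),
                )
                if best is None or cand[:4] < best[:4]:
                    best = cand
    return best[4] if best is not None else None


def map_reads_exact(
    reads: list[tuple[str, str]],
    reference: dict[str, str],
    k: int = 20,
) -> dict[str, Alignment | None]:
    """Map a read set against the reference; returns read id -> alignment."""
    index = KmerIndex(reference, k=k)
    out: dict[str, Alignment | None] = {}
    n_unmapped = 0
    for rid, seq in reads:
        aln = map_read(rid, seq, index, k=k)
        if aln is None:
            n_unmapped += 1
        out[rid] = aln
    if n_unmapped:
        logger.info("%d reads unmapped", n_unmapped)
    return out


@dataclass
class JunctionEvidence:
    """Clustered per-side split/discordant support for one candidate junction."""

    chrom: str
    start: int
    end: int
    family: str
    left_split: int = 0
    right_split: int = 0
    left_discordant: int = 0
    right_discordant: int = 0
    left_positions: list[int] = field(default_factory=list)
    right_positions: list[int] = field(default_factory=list)
    left_split_positions: list[int] = field(default_factory=list)
    right_split_positions: list[int] = field(default_factory=list)


def _te_span_lookup(features: FeatureTable):
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for f in features.tes():
        by_chrom.setdefault(f.interval.chrom, []).append(
            (f.interval.start, f.interval.end, f.id, f.superfamily)
        )
    for v in by_chrom.values():
        v.sort()
    return by_chrom


def _find_te(by_chrom, chrom: str, start: int, end: int) -> tuple[str, str] | None:
    for s, e, tid, fam in by_chrom.get(chrom, []):
        if start < e and s < end:
            return tid, fam
    return None


def _remap_clip(clip: str, te_seqs: dict[str, str], families: dict[str, str]) -> str | None:
    """Family of the TE a clipped segment maps into (exact, either strand)."""
    for probe in (clip, revcomp(clip)):
        for tid, seq in te_seqs.items():
            if probe in seq:
                return families[tid]
    return None


def collect_evidence(
    alignments_r1: dict[str, Alignment | None],
    alignments_r2: dict[str, Alignment | None],
    annotation: FeatureTable,
    reference: dict[str, str],
    te_consensus: dict[str, str] | None = None,
    params: InsertionParams | None = None,
    concordant_distance: int = 1000,
) -> list[JunctionEvidence]:
    """Collect split and discordant evidence and cluster it by position.

    Clips of at least ``min_clip`` bp on genome-anchored reads are
    remapped (exact substring search) into annotated TE sequences or the
    consensus library; a clip landing in a TE yields split evidence whose
    side follows the clip orientation. Pairs whose mates map further than
    ``concordant_distance`` apart (or to different chromosomes), with one
    mate inside a TE span, yield discordant evidence at the genome-anchored
    mate. Evidence is clustered per family within ``max_cluster`` bp.
    """
    params = params or InsertionParams()
    by_chrom = _te_span_lookup(annotation)
    te_seqs = {
        f.id: reference[f.interval.chrom][f.interval.start : f.interval.end]
        for f in annotation.tes()
    }
    families = {f.id: f.superfamily for f in annotation.tes()}
    if te_consensus:
        te_seqs = dict(te_seqs)
        for fam, seq in te_consensus.items():
            te_seqs[f"consensus:{fam}"] = seq
            families[f"consensus:{fam}"] = fam

    # evidence rows: (chrom, pos, side, kind, family)
    rows: list[tuple[str, int, str, str, str]] = []

    def add_split(aln: Alignment) -> None:
        for clip, side, pos in (
            (aln.clip_right, "left", aln.ref_end),
            (aln.clip_left, "right", aln.ref_start),
        ):
            if len(clip) < params.min_clip:
                continue
            # genome anchor must itself be outside annotated TEs
            if _find_te(by_chrom, aln.ref, aln.ref_start, aln.ref_end) is not None:
                continue
            fam = _remap_clip(clip, te_seqs, families)
            if fam is not None:
                rows.append((aln.ref, pos, side, "split", fam))

    for rid, a1 in alignments_r1.items():
        a2 = alignments_r2.get(rid)
        for aln in (a1, a2):
            if aln is not None and aln.ref in reference:
                add_split(aln)
        if a1 is None or a2 is None:
            continue
        discordant = a1.ref != a2.ref or abs(a1.ref_start - a2.ref_start) > concordant_distance
        if not discordant:
            continue
        te1 = _find_te(by_chrom, a1.ref, a1.ref_start, a1.ref_end)
        te2 = _find_te(by_chrom, a2.ref, a2.ref_start, a2.ref_end)
        if (te1 is None) == (te2 is None):
            continue  # need exactly one TE mate and one genome anchor
        anchor, te = (a1, te2) if te1 is None else (a2, te1)
        fam = te[1]
        if anchor.strand == "+":
            rows.append((anchor.ref, anchor.ref_end, "left", "discordant", fam))
        else:
            rows.append((anchor.ref, anchor.ref_start, "right", "discordant", fam))

    # cluster per (chrom, family) within max_cluster
    clusters: list[JunctionEvidence] = []
    rows.sort(key=lambda r: (r[0], r[4], r[1]))
    cur: JunctionEvidence | None = None
    for chrom, pos, side, kind, fam in rows:
        if (
            cur is None
            or chrom != cur.chrom
            or fam != cur.family
            or pos - cur.start > params.max_cluster
        ):
            cur = JunctionEvidence(chrom=chrom, start=pos, end=pos + 1, family=fam)
            clusters.append(cur)
        cur.end = max(cur.end, pos + 1)
        if side == "left":
            cur.left_positions.append(pos)
            if kind == "split":
                cur.left_split += 1
                cur.left_split_positions.append(pos)
            else:
                cur.left_discordant += 1
        else:
            cur.right_positions.append(pos)
            if kind == "split":
                cur.right_split += 1
                cur.right_split_positions.append(pos)
            else:
                cur.right_discordant += 1
    return clusters


def call_insertions(
    evidence: list[JunctionEvidence],
    donor_spans: dict[str, GenomicInterval],
    centromere_mask: list[GenomicInterval],
    library: str = "lib1",
) -> pd.DataFrame:
    """Two-sided calling with donor-span and centromere exclusion.

    A cluster becomes a call only with >= 1 split or discordant read on
    each side. The call interval is bounded by the junction estimates
    (split positions preferred; they are base-exact on clean data). Calls
    intersecting the same family's donor span get ``donor_span``; calls
    intersecting the centromere mask get ``centromeric``.
    """
    rows = []
    for ev in evidence:
        left_n = ev.left_split + ev.left_discordant
        right_n = ev.right_split + ev.right_discordant
        if left_n < 1 or right_n < 1:
            continue
        left_pos = max(ev.left_split_positions or ev.left_positions)
        right_pos = min(ev.right_split_positions or ev.right_positions)
        start, end = min(left_pos, right_pos), max(left_pos, right_pos)
        if end == start:
            end = start + 1
        reason = "none"
        call_iv = GenomicInterval(ev.chrom, start, end)
        donor = donor_spans.get(ev.family)
        if donor is not None and call_iv.overlaps(donor):
            reason = "donor_span"
        elif any(call_iv.overlaps(m) for m in centromere_mask):
            reason = "centromeric"
        rows.append(
            {
                "library": library,
                "chrom": ev.chrom,
                "start": start,
                "end": end,
                "family": ev.family,
                "left_split": ev.left_split,
                "right_split": ev.right_split,
                "left_discordant": ev.left_discordant,
                "right_discordant": ev.right_discordant,
                "excluded_reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def filter_sample_specific(
    calls_per_library: dict[str, pd.DataFrame], match_radius: int = 100
) -> dict[str, pd.DataFrame]:
    """Drop calls seen in more than one library (marks ``multi_library``).

    Calls match across libraries when they share a family and chromosome
    and their interval centers lie within ``match_radius`` bp.
    """
    libs = list(calls_per_library)
    if len(libs) < 2:
        logger.warning("sample-specificity filter needs >= 2 libraries; identity")
        return calls_per_library
    centers = {
        lib: ((df["start"] + df["end"]) // 2).to_numpy() if len(df) else np.array([])
        for lib, df in calls_per_library.items()
    }
    out = {}
    for lib, df in calls_per_library.items():
        df = df.copy()
        for i, rec in df.iterrows():
            if rec["excluded_reason"] != "none":
                continue
            c = (rec["start"] + rec["end"]) // 2
            for other in libs:
                if other == lib:
                    continue
                odf = calls_per_library[other]
                if len(odf) == 0:
                    continue
                match = (
                    (odf["family"] == rec["family"])
                    & (odf["chrom"] == rec["chrom"])
                    & (np.abs(centers[other] - c) <= match_radius)
                )
                if bool(match.any()):
                    df.loc[i, "excluded_reason"] = "multi_library"
                    break
        out[lib] = df
    return out


def retained(calls: pd.DataFrame) -> pd.DataFrame:
    if calls.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return calls[calls["excluded_reason"] == "none"].reset_index(drop=True)


def family_transposition_table(
    calls_per_library: dict[str, pd.DataFrame], design_families: list[str]
) -> pd.DataFrame:
    """Retained-insertion counts per family x library.

    Families in the capture design appear even when all-zero.
    """
    libs = sorted(calls_per_library)
    fams = sorted(
        set(design_families)
        | {f for df in calls_per_library.values() for f in retained(df)["family"]}
    )
    mat = pd.DataFrame(0, index=fams, columns=libs)
    for lib, df in calls_per_library.items():
        for fam, n in retained(df)["family"].value_counts().items():
            mat.loc[fam, lib] = int(n)
    mat.index.name = "family"
    return mat
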