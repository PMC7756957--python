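"""Windowed differential DNA methylation and DMR calling.

The genome is tiled from coordinate 0 in non-overlapping windows (100 bp
for conventional DMRs, 20 bp for the short-DMR mode that resolves
linker-confined hypermethylation). Replicate libraries are pooled per
condition; each window is tested with a two-sided Fisher exact test on
the pooled methylated/unmethylated table, BH-adjusted per context at
FDR < 0.05, and retained as differential only when the coverage-weighted
methylation difference clears the context cutoff (40 percentage points
for CG, 20 for CHG and CHH). Neighbouring significant windows of the
same direction within one window size of each other are merged into DMRs.

Coverage filters mirror the windowed protocol: a cytosine counts toward a
window only when it is covered by at least 6 (CG, CHG) or 10 (CHH) reads
in every library, and a window is tested only when at least
``min_cytosines`` pass (6 in 100-bp mode; 2 in 20-bp mode, where six
cytosines are geometrically impossible for most windows).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import DmrParams
from .intervals import FeatureTable, MethylomeCounts

logger = logging.getLogger("epiphase.dmr")

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "difference",
    "q",
    "n_windows",
]


def aggregate_windows(
    methylomes_a: list[MethylomeCounts],
    methylomes_b: list[MethylomeCounts],
    context: str,
    params: DmrParams,
) -> pd.DataFrame:
    """Pool per-condition counts into non-overlapping windows.

    Returns one row per retained window with pooled ``meth_a/total_a/
    meth_b/total_b`` counts over qualifying cytosines and the number of
    qualifying cytosines. Windows are dropped unless at least
    ``params.min_cytosines`` cytosines are covered at the context's
    ``min_reads`` floor in *all* libraries of both conditions.
    """
    min_reads = params.min_reads[context]
    frames = []
    for cond, libs in (("a", methylomes_a), ("b", methylomes_b)):
        for i, m in enumerate(libs):
            sub = m.subset_context(context).frame
            frames.append(
                sub[["chrom", "pos", "strand", "n_meth", "n_total"]]
                .rename(
                    columns={
                        "n_meth": f"meth_{cond}{i}",
                        "n_total": f"total_{cond}{i}",
                    }
                )
                .set_index(["chrom", "pos", "strand"])
            )
    joined = pd.concat(frames, axis=1, join="outer").fillna(0)
    chroms_a = set(methylomes_a[0].chromosomes())
    chroms_b = set(methylomes_b[0].chromosomes())
    if not (chroms_a & chroms_b):
        raise ValueError("no overlapping chromosomes between conditions")

    total_cols = [c for c in joined.columns if c.startswith("total_")]
    a_meth = [c for c in joined.columns if c.startswith("meth_a")]
    a_tot = [c for c in joined.columns if c.startswith("total_a")]
    b_meth = [c for c in joined.columns if c.startswith("meth_b")]
    b_tot = [c for c in joined.columns if c.startswith("total_b")]

    qualifies = (joined[total_cols] >= min_reads).all(axis=1)
    joined = joined[qualifies]
    if joined.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cytosines", "meth_a", "total_a", "meth_b", "total_b"]
        )

    idx = joined.index.to_frame(index=False)
    win = idx["pos"] // params.window_size
    agg = pd.DataFrame(
        {
            "chrom": idx["chrom"].to_numpy(),
            "win": win.to_numpy(),
            "meth_a": joined[a_meth].sum(axis=1).to_numpy(),
            "total_a": joined[a_tot].sum(axis=1).to_numpy(),
            "meth_b": joined[b_meth].sum(axis=1).to_numpy(),
            "total_b": joined[b_tot].sum(axis=1).to_numpy(),
        }
    )
    grouped = agg.groupby(["chrom", "win"], sort=True).agg(
        n_cytosines=("meth_a", "size"),
        meth_a=("meth_a", "sum"),
        total_a=("total_a", "sum"),
        meth_b=("meth_b", "sum"),
        total_b=("total_b", "sum"),
    )
    grouped = grouped[grouped["n_cytosines"] >= params.min_cytosines].reset_index()
    grouped["start"] = grouped["win"] * params.window_size
    grouped["end"] = grouped["start"] + params.window_size
    return grouped[
        ["chrom", "start", "end", "n_cytosines", "meth_a", "total_a", "meth_b", "total_b"]
    ].astype(
        {
            "start": np.int64,
            "end": np.int64,
            "meth_a": np.int64,
            "total_a": np.int64,
            "meth_b": np.int64,
            "total_b": np.int64,
        }
    )


def fisher_two_sided(
    meth_a: np.ndarray, total_a: np.ndarray, meth_b: np.ndarray, total_b: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for 2x2 tables.

    The two-sided p sums hypergeometric point probabilities not exceeding
    the observed table's probability (with a small relative tolerance for
    floating-point ties), identical to the conditional exact test.
    """
    meth_a = np.asarray(meth_a, dtype=np.int64)
    total_a = np.asarray(total_a, dtype=np.int64)
    meth_b = np.asarray(meth_b, dtype=np.int64)
    total_b = np.asarray(total_b, dtype=np.int64)
    K = meth_a + meth_b
    N = total_a + total_b
    lo = np.maximum(0, K - total_b)
    hi = np.minimum(K, total_a)
    support = hi - lo + 1
    offsets = np.concatenate([[0], np.cumsum(support)])
    flat_k = np.concatenate([np.arange(l, h + 1) for l, h in zip(lo, hi)]) if len(lo) else np.array([], dtype=np.int64)
    rep = np.repeat(np.arange(len(K)), support)
    pmf = stats.hypergeom.pmf(flat_k, N[rep], K[rep], total_a[rep])
    p_obs = stats.hypergeom.pmf(meth_a, N, K, total_a)
    le = pmf <= p_obs[rep] * (1 + 1e-7)
    sums = np.add.reduceat(np.where(le, pmf, 0.0), offsets[:-1])
    return np.minimum(sums, 1.0)


def test_windows(windows: pd.DataFrame, params: DmrParams, context: str) -> pd.DataFrame:
    """Fisher-test pooled windows and BH-adjust within the run.

    Adds ``pct_a``, ``pct_b`` (coverage-weighted methylation percent),
    ``difference`` (B minus A, percentage points), ``p`` and ``q``.
    Windows with zero total coverage in a condition are skipped.
    """
    out = windows.copy()
    usable = (out["total_a"] > 0) & (out["total_b"] > 0)
    n_skip = int((~usable).sum())
    if n_skip:
        logger.info("skipping %d windows with zero coverage in a condition", n_skip)
    out = out[usable].reset_index(drop=True)
    if out.empty:
        for col in ("pct_a", "pct_b", "difference", "p", "q"):
            out[col] = pd.Series(dtype=float)
        return out
    out["pct_a"] = 100.0 * out["meth_a"] / out["total_a"]
    out["pct_b"] = 100.0 * out["meth_b"] / out["total_b"]
    out["difference"] = out["pct_b"] - out["pct_a"]
    out["p"] = fisher_two_sided(
        out["meth_a"].to_numpy(),
        out["total_a"].to_numpy(),
        out["meth_b"].to_numpy(),
        out["total_b"].to_numpy(),
    )
    out["q"] = stats.false_discovery_control(out["p"].to_numpy())
    out["context"] = context
    return out


def merge_windows_to_dmrs(tested: pd.DataFrame, params: DmrParams, context: str) -> pd.DataFrame:
    """Merge significant windows of one direction into DMRs.

    A window is significant when q < FDR and |difference| >= the context
    cutoff. Windows whose gap is at most one window size and whose
    direction matches are merged; the merged difference is recomputed from
    pooled counts and q is the minimum across members. The result is
    independent of input row order.
    """
    cutoff = params.diff_cutoffs[context]
    sig = tested[
        (tested["q"] < params.fdr) & (tested["difference"].abs() >= cutoff)
    ].copy()
    if sig.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    sig["direction"] = np.where(sig["difference"] > 0, "hyper", "hypo")
    sig = sig.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    rows = []
    cur = None
    for rec in sig.itertuples(index=False):
        if (
            cur is not None
            and rec.chrom == cur["chrom"]
            and rec.direction == cur["direction"]
            and rec.start - cur["end"] <= params.merge_gap
        ):
            cur["end"] = rec.end
            cur["meth_a"] += rec.meth_a
            cur["total_a"] += rec.total_a
            cur["meth_b"] += rec.meth_b
            cur["total_b"] += rec.total_b
            cur["q"] = min(cur["q"], rec.q)
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "direction": rec.direction,
                "meth_a": rec.meth_a,
                "total_a": rec.total_a,
                "meth_b": rec.meth_b,
                "total_b": rec.total_b,
                "q": rec.q,
                "n_windows": 1,
            }
    rows.append(cur)
    dmrs = pd.DataFrame(rows)
    dmrs["difference"] = 100.0 * (
        dmrs["meth_b"] / dmrs["total_b"] - dmrs["meth_a"] / dmrs["total_a"]
    )
    dmrs["context"] = context
    return dmrs[DMR_COLUMNS]


def call_dmrs(
    methylomes_a: list[MethylomeCounts],
    methylomes_b: list[MethylomeCounts],
    context: str,
    params: DmrParams,
) -> pd.DataFrame:
    """Window, test and merge in one call (condition B minus A)."""
    windows = aggregate_windows(methylomes_a, methylomes_b, context, params)
    tested = test_windows(windows, params, context)
    return merge_windows_to_dmrs(tested, params, context)


def restrict_to_features(
    dmrs: pd.DataFrame, features: FeatureTable, min_overlap_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep DMRs with at least the given fraction of their length in a feature.

    Adds a ``te_id`` column naming the feature carrying the largest overlap.
    """
    if dmrs.empty:
        out = dmrs.copy()
        out["te_id"] = pd.Series(dtype=str)
        return out
    by_chrom: dict[str, list] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    keep, te_ids = [], []
    for rec in dmrs.itertuples(index=False):
        best, best_ov = None, 0
        for f in by_chrom.get(rec.chrom, []):
            ov = max(0, min(rec.end, f.interval.end) - max(rec.start, f.interval.start))
            if ov > best_ov:
                best, best_ov = f.id, ov
        if best is not None and best_ov >= min_overlap_fraction * (rec.end - rec.start):
            keep.append(True)
            te_ids.append(best)
        else:
            keep.append(False)
            te_ids.append("")
    out = dmrs[np.array(keep)].copy()
    out["te_id"] = [t for t, k in zip(te_ids, keep) if k]
    return out.reset_index(drop=True)


def call_short_hyper_dmrs(
    methylomes_test: list[MethylomeCounts],
    methylomes_control: list[MethylomeCounts],
    annotation: FeatureTable,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """TE-specific short (20-bp) CG hyper-DMRs, test vs control.

    The composite short-DMR discovery: 20-bp CG windows, Fisher + BH,
    40-point cutoff, merging, then intersection with TE annotation (a DMR
    is TE-specific when >= 50% of its length lies within a TE). Only
    hypermethylated (test > control) DMRs are returned.
    """
    params = params or DmrParams.short()
    dmrs = call_dmrs(methylomes_control, methylomes_test, "CG", params)
    hyper = dmrs[dmrs["direction"] == "hyper"].reset_index(drop=True)
    return restrict_to_features(hyper, annotation.tes())


def metagene_methylation(
    methylome: MethylomeCounts,
    features: FeatureTable,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    n_bins: int = 50,
    flank: int = 500,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Meta-feature weighted methylation profile per context.

    Bins average the pooled ``sum(n_meth)/sum(n_total)`` of cytosines
    falling in each bin; positions without a covered cytosine contribute
    nothing to the bin mean. Returns a frame with ``context``, ``bin``
    (0 .. n_bins + 2*n_flank_bins - 1, left flank first) and
    ``methylation`` (percent).
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    total_bins = n_bins + 2 * n_flank_bins
    out_rows = []
    for context in contexts:
        sub = methylome.subset_context(context).frame
        by_chrom = {c: g for c, g in sub.groupby("chrom")}
        meth_sum = np.zeros(total_bins)
        total_sum = np.zeros(total_bins)
        for f in features:
            iv = f.interval
            g = by_chrom.get(iv.chrom)
            if g is None:
                continue
            pos = g["pos"].to_numpy()
            lo, hi = iv.start - flank, iv.end + flank
            m = (pos >= lo) & (pos < hi)
            if not m.any():
                continue
            p = pos[m]
            nm = g["n_meth"].to_numpy()[m]
            nt = g["n_total"].to_numpy()[m]
            bins = np.empty(len(p), dtype=np.int64)
            left = p < iv.start
            right = p >= iv.end
            body = ~left & ~right
            flank_bin = max(flank // n_flank_bins, 1)
            bins[left] = np.minimum((p[left] - lo) // flank_bin, n_flank_bins - 1)
            bins[body] = n_flank_bins + (
                (p[body] - iv.start) * n_bins // max(len(iv), 1)
            )
            bins[right] = (
                n_flank_bins
                + n_bins
                + np.minimum((p[right] - iv.end) // flank_bin, n_flank_bins - 1)
            )
            np.add.at(meth_sum, bins, nm)
            np.add.at(total_sum, bins, nt)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * meth_sum / total_sum
        for b in range(total_bins):
            out_rows.append({"context": context, "bin": b, "methylation": pct[b]})
    return pd.DataFrame(out_rows)
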