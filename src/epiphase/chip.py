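"""Spike-in ChIP quantification and differential marking.

Libraries spiked with exogenous (Drosophila) chromatin are scaled by
``Rx = r / Nd_IP``, where ``Nd_IP`` is the count of IP reads mapping to
the spike-in genome and ``r`` the percentage of spike-in-derived reads in
the matched input. Because the exogenous chromatin mass is constant
across samples, Rx-normalized totals recover genuine global changes in
the mark (for example a genome-wide halving of H3K27me3) that
within-library normalization erases.

Feature-level calling uses a per-feature Poisson enrichment test (IP vs
input) with BH control, and differential marking between genotypes uses a
negative-binomial Wald test with a method-of-moments common dispersion.
A feature is classed as a gain when p < 0.1 and log2FC > 2, a loss when
p < 0.1 and log2FC < -2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ChipParams
from .intervals import FeatureTable

logger = logging.getLogger("epiphase.chip")


@dataclass
class SpikeInStats:
    """Spike-in tallies for one library; ``rx`` is computed on demand."""

    library: str
    r: float  # percentage of spike-in reads in the input, (0, 100]
    nd_ip: int  # IP reads mapped to the spike-in genome

    @property
    def rx(self) -> float:
        return compute_rx(self.r, self.nd_ip)


def compute_rx(r: float, nd_ip: int) -> float:
    """Spike-in normalization factor Rx = r / Nd_IP."""
    if nd_ip <= 0 or r <= 0:
        raise ValueError(
            f"unusable spike-in: r={r}, Nd_IP={nd_ip} (both must be positive)"
        )
    return r / nd_ip


def normalize_feature_counts(counts: pd.DataFrame, stats_: SpikeInStats) -> pd.DataFrame:
    """Multiply each feature count by the library's Rx factor.

    Expects a frame with ``feature_id`` and ``count``; returns a copy with
    ``norm_count`` added. Scaling preserves the count ordering of features.
    """
    out = counts.copy()
    out["norm_count"] = out["count"] * stats_.rx
    return out


def call_marked_features(
    ip: pd.DataFrame,
    input_: pd.DataFrame,
    fdr: float = 0.01,
    pseudocount: float = 0.5,
) -> set[str]:
    """Features significantly marked in an IP library relative to input.

    One-sided Poisson tail P(X >= ip_count) with lambda equal to the
    depth-ratio-scaled input count plus a pseudocount, BH-adjusted across
    features at the given level.
    """
    merged = ip.merge(input_, on="feature_id", suffixes=("_ip", "_in"))
    if len(merged) != len(ip) or len(merged) != len(input_):
        raise ValueError("mismatched feature sets between IP and input")
    depth_ratio = ip["count"].sum() / max(input_["count"].sum(), 1)
    lam = merged["count_in"].to_numpy() * depth_ratio + pseudocount
    p = stats.poisson.sf(merged["count_ip"].to_numpy() - 1, lam)
    q = stats.false_discovery_control(p)
    return set(merged.loc[q < fdr, "feature_id"])


def _common_dispersion(mat: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across features.

    ``mat`` is features x replicates for one condition. Pools the moment
    equation var = mu + disp * mu^2 across features (ratio of sums), which
    stays unbiased even with two replicates, unlike a per-feature median.
    A value <= 0 means the data look Poisson- or under-dispersed.
    """
    mu = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    denom = float((mu**2).sum())
    if denom == 0:
        return 0.0
    return float((var - mu).sum() / denom)


def differential_marking(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    params: ChipParams | None = None,
) -> pd.DataFrame:
    """Differential marking of condition B versus A from normalized counts.

    Input frames have one row per feature (``feature_id``) and one column
    per replicate of normalized counts. The fold change is
    ``log2((mean_B + 1) / (mean_A + 1))`` and the p-value a Wald test on
    the log scale under a negative-binomial variance with method-of-moments
    common dispersion (Poisson fallback when the estimate is <= 0).
    """
    params = params or ChipParams()
    if not counts_a["feature_id"].equals(counts_b["feature_id"]):
        a_ids, b_ids = set(counts_a["feature_id"]), set(counts_b["feature_id"])
        if a_ids != b_ids:
            raise ValueError("feature absent in one condition")
        counts_b = (
            counts_b.set_index("feature_id").loc[counts_a["feature_id"]].reset_index()
        )
    mat_a = counts_a.drop(columns="feature_id").to_numpy(dtype=float)
    mat_b = counts_b.drop(columns="feature_id").to_numpy(dtype=float)
    n_a, n_b = mat_a.shape[1], mat_b.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValueError("need at least one replicate per condition")

    mean_a, mean_b = mat_a.mean(axis=1), mat_b.mean(axis=1)
    lfc = np.log2((mean_b + 1.0) / (mean_a + 1.0))

    # dispersion estimated within conditions that carry replicates
    ests = [_common_dispersion(m) for m in (mat_a, mat_b) if m.shape[1] > 1]
    disp = float(np.mean(ests)) if ests else 0.0
    if disp <= 0:
        disp = 0.0  # Poisson fallback: var = mu

    # delta-method variance of log(mean + 1); evaluated at the pooled null
    # mean (score-test style), which keeps the null distribution close to
    # normal where a per-condition plug-in inflates the tails
    mean_0 = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    var_0 = (mean_0 + disp * mean_0**2) / (mean_0 + 1.0) ** 2
    se = np.sqrt(var_0 / n_a + var_0 / n_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    # small-sample reference: classical two-sample df when replicates exist,
    # normal otherwise (the 1-vs-1 Poisson fallback has no replicate df)
    df = n_a + n_b - 2
    if df >= 1:
        p = 2 * stats.t.sf(np.abs(z), df)
    else:
        p = 2 * stats.norm.sf(np.abs(z))

    klass = np.where(
        (p < params.p_threshold) & (lfc > params.lfc_threshold),
        "gain",
        np.where(
            (p < params.p_threshold) & (lfc < -params.lfc_threshold), "loss", "none"
        ),
    )
    return pd.DataFrame(
        {
            "feature_id": counts_a["feature_id"],
            "log2FC": lfc,
            "p": p,
            "class": klass,
        }
    )


def classify(p: float, lfc: float, params: ChipParams | None = None) -> str:
    """Threshold rule: gain iff p < 0.1 and log2FC > 2; loss iff < -2."""
    params = params or ChipParams()
    if p < params.p_threshold and lfc > params.lfc_threshold:
        return "gain"
    if p < params.p_threshold and lfc < -params.lfc_threshold:
        return "loss"
    return "none"


def metaprofile(
    signal: dict[str, np.ndarray],
    features: FeatureTable,
    n_bins: int = 50,
    flank: int = 500,
    n_flank_bins: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Length-normalized mean profile and per-feature matrix over features.

    Each feature body is rescaled into ``n_bins`` bins flanked by
    ``n_flank_bins`` fixed-width bins covering ``flank`` bp on each side.
    Returns the column-mean profile and the per-feature matrix sorted by
    descending row mean (ties broken by feature id).
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    total_bins = n_bins + 2 * n_flank_bins
    rows, ids = [], []
    flank_bin = max(flank // n_flank_bins, 1)
    for f in features:
        iv = f.interval
        sig = signal[iv.chrom]
        if len(iv) < n_bins:
            logger.warning("feature %s shorter than bin count; bins repeat", f.id)
        row = np.empty(total_bins)
        edges = np.linspace(iv.start, iv.end, n_bins + 1).astype(int)
        for b in range(n_bins):
            lo, hi = edges[b], max(edges[b + 1], edges[b] + 1)
            row[n_flank_bins + b] = np.nanmean(sig[lo:hi])
        for b in range(n_flank_bins):
            lo = iv.start - flank + b * flank_bin
            hi = lo + flank_bin
            row[b] = np.nanmean(sig[max(lo, 0) : max(hi, 1)]) if hi > 0 else np.nan
            lo2 = iv.end + b * flank_bin
            row[n_flank_bins + n_bins + b] = (
                np.nanmean(sig[lo2 : lo2 + flank_bin]) if lo2 < len(sig) else np.nan
            )
        rows.append(row)
        ids.append(f.id)
    mat = pd.DataFrame(rows, index=ids)
    order = (
        mat.mean(axis=1)
        .to_frame("m")
        .assign(id=mat.index)
        .sort_values(["m", "id"], ascending=[False, True])
        .index
    )
    mat = mat.loc[order]
    return np.nanmean(mat.to_numpy(), axis=0), mat
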