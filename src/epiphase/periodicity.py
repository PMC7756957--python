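"""Nucleosome-phased methylation periodicity.

Per-position methylation fractions are extracted in a fixed window around
anchor positions (short-DMR centers, or the centers of well-positioned
nucleosomes overlapping those DMRs — the two-stage procedure: DMRs select
the loci, nucleosome centers anchor the final profile). The averaged
profile is analysed with a discrete Fourier transform periodogram after
mean removal, linear detrending and a split-cosine-bell taper — the
classical smoothed-periodogram preprocessing — and the dominant period is
the reciprocal of the highest-power frequency inside a period band
(default 50-500 bp). A phasing summary contrasts methylation over linker
versus core positions of a nucleosome occupancy profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PeriodicityParams
from .intervals import MethylomeCounts, NucleosomeTrack

logger = logging.getLogger("epiphase.periodicity")


@dataclass
class AnchoredProfileMatrix:
    """Per-anchor methylation fractions on a -flank..+flank offset grid."""

    anchors: list[tuple[str, int]]
    flank: int
    matrix: np.ndarray  # rows = anchors, columns = 2*flank+1 offsets; NaN = uncovered

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def mean_profile(self) -> np.ndarray:
        """Column means ignoring missing cells."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    def support(self) -> np.ndarray:
        return np.sum(~np.isnan(self.matrix), axis=0)


@dataclass
class Periodogram:
    freq: np.ndarray  # cycles/bp, strictly increasing in (0, 0.5]
    spec: np.ndarray  # power per frequency
    n: int

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.freq


@dataclass
class PhasingSummary:
    linker_mean: float
    core_mean: float
    correlation: float


def extract_anchored_profile(
    methylome: MethylomeCounts,
    anchors: list[tuple[str, int]],
    flank: int = 1000,
    context: str | None = "CG",
    chromosome_lengths: dict[str, int] | None = None,
) -> AnchoredProfileMatrix:
    """Methylation fraction at each offset around each anchor.

    Anchors closer than ``flank`` to a chromosome end are excluded. Cells
    with no covered cytosine are NaN and ignored by the column means.
    """
    frame = (
        methylome.subset_context(context).frame if context else methylome.frame
    )
    by_chrom = {}
    for chrom, g in frame.groupby("chrom"):
        g2 = g.groupby("pos", as_index=False)[["n_meth", "n_total"]].sum()
        by_chrom[chrom] = (
            g2["pos"].to_numpy(),
            g2["n_meth"].to_numpy(),
            g2["n_total"].to_numpy(),
        )

    kept = []
    for chrom, pos in anchors:
        if pos - flank < 0:
            continue
        if chromosome_lengths is not None and pos + flank >= chromosome_lengths[chrom]:
            continue
        if chromosome_lengths is None and chrom in by_chrom:
            if pos + flank > by_chrom[chrom][0].max():
                continue
        kept.append((chrom, int(pos)))
    if not kept:
        raise ValueError("all anchors fall out of bounds")

    width = 2 * flank + 1
    mat = np.full((len(kept), width), np.nan)
    for i, (chrom, pos) in enumerate(kept):
        if chrom not in by_chrom:
            continue
        cpos, nm, nt = by_chrom[chrom]
        lo = np.searchsorted(cpos, pos - flank)
        hi = np.searchsorted(cpos, pos + flank, side="right")
        sel = slice(lo, hi)
        cols = cpos[sel] - (pos - flank)
        covered = nt[sel] > 0
        mat[i, cols[covered]] = nm[sel][covered] / nt[sel][covered]
    return AnchoredProfileMatrix(anchors=kept, flank=flank, matrix=mat)


def _split_cosine_taper(n: int, fraction: float) -> np.ndarray:
    """Split cosine bell over ``fraction`` of each end (as in spectral practice)."""
    w = np.ones(n)
    m = int(np.floor(n * fraction))
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(m) + 0.5) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def periodogram(
    profile: np.ndarray,
    params: PeriodicityParams | None = None,
) -> Periodogram:
    """Raw FFT periodogram of a (possibly gappy) profile.

    Missing values are linearly interpolated (error above the configured
    missingness ceiling); the mean and a linear trend are removed and a
    split-cosine taper applied before the transform. Power is
    ``|X_k|^2 / n`` at frequencies ``k/n`` for ``k = 1 .. n//2``.
    """
    params = params or PeriodicityParams()
    x = np.asarray(profile, dtype=float).copy()
    n = len(x)
    if n < 64:
        raise ValueError(f"profile length {n} below the 64-sample minimum")
    missing = np.isnan(x)
    frac_missing = missing.mean()
    if frac_missing > params.max_missing_fraction:
        raise ValueError(
            f"{frac_missing:.0%} of the profile is missing "
            f"(ceiling {params.max_missing_fraction:.0%})"
        )
    if missing.any():
        idx = np.arange(n)
        x[missing] = np.interp(idx[missing], idx[~missing], x[~missing])

    x = x - x.mean()
    if params.detrend:
        t = np.arange(n) - (n - 1) / 2
        x = x - (t @ x) / (t @ t) * t
    if params.taper_fraction > 0:
        x = x * _split_cosine_taper(n, params.taper_fraction)

    X = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    freq = k / n
    spec = np.abs(X[1 : n // 2 + 1]) ** 2 / n
    return Periodogram(freq=freq, spec=spec, n=n)


def dominant_period(
    pg: Periodogram, band: tuple[float, float] = (50.0, 500.0)
) -> float:
    """Period (bp) of maximal power among frequencies whose reciprocal is in band.

    Ties are broken toward the lower period (higher frequency).
    """
    lo, hi = band
    periods = 1.0 / pg.freq
    in_band = (periods >= lo) & (periods <= hi)
    if not in_band.any():
        raise ValueError(f"no periodogram frequency falls in the {band} bp band")
    spec = pg.spec[in_band]
    per = periods[in_band]
    best = np.flatnonzero(spec == spec.max())
    return float(per[best].min())


def linker_phase_summary(
    methylation_profile: np.ndarray, occupancy_profile: np.ndarray
) -> PhasingSummary:
    """Linker-vs-core methylation means and profile correlation.

    Linker positions are those with occupancy below its median; core
    positions are at or above. The correlation is Pearson's r between the
    two profiles; it is negative when methylation is phased to linkers.
    """
    meth = np.asarray(methylation_profile, dtype=float)
    occ = np.asarray(occupancy_profile, dtype=float)
    if meth.shape != occ.shape:
        raise ValueError("profiles must share the offset grid")
    if np.nanstd(occ) == 0:
        raise ValueError("occupancy profile has zero variance; phasing undefined")
    ok = ~np.isnan(meth) & ~np.isnan(occ)
    meth, occ = meth[ok], occ[ok]
    med = np.median(occ)
    linker = occ < med
    corr = float(np.corrcoef(meth, occ)[0, 1])
    return PhasingSummary(
        linker_mean=float(meth[linker].mean()),
        core_mean=float(meth[~linker].mean()),
        correlation=corr,
    )


def nucleosome_anchors_near_dmrs(
    track: NucleosomeTrack, dmrs: pd.DataFrame, radius: int = 100
) -> list[tuple[str, int]]:
    """Centers of well-positioned nucleosomes within ``radius`` of a DMR center.

    The headline periodicity profile anchors on nucleosome centers of
    DMR-overlapping nucleosomes rather than on the DMRs themselves.
    """
    anchors = []
    for chrom in track.chromosomes():
        centers = track.centers[chrom]
        sub = dmrs[dmrs["chrom"] == chrom]
        if sub.empty or len(centers) == 0:
            continue
        dmr_centers = ((sub["start"] + sub["end"]) // 2).to_numpy()
        dmr_centers.sort()
        idx = np.searchsorted(dmr_centers, centers)
        near = np.zeros(len(centers), dtype=bool)
        left_ok = idx > 0
        near[left_ok] |= centers[left_ok] - dmr_centers[idx[left_ok] - 1] <= radius
        right_ok = idx < len(dmr_centers)
        near[right_ok] |= dmr_centers[idx[right_ok]] - centers[right_ok] <= radius
        anchors.extend((chrom, int(c)) for c in centers[near])
    return anchors


def occupancy_profile_from_track(
    track: NucleosomeTrack,
    anchors: list[tuple[str, int]],
    flank: int,
    core_width: int = 130,
) -> np.ndarray:
    """Mean rectangular-core occupancy around anchors, from center positions."""
    width = 2 * flank + 1
    acc = np.zeros(width)
    half = core_width // 2
    n = 0
    for chrom, pos in anchors:
        centers = track.centers.get(chrom)
        if centers is None:
            continue
        occ = np.zeros(width)
        lo = np.searchsorted(centers, pos - flank - half)
        hi = np.searchsorted(centers, pos + flank + half, side="right")
        for c in centers[lo:hi]:
            a = max(c - half - (pos - flank), 0)
            b = min(c + half + 1 - (pos - flank), width)
            if b > a:
                occ[a:b] = 1.0
        acc += occ
        n += 1
    if n == 0:
        raise ValueError("no anchors with a nucleosome track")
    return acc / n
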