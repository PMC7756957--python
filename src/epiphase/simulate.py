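"""Synthetic epigenome generator with known truth.

Builds random genomes carrying planted transposable elements (TEs) and
genes, phased nucleosome tracks across TE bodies, genotype-specific
methylomes in which hypermethylation is confined to inter-nucleosomal
linker patches, spike-in ChIP count tables, and paired-end read sets
spanning planted TE insertion junctions under a probe-capture design.
Every stochastic output comes with a truth table sufficient to score the
downstream callers without re-deriving ground truth.

The default geometry — a nucleosome repeat length (NRL) of 150 bp, a
130-bp core particle and a 20-bp hypermethylation patch centred
mid-linker — mirrors the regime the package's analysis stages are built
to detect: short (~20 bp) hypermethylated sequences spaced ~150 bp apart
and phased to well-positioned nucleosomes, as seen in Arabidopsis
*ddm1 clf* relative to *ddm1*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .config import substream
from .intervals import (
    FeatureRecord,
    FeatureTable,
    GenomicInterval,
    MethylomeCounts,
    NucleosomeTrack,
)

logger = logging.getLogger("epiphase.simulate")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

# family name -> consensus length (bp); loosely modelled on Arabidopsis
# TE superfamilies, including a Copia donor standing in for ATCOPIA93/EVD
DEFAULT_FAMILIES = {
    "LTR/Gypsy": 6000,
    "LTR/Copia": 5000,
    "DNA/MuDR": 3000,
    "DNA/others": 2500,
    "LINE/L1": 4000,
    "RC/Helitron": 3500,
}

PRE_MOTIFS = {
    "Telobox": "TTTAGGG",
    "GA-repeat": "GAGAGAGA",
    "CTCC": "CTCCCTCC",
    "AC-rich": "ACACACACAC",
}


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return decode(3 - encode(seq)[::-1])


@dataclass
class GenomeSpec:
    """Layout of a synthetic genome.

    ``nrl`` is the nucleosome repeat length; ``core_width`` the nucleosome
    core particle footprint; ``patch_width`` the linker hypermethylation
    patch, centred mid-linker. Defaults (150 / 130 / 20 bp) leave the patch
    exactly filling the linker.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 2_000_000
    pericentromere_fraction: float = 0.4
    centromere_fraction: float = 0.02
    te_count: int = 120
    te_length_range: tuple[int, int] = (2000, 8000)
    gene_count: int = 150
    gene_length_range: tuple[int, int] = (1000, 3000)
    nrl: int = 150
    core_width: int = 130
    patch_width: int = 20
    snap_patches_to_grid: int = 0  # 0 = off; else the window grid in bp
    te_divergence: float = 0.02
    motif_positive_fraction: float = 0.3
    cpg_boost: float = 0.5  # P(G | previous C) in TE consensus sequences
    families: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIES))

    def __post_init__(self) -> None:
        if self.core_width >= self.nrl:
            raise ValueError("nucleosome core width must be below the repeat length")
        if self.patch_width > self.nrl - self.core_width + self.snap_patches_to_grid:
            raise ValueError("patch width exceeds the linker plus grid tolerance")

    @classmethod
    def scaled(cls, chromosome_length: int, **kwargs) -> "GenomeSpec":
        """A spec with TE and gene counts scaled to the genome size, keeping
        the default feature density (so packing stays feasible)."""
        base = cls()
        scale = chromosome_length / base.chromosome_length
        kwargs.setdefault("te_count", max(4, round(base.te_count * scale)))
        kwargs.setdefault("gene_count", max(4, round(base.gene_count * scale)))
        return cls(chromosome_length=chromosome_length, **kwargs)


@dataclass
class SimulatedGenome:
    """A built genome plus every truth table downstream stages need."""

    spec: GenomeSpec
    sequences: dict[str, str]
    features: FeatureTable
    nucleosomes: NucleosomeTrack
    centromere_mask: list[GenomicInterval]
    pericentromeres: dict[str, tuple[int, int]]
    linker_patches: pd.DataFrame  # chrom, start, end, te_id
    motif_positive_ids: list[str]
    consensus: dict[str, str]  # family -> consensus sequence

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_fasta(self.sequences, outdir / "genome.fa")
        eio.write_fasta(self.consensus, outdir / "te_consensus.fa")
        eio.write_feature_annotation(self.features, outdir / "annotation.gff3", "GFF3")
        eio.write_nucleosome_centers(self.nucleosomes, outdir / "nucleosomes.bed")
        with open(outdir / "centromere_mask.bed", "w") as fh:
            for iv in self.centromere_mask:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        eio.write_table(self.linker_patches, outdir / "linker_patches.tsv")


def _markov_sequence(rng: np.random.Generator, length: int, cpg_boost: float) -> np.ndarray:
    """First-order Markov sequence with elevated P(G | C).

    Plant TE bodies are CpG-dense; a uniform random sequence would leave
    ~29% of 20-bp windows without a single CG dinucleotide and hence
    untestable for CG methylation.
    """
    rest = (1.0 - cpg_boost) / 3.0
    after_c = np.array([rest, rest, cpg_boost, rest])
    uniform = np.full(4, 0.25)
    out = np.empty(length, dtype=np.uint8)
    out[0] = rng.integers(4)
    draws = rng.random(length)
    cum_after_c = np.cumsum(after_c)
    cum_uniform = np.cumsum(uniform)
    for i in range(1, length):
        cum = cum_after_c if out[i - 1] == 1 else cum_uniform
        out[i] = np.searchsorted(cum, draws[i])
    return out


def _place_features(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    lengths: list[int],
    max_tries: int = 2000,
) -> list[int]:
    """Greedy non-overlapping placement; raises on infeasible packing."""
    L = len(occupancy)
    starts = []
    for length in lengths:
        placed = False
        for _ in range(max_tries):
            s = int(rng.integers(0, L - length))
            if not occupancy[s : s + length].any():
                occupancy[s : s + length] = True
                starts.append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: could not place a {length}-bp feature "
                f"after {max_tries} tries"
            )
    return starts


def build_genome(spec: GenomeSpec, seed: int) -> SimulatedGenome:
    """Build a genome with planted TEs, genes, nucleosomes and linker patches.

    TEs carry their family consensus with ``te_divergence`` substitutions;
    nucleosome centers are phased every ``nrl`` bp across each TE body; a
    hypermethylation patch of ``patch_width`` bp is recorded mid-linker
    between each pair of consecutive centers. PRE-like motifs are planted
    into a random ``motif_positive_fraction`` of TEs.
    """
    rng = substream(seed, "genome")
    consensus = {
        fam: decode(_markov_sequence(rng, length, spec.cpg_boost))
        for fam, length in spec.families.items()
    }
    fam_names = list(spec.families)

    sequences: dict[str, str] = {}
    features = FeatureTable()
    nucleosomes = NucleosomeTrack()
    centromere_mask: list[GenomicInterval] = []
    pericentromeres: dict[str, tuple[int, int]] = {}
    patch_rows: list[tuple[str, int, int, str]] = []
    motif_positive: list[str] = []

    lo, hi = spec.te_length_range
    glo, ghi = spec.gene_length_range
    half_core = spec.core_width // 2
    half_patch = spec.patch_width // 2

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = spec.chromosome_length
        codes = rng.integers(0, 4, size=L).astype(np.uint8)
        mid = L // 2
        peri_half = int(L * spec.pericentromere_fraction / 2)
        pericentromeres[chrom] = (mid - peri_half, mid + peri_half)
        cen_half = int(L * spec.centromere_fraction / 2)
        if cen_half > 0:
            centromere_mask.append(GenomicInterval(chrom, mid - cen_half, mid + cen_half))

        occupancy = np.zeros(L, dtype=bool)
        occupancy[mid - cen_half : mid + cen_half] = True  # keep TEs/genes off the centromere

        te_lengths, te_fams = [], []
        for _ in range(spec.te_count):
            fam = fam_names[int(rng.integers(len(fam_names)))]
            length = int(
                min(len(consensus[fam]), rng.integers(lo, hi + 1))
            )
            te_lengths.append(length)
            te_fams.append(fam)
        te_starts = _place_features(rng, occupancy, te_lengths)
        gene_lengths = [int(rng.integers(glo, ghi + 1)) for _ in range(spec.gene_count)]
        gene_starts = _place_features(rng, occupancy, gene_lengths)

        order = np.argsort(te_starts)
        for rank, idx in enumerate(order):
            s, length, fam = te_starts[idx], te_lengths[idx], te_fams[idx]
            te_id = f"{chrom}_TE{rank:04d}"
            body = encode(consensus[fam][:length]).copy()
            n_sub = rng.binomial(length, spec.te_divergence)
            if n_sub:
                pos = rng.choice(length, size=n_sub, replace=False)
                body[pos] = (body[pos] + rng.integers(1, 4, size=n_sub)) % 4
            codes[s : s + length] = body
            compartment = (
                "pericentromeric"
                if pericentromeres[chrom][0] <= s + length // 2 < pericentromeres[chrom][1]
                else "arm"
            )
            features.add(
                FeatureRecord(
                    GenomicInterval(chrom, s, s + length, "+"),
                    id=te_id,
                    kind="TE",
                    superfamily=fam,
                    compartment=compartment,
                )
            )
            # phased nucleosomes across the TE body
            centers = np.arange(s + half_core, s + length - half_core + 1, spec.nrl)
            if chrom in nucleosomes.centers:
                nucleosomes.centers[chrom] = np.concatenate(
                    [nucleosomes.centers[chrom], centers]
                )
            else:
                nucleosomes.centers[chrom] = centers.astype(np.int64)
            # mid-linker hypermethylation patches between consecutive centers
            for a, b in zip(centers[:-1], centers[1:]):
                pc = (a + b) // 2
                ps = int(pc - half_patch)
                if spec.snap_patches_to_grid:
                    g = spec.snap_patches_to_grid
                    ps = int(round(ps / g) * g)
                patch_rows.append((chrom, ps, ps + spec.patch_width, te_id))
            if rng.random() < spec.motif_positive_fraction:
                motif_positive.append(te_id)
                motif = PRE_MOTIFS[
                    list(PRE_MOTIFS)[int(rng.integers(len(PRE_MOTIFS)))]
                ]
                mpos = int(rng.integers(s, s + length - len(motif)))
                codes[mpos : mpos + len(motif)] = encode(motif)

        for gi, (s, length) in enumerate(
            sorted(zip(gene_starts, gene_lengths), key=lambda t: t[0])
        ):
            compartment = (
                "pericentromeric"
                if pericentromeres[chrom][0] <= s + length // 2 < pericentromeres[chrom][1]
                else "arm"
            )
            features.add(
                FeatureRecord(
                    GenomicInterval(chrom, s, s + length, "+"),
                    id=f"{chrom}_gene{gi:04d}",
                    kind="gene",
                    superfamily="",
                    compartment=compartment,
                )
            )

        nucleosomes.centers[chrom] = np.sort(nucleosomes.centers[chrom])
        sequences[chrom] = decode(codes)

    patches = pd.DataFrame(patch_rows, columns=["chrom", "start", "end", "te_id"])
    return SimulatedGenome(
        spec=spec,
        sequences=sequences,
        features=features,
        nucleosomes=nucleosomes,
        centromere_mask=centromere_mask,
        pericentromeres=pericentromeres,
        linker_patches=patches,
        motif_positive_ids=motif_positive,
        consensus=consensus,
    )


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

REGION_CLASSES = ("intergenic", "gene", "te_arm", "te_peri")


@dataclass
class GenotypeProfile:
    """Per-context, per-compartment methylation baselines for one genotype.

    ``baselines[context][region]`` gives the per-cytosine methylation
    probability; ``linker_gain[context]`` is added inside linker patches
    (the *ddm1 clf* hypermethylation). Coverage is Poisson with the given
    mean per cytosine.
    """

    name: str
    baselines: dict
    linker_gain: dict = field(default_factory=lambda: {"CG": 0.0, "CHG": 0.0, "CHH": 0.0})
    coverage: float = 30.0

    @classmethod
    def wt(cls, coverage: float = 30.0) -> "GenotypeProfile":
        return cls(
            "WT",
            {
                "CG": {"intergenic": 0.05, "gene": 0.05, "te_arm": 0.70, "te_peri": 0.85},
                "CHG": {"intergenic": 0.02, "gene": 0.01, "te_arm": 0.45, "te_peri": 0.60},
                "CHH": {"intergenic": 0.02, "gene": 0.01, "te_arm": 0.10, "te_peri": 0.15},
            },
            coverage=coverage,
        )

    @classmethod
    def ddm1(cls, coverage: float = 30.0) -> "GenotypeProfile":
        # DDM1 loss drains methylation from heterochromatic TEs
        return cls(
            "ddm1",
            {
                "CG": {"intergenic": 0.05, "gene": 0.05, "te_arm": 0.40, "te_peri": 0.20},
                "CHG": {"intergenic": 0.02, "gene": 0.01, "te_arm": 0.20, "te_peri": 0.10},
                "CHH": {"intergenic": 0.02, "gene": 0.01, "te_arm": 0.06, "te_peri": 0.05},
            },
            coverage=coverage,
        )

    @classmethod
    def clf(cls, coverage: float = 30.0) -> "GenotypeProfile":
        p = cls.wt(coverage)
        p.name = "clf"
        return p

    @classmethod
    def ddm1_clf(
        cls,
        coverage: float = 30.0,
        linker_gain: dict | None = None,
    ) -> "GenotypeProfile":
        # linker patches remethylate toward wild-type heterochromatic
        # levels (0.20 -> 0.75 CG in pericentromeric TEs): hypermethylation
        # strong enough that a caller with the standard 40-point CG cutoff
        # recovers planted patches reliably, as the phenomenon demands
        p = cls.ddm1(coverage)
        p.name = "ddm1_clf"
        p.linker_gain = linker_gain or {"CG": 0.55, "CHG": 0.30, "CHH": 0.10}
        return p


def reference_cytosines(sequence: str, chrom: str) -> pd.DataFrame:
    """All cytosine positions on both strands with their CG/CHG/CHH context."""
    codes = encode(sequence)
    n = len(codes)
    nxt1 = np.roll(codes, -1)
    nxt2 = np.roll(codes, -2)
    nxt1[-1] = 255
    nxt2[-2:] = 255
    prv1 = np.roll(codes, 1)
    prv2 = np.roll(codes, 2)
    prv1[0] = 255
    prv2[:2] = 255

    frames = []
    plus = np.flatnonzero(codes == 1)  # C on + strand
    ctx_p = np.where(
        nxt1[plus] == 2, "CG", np.where(nxt2[plus] == 2, "CHG", "CHH")
    )
    frames.append(pd.DataFrame({"pos": plus, "strand": "+", "context": ctx_p}))
    minus = np.flatnonzero(codes == 2)  # G on + strand = C on - strand
    ctx_m = np.where(
        prv1[minus] == 1, "CG", np.where(prv2[minus] == 1, "CHG", "CHH")
    )
    frames.append(pd.DataFrame({"pos": minus, "strand": "-", "context": ctx_m}))
    out = pd.concat(frames).sort_values(["pos", "strand"]).reset_index(drop=True)
    out.insert(0, "chrom", chrom)
    return out


def _region_class_array(genome: SimulatedGenome, chrom: str) -> np.ndarray:
    L = len(genome.sequences[chrom])
    cls = np.zeros(L, dtype=np.uint8)  # 0 = intergenic
    for f in genome.features:
        if f.interval.chrom != chrom:
            continue
        if f.kind == "gene":
            cls[f.interval.start : f.interval.end] = 1
        else:
            cls[f.interval.start : f.interval.end] = (
                3 if f.compartment == "pericentromeric" else 2
            )
    return cls


def simulate_methylome(
    genome: SimulatedGenome, profile: GenotypeProfile, seed: int
) -> MethylomeCounts:
    """Simulate per-cytosine counts for one library of one genotype.

    For every reference cytosine, coverage is Poisson(``profile.coverage``)
    and the methylated count is Binomial(coverage, p) with
    p = baseline(context, region) + linker gain inside patch intervals,
    clipped into [0, 1] (with a warning if clipping was needed).
    """
    rng = substream(seed, f"methylome:{profile.name}")
    frames = []
    for chrom, seq in genome.sequences.items():
        cyt = reference_cytosines(seq, chrom)
        region = _region_class_array(genome, chrom)[cyt["pos"].to_numpy()]
        in_patch = np.zeros(len(seq), dtype=bool)
        sub = genome.linker_patches[genome.linker_patches["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            in_patch[s:e] = True
        patch_mask = in_patch[cyt["pos"].to_numpy()]

        p = np.empty(len(cyt))
        ctx = cyt["context"].to_numpy()
        for context in ("CG", "CHG", "CHH"):
            lut = np.array(
                [profile.baselines[context][rc] for rc in REGION_CLASSES]
            )
            m = ctx == context
            p[m] = lut[region[m]]
            gain = profile.linker_gain.get(context, 0.0)
            if gain:
                p[m & patch_mask] += gain
        if (p > 1).any() or (p < 0).any():
            logger.warning(
                "clipping %d methylation probabilities outside [0, 1]",
                int(((p > 1) | (p < 0)).sum()),
            )
            p = np.clip(p, 0.0, 1.0)

        n_total = rng.poisson(profile.coverage, size=len(cyt))
        n_meth = rng.binomial(n_total, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cyt["pos"].to_numpy(),
                    "strand": cyt["strand"].to_numpy(),
                    "context": ctx,
                    "n_meth": n_meth,
                    "n_total": n_total,
                }
            )
        )
    return MethylomeCounts(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# spike-in ChIP simulation
# ---------------------------------------------------------------------------


@dataclass
class ChipSimSpec:
    """One ChIP-seq library draw.

    ``multipliers`` maps feature id to its true enrichment multiplier (the
    amount of immunoprecipitated material per bp relative to baseline);
    ``spikein_mass`` is the exogenous chromatin mass on the same scale, so
    the expected spike-in read fraction is mass / (target + mass);
    ``input_r`` is the percentage of spike-in reads in the matched input.
    Counts are gamma-Poisson (negative binomial) with the given dispersion.
    """

    multipliers: dict
    library_size: int = 1_000_000
    spikein_mass: float | None = None  # default: 5% of unit-multiplier target mass
    input_r: float = 5.0
    dispersion: float = 0.1


def simulate_chip_experiment(
    genome: SimulatedGenome, spec: ChipSimSpec, seed: int, library_id: str = "lib1"
) -> tuple[pd.DataFrame, "SpikeInStats"]:
    """Simulate one IP library: per-feature counts plus spike-in tallies.

    Returns a counts DataFrame (feature_id, count) and the library's
    :class:`~epiphase.chip.SpikeInStats` with r and Nd_IP filled in.
    """
    from .chip import SpikeInStats  # local import to avoid a cycle

    if spec.library_size <= 0:
        raise ValueError("library size must be positive")
    rng = substream(seed, f"chip:{library_id}")
    feats = [f for f in genome.features if f.id in spec.multipliers]
    if len(feats) != len(spec.multipliers):
        missing = set(spec.multipliers) - {f.id for f in feats}
        raise ValueError(f"enrichment map covers unknown features {sorted(missing)}")
    lengths = np.array([len(f.interval) for f in feats], dtype=float)
    mult = np.array([spec.multipliers[f.id] for f in feats], dtype=float)
    target_mass = mult * lengths
    unit_mass = float(lengths.sum())
    spike_mass = spec.spikein_mass if spec.spikein_mass is not None else 0.05 * unit_mass
    total = target_mass.sum() + spike_mass

    lam = spec.library_size * target_mass / total
    if spec.dispersion > 0:
        # gamma-Poisson mixture => negative binomial with var = mu + disp * mu^2
        lam = lam * rng.gamma(1.0 / spec.dispersion, spec.dispersion, size=len(lam))
    counts = rng.poisson(lam)
    counts[mult == 0] = 0
    nd_ip = int(rng.binomial(spec.library_size, spike_mass / total))
    frame = pd.DataFrame({"feature_id": [f.id for f in feats], "count": counts})
    stats = SpikeInStats(library=library_id, r=spec.input_r, nd_ip=nd_ip)
    return frame, stats


# ---------------------------------------------------------------------------
# insertion + read simulation
# ---------------------------------------------------------------------------


@dataclass
class InsertionSimSpec:
    """Planted-insertion read simulation under a TE-end capture design.

    Probes cover ``capture_end_bp`` at both ends of every mobile TE copy
    (donor and planted); only read pairs overlapping a probe window are
    retained, mimicking TE-sequence capture.
    """

    donor_te_id: str
    n_insertions: int = 5
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    capture_end_bp: int = 200
    min_gap: int = 2000  # between planted insertion sites and from donor/centromere


def simulate_insertions_and_reads(
    genome: SimulatedGenome, spec: InsertionSimSpec, seed: int, library_id: str = "lib1"
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Plant insertions of the donor TE and emit capture-retained read pairs.

    Returns ``(reads_r1, reads_r2, truth)`` where reads are
    ``(read_id, sequence)`` lists and ``truth`` has one row per planted
    insertion with its reference-coordinate junction position.
    """
    rng = substream(seed, f"insertions:{library_id}")
    donor = genome.features[spec.donor_te_id]
    chrom = donor.interval.chrom
    ref = genome.sequences[chrom]
    L = len(ref)
    donor_seq = ref[donor.interval.start : donor.interval.end]
    if spec.read_length >= spec.insert_mean:
        raise ValueError("read length must be below the mean insert size")

    forbidden: list[tuple[int, int]] = [
        (donor.interval.start - spec.min_gap, donor.interval.end + spec.min_gap)
    ]
    for iv in genome.centromere_mask:
        if iv.chrom == chrom:
            forbidden.append((iv.start - spec.min_gap, iv.end + spec.min_gap))
    # junctions inside annotated TEs are unresolvable for a split-read
    # caller (repeat-ambiguous anchors), so sites avoid all TE spans
    for f in genome.features.tes():
        if f.interval.chrom == chrom:
            forbidden.append((f.interval.start - spec.read_length, f.interval.end + spec.read_length))

    sites: list[int] = []
    tries = 0
    while len(sites) < spec.n_insertions:
        tries += 1
        if tries > 10000:
            raise ValueError("could not place requested insertions")
        x = int(rng.integers(spec.min_gap, L - spec.min_gap))
        if any(lo <= x < hi for lo, hi in forbidden):
            logger.debug("rejected insertion site %d inside a masked span", x)
            continue
        if any(abs(x - s) < spec.min_gap for s in sites):
            continue
        sites.append(x)
    sites.sort()

    # build the sample haplotype and track TE copy intervals in hap coords
    pieces, te_copies = [], []
    prev = 0
    shift = 0
    for x in sites:
        pieces.append(ref[prev:x])
        te_copies.append((x + shift, x + shift + len(donor_seq)))
        pieces.append(donor_seq)
        shift += len(donor_seq)
        prev = x
    pieces.append(ref[prev:])
    hap = "".join(pieces)
    # reference TE copies of the donor family shift with upstream insertions
    for f in genome.features:
        if f.kind == "TE" and f.interval.chrom == chrom and f.superfamily == donor.superfamily:
            off = sum(len(donor_seq) for x in sites if x <= f.interval.start)
            te_copies.append((f.interval.start + off, f.interval.end + off))

    cap = spec.capture_end_bp
    windows = []
    for s, e in te_copies:
        windows.append((max(0, s - 0), min(len(hap), s + cap)))
        windows.append((max(0, e - cap), min(len(hap), e)))
    windows.sort()
    merged = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    win_starts = np.array([w[0] for w in merged])
    win_ends = np.array([w[1] for w in merged])

    n_frag = int(spec.coverage * len(hap) / (2 * spec.read_length))
    frag_len = np.maximum(
        rng.normal(spec.insert_mean, spec.insert_sd, size=n_frag).astype(int),
        2 * spec.read_length,
    )
    starts = rng.integers(0, len(hap) - frag_len.max() - 1, size=n_frag)
    ends = starts + frag_len

    def overlaps_capture(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(win_starts, hi) - 1
        ok = idx >= 0
        out = np.zeros(len(lo), dtype=bool)
        out[ok] = lo[ok] < win_ends[idx[ok]]
        # also the window starting inside [lo, hi)
        idx2 = np.searchsorted(win_starts, lo)
        ok2 = idx2 < len(win_starts)
        out[ok2] |= win_starts[idx2[ok2]] < hi[ok2]
        return out

    rl = spec.read_length
    keep = overlaps_capture(starts, starts + rl) | overlaps_capture(ends - rl, ends)
    reads_r1, reads_r2 = [], []
    for i in np.flatnonzero(keep):
        s, e = int(starts[i]), int(ends[i])
        rid = f"{library_id}_frag{i}"
        reads_r1.append((rid, hap[s : s + rl]))
        reads_r2.append((rid, revcomp(hap[e - rl : e])))

    truth = pd.DataFrame(
        {
            "library": library_id,
            "chrom": chrom,
            "position": sites,
            "family": donor.superfamily,
            "donor_te_id": spec.donor_te_id,
        }
    )
    return reads_r1, reads_r2, truth
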