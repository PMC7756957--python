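"""Run configuration and seeded random-number substreams.

A single master seed drives every stochastic stage. Each stage draws a
*named* substream via :func:`substream`, so re-running one stage in
isolation reproduces exactly the numbers it saw inside a full run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger("epiphase")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child RNG of a master seed.

    Uses :class:`numpy.random.SeedSequence` spawn keys derived from the
    stage name, so streams for different stages are statistically
    independent and insensitive to call order.
    """
    key = [b for b in name.encode("utf-8")]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class DmrParams:
    """Windowed DMR-calling parameters.

    ``diff_cutoffs`` are in percentage points; ``min_reads`` is the
    per-cytosine coverage floor applied in every library; ``min_cytosines``
    is the per-window floor of cytosines passing that filter. The merge gap
    equals the window size.
    """

    window_size: int = 100
    fdr: float = 0.05
    diff_cutoffs: dict = field(
        default_factory=lambda: {"CG": 40.0, "CHG": 20.0, "CHH": 20.0}
    )
    min_reads: dict = field(default_factory=lambda: {"CG": 6, "CHG": 6, "CHH": 10})
    min_cytosines: int = 6

    @classmethod
    def short(cls) -> "DmrParams":
        """The 20-bp short-DMR configuration.

        The six-cytosine floor is geometrically impossible in most 20-bp
        windows, so the short mode defaults to two qualifying cytosines.
        """
        return cls(window_size=20, min_cytosines=2)

    @property
    def merge_gap(self) -> int:
        return self.window_size


@dataclass
class ChipParams:
    """Differential-marking thresholds (p < 0.1, |log2FC| > 2) and the
    marked-feature caller's BH level."""

    p_threshold: float = 0.1
    lfc_threshold: float = 2.0
    marked_fdr: float = 0.01


@dataclass
class PeriodicityParams:
    flank: int = 1000
    band_low: float = 50.0
    band_high: float = 500.0
    taper_fraction: float = 0.1
    detrend: bool = True
    max_missing_fraction: float = 0.2


@dataclass
class InsertionParams:
    seed_k: int = 20
    min_clip: int = 15
    max_cluster: int = 200
    match_radius: int = 100


@dataclass
class RunConfig:
    """Top-level run configuration: master seed plus per-stage parameter blocks."""

    seed: int = 0
    dmr: DmrParams = field(default_factory=DmrParams)
    chip: ChipParams = field(default_factory=ChipParams)
    periodicity: PeriodicityParams = field(default_factory=PeriodicityParams)
    insertions: InsertionParams = field(default_factory=InsertionParams)
    # pericentromere span per chromosome, {chrom: (start, end)}; not inferred
    pericentromeres: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
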