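"""Set-level statistics: overlap, motif and family enrichment, allele
fractions and fold-change summaries over feature subsets.

Overlap enrichment answers questions of the form "do TEs that gain
H3K27me3 overlap TEs that gain CG methylation more than chance?" with an
exact upper-tail hypergeometric test; the expected overlap under
independence is |A| x |B| / N for a universe of N features, and the fold
is observed / expected. The universe size is always an explicit input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import revcomp

logger = logging.getLogger("epiphase.setstats")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

# default PRE-like motif patterns; the published motif catalogue does not
# print explicit patterns, so these are config defaults, overridable
DEFAULT_MOTIFS = {
    "Telobox": "TTTAGGG",
    "CTCC": "CTCCCTCC",
    "GA-repeat": "GAGAGAGA",
    "AC-rich": "ACACACACAC",
}


@dataclass
class OverlapEnrichmentResult:
    n_a: int
    n_b: int
    n_observed: int
    n_universe: int
    expected: float
    fold: float
    p: float


@dataclass
class MotifSpec:
    """An IUPAC motif; a sequence is motif-positive at >= min_occurrences
    matches on either strand."""

    name: str
    pattern: str
    min_occurrences: int = 1

    def count(self, sequence: str) -> int:
        regex = re.compile("".join(IUPAC[c] for c in self.pattern.upper()))
        n = len(regex.findall(sequence))
        n += len(regex.findall(revcomp(sequence)))
        return n

    def positive(self, sequence: str) -> bool:
        return self.count(sequence) >= self.min_occurrences


def default_motifs() -> list[MotifSpec]:
    return [MotifSpec(name, pat) for name, pat in DEFAULT_MOTIFS.items()]


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapEnrichmentResult:
    """Fold and exact hypergeometric upper-tail p for the overlap of A and B.

    P(X >= observed) where X is the overlap of a random |B|-subset of the
    universe with the fixed set A.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("A and B must be subsets of the universe")
    n_a, n_b, n = len(set_a), len(set_b), len(universe)
    observed = len(set_a & set_b)
    expected = n_a * n_b / n
    fold = observed / expected if expected > 0 else np.nan
    p = float(stats.hypergeom.sf(observed - 1, n, n_a, n_b))
    return OverlapEnrichmentResult(
        n_a=n_a, n_b=n_b, n_observed=observed, n_universe=n,
        expected=expected, fold=fold, p=p,
    )


def motif_enrichment(
    target: dict[str, str],
    background: dict[str, str],
    motifs: list[MotifSpec] | None = None,
    test: str = "fisher",
) -> pd.DataFrame:
    """Per-motif positive proportions in target vs background sequences.

    Each motif's 2x2 positive/negative x target/background table is tested
    two-sided (Fisher exact by default; ``test="prop_t"`` uses a two-sample
    z/t approximation of the proportion difference for compatibility).
    """
    motifs = motifs or default_motifs()
    rows = []
    for motif in motifs:
        pos_t = sum(motif.positive(s) for s in target.values())
        pos_b = sum(motif.positive(s) for s in background.values())
        n_t, n_b = len(target), len(background)
        prop_t = pos_t / n_t if n_t else 0.0
        prop_b = pos_b / n_b if n_b else 0.0
        if max((len(s) for s in list(target.values()) + list(background.values())), default=0) < len(motif.pattern):
            p = 1.0
        elif test == "fisher":
            _, p = stats.fisher_exact(
                [[pos_t, n_t - pos_t], [pos_b, n_b - pos_b]], alternative="two-sided"
            )
        else:
            pool = (pos_t + pos_b) / (n_t + n_b)
            se = np.sqrt(pool * (1 - pool) * (1 / n_t + 1 / n_b))
            z = (prop_t - prop_b) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "motif": motif.name,
                "proportion_target": prop_t,
                "proportion_background": prop_b,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def family_composition(
    set_ids: set[str],
    annotation,
    background_ids: set[str],
    min_expected: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Superfamily proportions of a set vs background, with a chi-square test.

    Tests the set's family counts against the background proportions,
    pooling categories whose expected count falls below ``min_expected``
    into an "other" class. Returns (proportions frame, p); p is NaN when
    the background has a single family (test skipped).
    """
    if not set_ids:
        raise ValueError("empty feature set")
    fam_of = {f.id: f.superfamily for f in annotation}
    set_counts = pd.Series([fam_of[i] for i in set_ids]).value_counts()
    bg_counts = pd.Series([fam_of[i] for i in background_ids]).value_counts()
    fams = sorted(set(bg_counts.index) | set(set_counts.index))
    frame = pd.DataFrame(
        {
            "superfamily": fams,
            "proportion_set": [set_counts.get(f, 0) / len(set_ids) for f in fams],
            "proportion_background": [
                bg_counts.get(f, 0) / len(background_ids) for f in fams
            ],
        }
    )
    if len(bg_counts) < 2:
        logger.warning("single-family background; chi-square test skipped")
        return frame, float("nan")
    obs = np.array([set_counts.get(f, 0) for f in fams], dtype=float)
    exp = np.array([bg_counts.get(f, 0) / len(background_ids) for f in fams]) * len(set_ids)
    # pool small-expectation categories
    big = exp >= min_expected
    if (~big).any():
        obs = np.concatenate([obs[big], [obs[~big].sum()]])
        exp = np.concatenate([exp[big], [exp[~big].sum()]])
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    exp = exp * obs.sum() / exp.sum()  # renormalize after pooling/drops
    if len(obs) < 2:
        return frame, float("nan")
    _, p = stats.chisquare(obs, exp)
    return frame, float(p)


def allele_fraction(count_g: int, count_t: int) -> tuple[float, float]:
    """Percent of the diagnostic G (EVD) and T (ATR) alleles at the
    discriminating SNP, from pyrosequencing-style counts."""
    if count_g < 0 or count_t < 0:
        raise ValueError("negative allele counts")
    total = count_g + count_t
    if total == 0:
        raise ValueError("zero total allele count; fraction undefined")
    pct_evd = 100.0 * count_g / total
    return pct_evd, 100.0 - pct_evd


@dataclass
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


def fc_summary(
    de_table: pd.DataFrame,
    subset: set[str],
    group_col: str = "group",
    value_col: str = "log2FC",
    id_col: str = "feature_id",
    reference_group: str | None = None,
) -> tuple[list[GroupSummary], pd.DataFrame]:
    """Boxplot statistics of log2 fold changes per group over a feature
    subset, plus Welch t-tests of each group against the reference.

    Returns (group summaries, pairwise frame with columns group, ref,
    t, p, direction). With a single observation per group the quartiles
    collapse to the value and the t-test is skipped with a warning.
    """
    sub = de_table[de_table[id_col].isin(subset)]
    if sub.empty:
        raise ValueError("feature subset is disjoint from the DE table")
    groups = list(dict.fromkeys(sub[group_col]))
    ref = reference_group if reference_group is not None else groups[0]
    summaries = []
    for g in groups:
        v = sub.loc[sub[group_col] == g, value_col].to_numpy(dtype=float)
        summaries.append(
            GroupSummary(
                group=g,
                n=len(v),
                median=float(np.median(v)),
                q1=float(np.percentile(v, 25)),
                q3=float(np.percentile(v, 75)),
            )
        )
    rows = []
    ref_v = sub.loc[sub[group_col] == ref, value_col].to_numpy(dtype=float)
    for g in groups:
        if g == ref:
            continue
        v = sub.loc[sub[group_col] == g, value_col].to_numpy(dtype=float)
        if len(v) < 2 or len(ref_v) < 2:
            logger.warning("group %s or reference has < 2 observations; t-test skipped", g)
            t = p = float("nan")
        else:
            t, p = stats.ttest_ind(v, ref_v, equal_var=False)
        rows.append(
            {
                "group": g,
                "ref": ref,
                "t": float(t),
                "p": float(p),
                "direction": "decrease" if np.median(v) < np.median(ref_v) else "increase",
            }
        )
    return summaries, pd.DataFrame(rows, columns=["group", "ref", "t", "p", "direction"])
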