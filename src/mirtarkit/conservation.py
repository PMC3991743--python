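"""Positional conservation and SNP-impact analysis of target sites.

A germplasm panel is a set of varieties, each contributing one sequence of
the fixed-length target site (amplicons are trimmed to the site before
input; rice varieties are inbred, so one sequence per variety).  The module
computes a per-position base-frequency profile with information content
(the statistic behind sequence-logo letter heights), calls SNPs in mature
miRNA coordinates, and re-scores each variety's site against the miRNA to
ask whether recognition is retained.

Site positions map to miRNA coordinates antiparallel-wise: miRNA position
``p`` faces site position ``L - p + 1`` (5'->3' on the mRNA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duplex import (
    MatureMiRNA,
    ScoringParams,
    accept_site,
    normalize_sequence,
    score_duplex,
)

__all__ = [
    "GermplasmPanel",
    "PositionProfile",
    "SNPRecord",
    "ImpactCall",
    "build_profile",
    "call_snps",
    "count_critical_snps",
    "classify_impact",
    "plot_logo",
]

_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class GermplasmPanel:
    """Variety-labelled site sequences aligned to a reference site."""

    gene_id: str
    reference_site: str
    entries: dict  # variety_id -> site sequence (normalised, length L)

    def __post_init__(self) -> None:
        ref = normalize_sequence(self.reference_site)
        object.__setattr__(self, "reference_site", ref)
        if not self.entries:
            raise ValueError(f"panel {self.gene_id!r} has no entries")
        norm = {}
        for vid, seq in self.entries.items():
            seq = normalize_sequence(seq)
            if len(seq) != len(ref):
                raise ValueError(
                    f"panel {self.gene_id!r}: variety {vid!r} sequence length "
                    f"{len(seq)} != reference length {len(ref)}"
                )
            norm[vid] = seq
        object.__setattr__(self, "entries", norm)

    @property
    def length(self) -> int:
        return len(self.reference_site)

    @property
    def size(self) -> int:
        return len(self.entries)

    def site_index(self, mirna_position: int) -> int:
        """0-based site string index facing a 1-based miRNA position."""
        return self.length - mirna_position


@dataclass(frozen=True)
class PositionProfile:
    """Per-miRNA-position base counts, frequencies and information content.

    ``counts``/``frequencies`` are DataFrames indexed by miRNA position
    1..L with columns A, C, G, U; ``information_bits`` is a Series on the
    same index with IC_p = 2 + sum_b f_b log2 f_b (0 log 0 := 0), i.e. the
    total letter height at that position of a sequence logo.  No
    small-sample correction is applied.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    information_bits: pd.Series


def build_profile(panel: GermplasmPanel) -> PositionProfile:
    """Base-composition profile of a panel in miRNA coordinates."""
    L = panel.length
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, L + 1, name="mirna_position"),
        columns=list(_BASES), dtype=int,
    )
    for seq in panel.entries.values():
        for p in range(1, L + 1):
            counts.loc[p, seq[panel.site_index(p)]] += 1
    freqs = counts.div(counts.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs.values > 0, freqs.values * np.log2(freqs.values), 0.0)
    ic = pd.Series(2.0 + plogp.sum(axis=1), index=freqs.index, name="ic_bits")
    return PositionProfile(counts=counts, frequencies=freqs, information_bits=ic)


@dataclass(frozen=True)
class SNPRecord:
    """A polymorphic site position, reported in miRNA coordinates."""

    position: int
    alleles: dict  # base -> count, counts sum to panel size
    major_allele: str
    minor_alleles: tuple
    in_critical_region: bool
    genotypes: dict  # variety_id -> base


def call_snps(
    panel: GermplasmPanel,
    critical_region: tuple[int, int] = (2, 8),
    min_minor_count: int = 1,
) -> list[SNPRecord]:
    """Find positions with >= 2 observed alleles across the panel.

    The minimum minor-allele count defaults to 1 so that a single-variety
    haplotype (such as the Hongkezhenuo landrace) remains callable.
    Returns one record per polymorphic position, ascending in miRNA
    coordinates; a monomorphic panel yields an empty list.
    """
    lo, hi = critical_region
    records = []
    for p in range(1, panel.length + 1):
        idx = panel.site_index(p)
        genotypes = {vid: seq[idx] for vid, seq in panel.entries.items()}
        alleles = Counter(genotypes.values())
        if len(alleles) < 2:
            continue
        ordered = alleles.most_common()
        major = ordered[0][0]
        minors = tuple(b for b, c in ordered[1:] if c >= min_minor_count)
        if not minors:
            continue
        records.append(
            SNPRecord(
                position=p,
                alleles=dict(alleles),
                major_allele=major,
                minor_alleles=minors,
                in_critical_region=lo <= p <= hi,
                genotypes=genotypes,
            )
        )
    return records


def count_critical_snps(
    records: list[SNPRecord], critical_region: tuple[int, int] = (2, 8)
) -> int:
    """Number of SNP positions inside the inclusive critical interval."""
    lo, hi = critical_region
    return sum(1 for r in records if lo <= r.position <= hi)


@dataclass(frozen=True)
class ImpactCall:
    """Recognition-impact call for one variety's site haplotype."""

    variety_id: str
    site_sequence: str
    total: float
    critical_score: float
    call: str  # RETAINED | POSSIBLY_LOST


def classify_impact(
    panel: GermplasmPanel,
    mirna: MatureMiRNA,
    params: ScoringParams | None = None,
) -> list[ImpactCall]:
    """Re-score every variety's site and call recognition impact.

    RETAINED iff the variant site still passes the acceptance rule under
    the configured scoring mode; otherwise POSSIBLY_LOST (the variant may
    escape miRNA-guided regulation).
    """
    params = params or ScoringParams()
    calls = []
    for vid, seq in panel.entries.items():
        score = score_duplex(mirna, seq, params)
        ok = accept_site(score, params).accepted
        calls.append(
            ImpactCall(
                variety_id=vid,
                site_sequence=seq,
                total=score.total,
                critical_score=score.critical_score,
                call="RETAINED" if ok else "POSSIBLY_LOST",
            )
        )
    return calls


def plot_logo(profile: PositionProfile, ax=None):
    """Draw a simple sequence logo: letters stacked to information content.

    Letter height at position p is f_b * IC_p bits (max 2), the standard
    logo scaling.  Returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(profile.counts), 2.2))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    for p in profile.frequencies.index:
        ic = profile.information_bits.loc[p]
        y = 0.0
        for b in sorted(_BASES, key=lambda b: profile.frequencies.loc[p, b]):
            h = profile.frequencies.loc[p, b] * ic
            if h <= 0:
                continue
            ax.text(
                p, y + h / 2, b, ha="center", va="center",
                fontsize=6 + 10 * h, color=colors[b], family="monospace",
            )
            y += h
    ax.set_xlim(0.5, len(profile.counts) + 0.5)
    ax.set_ylim(0, 2.05)
    ax.set_xlabel("miRNA position (5'->3')")
    ax.set_ylabel("bits")
    return ax
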