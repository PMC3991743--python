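"""Mapping of 5'-RACE clone ends onto a target site in miRNA coordinates.

RNA-ligase-mediated 5'-RACE captures the 5' ends of miRNA-guided cleavage
products.  Each clone contributes one transcript coordinate: the first base
of the 3' cleavage fragment.  Mapped into mature-miRNA coordinates
(antiparallel: transcript position ``site.end`` faces miRNA position 1),
the canonical AGO slicing point - between the bases paired to miRNA
nucleotides 10 and 11 - places the clone's first base opposite miRNA
position 10, so a clean RACE experiment has its modal position at 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .scan import TargetSite

__all__ = ["RaceClone", "CleavageSummary", "OFF_SITE", "map_clone", "summarize_cleavage"]

OFF_SITE = "OFF_SITE"


@dataclass(frozen=True)
class RaceClone:
    """One sequenced RACE clone: its transcript and 5'-end coordinate."""

    clone_id: str
    transcript_id: str
    five_prime_end: int  # 1-based transcript coordinate of the clone's first base


def map_clone(clone: RaceClone, site: TargetSite):
    """Map one clone 5' end to a miRNA position, or OFF_SITE.

    A clone whose 5' end lies within [site.start, site.end] maps to the
    miRNA position paired with that transcript base,
    ``p = site.end - five_prime_end + 1``; clones outside the site are
    OFF_SITE.  Within the site this is a bijection between transcript
    coordinates and miRNA positions 1..L.
    """
    if clone.transcript_id != site.transcript_id:
        raise ValueError(
            f"clone {clone.clone_id!r} is on transcript "
            f"{clone.transcript_id!r}, site is on {site.transcript_id!r}"
        )
    if site.start <= clone.five_prime_end <= site.end:
        return site.end - clone.five_prime_end + 1
    return OFF_SITE


@dataclass(frozen=True)
class CleavageSummary:
    """Cleavage-position histogram with terminated-mRNA ratios.

    ``counts``/``ratios`` are keyed by miRNA position; ratios are fractions
    of all clones (in-site ratios plus the off-site fraction sum to 1).
    The modal position is the in-site position with the highest count;
    ties break to the smallest position and are listed in ``tied_modes``.
    """

    counts: dict
    ratios: dict
    modal_position: int | None
    tied_modes: tuple
    off_site_count: int
    n_clones: int

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "position": p,
                "count": self.counts[p],
                "ratio": self.ratios[p],
                "is_modal": p == self.modal_position,
            }
            for p in sorted(self.counts)
        ]
        return pd.DataFrame(
            rows, columns=["position", "count", "ratio", "is_modal"]
        )


def summarize_cleavage(clones: list[RaceClone], site: TargetSite) -> CleavageSummary:
    """Histogram of clone 5' ends over miRNA positions, with ratios.

    Off-site clones are counted separately and excluded from the modal
    computation.  Raises on an empty clone list.
    """
    if not clones:
        raise ValueError("no RACE clones supplied")
    positions = [map_clone(c, site) for c in clones]
    in_site = Counter(p for p in positions if p != OFF_SITE)
    off = sum(1 for p in positions if p == OFF_SITE)
    n = len(clones)
    if in_site:
        best = max(in_site.values())
        tied = tuple(sorted(p for p, c in in_site.items() if c == best))
        modal = tied[0]
    else:
        tied = ()
        modal = None
    return CleavageSummary(
        counts=dict(sorted(in_site.items())),
        ratios={p: c / n for p, c in sorted(in_site.items())},
        modal_position=modal,
        tied_modes=tied,
        off_site_count=off,
        n_clones=n,
    )
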