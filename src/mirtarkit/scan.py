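"""Transcriptome-wide sliding-window search for accepted miRNA target sites.

Every window of miRNA length on the sense strand of each transcript is
scored with the duplex mismatch model and kept when the acceptance rule
passes.  Targets are mRNAs, so only the given strand is scanned.  The scan
is O(N*L) per transcript, which is ample at the scale of ORF/cDNA sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .duplex import (
    DuplexScore,
    MatureMiRNA,
    ScoringParams,
    accept_site,
    normalize_sequence,
    score_duplex,
)

__all__ = ["TargetSite", "scan_transcript", "scan_fasta", "sites_to_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSite:
    """An accepted miRNA-binding site on a transcript.

    ``start``/``end`` are 1-based inclusive transcript coordinates;
    ``site_sequence`` is the transcript substring read 5'->3'.
    """

    transcript_id: str
    start: int
    end: int
    site_sequence: str
    score: DuplexScore
    region_label: str = "unannotated"


def scan_transcript(
    mirna: MatureMiRNA,
    transcript: str,
    params: ScoringParams | None = None,
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """Score every window of miRNA length and return the accepted sites.

    Overlapping accepted windows are all reported, sorted by start.  A
    transcript shorter than the miRNA yields an empty list with a warning.
    """
    params = params or ScoringParams()
    seq = normalize_sequence(transcript)
    L = len(mirna)
    if len(seq) < L:
        logger.warning(
            "transcript %s (%d nt) shorter than miRNA (%d nt); no scan",
            transcript_id, len(seq), L,
        )
        return []
    sites = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        score = score_duplex(mirna, window, params)
        if accept_site(score, params).accepted:
            sites.append(
                TargetSite(
                    transcript_id=transcript_id,
                    start=off + 1,
                    end=off + L,
                    site_sequence=window,
                    score=score,
                )
            )
    return sites


def _label_region(site: TargetSite, annotations: pd.DataFrame) -> str:
    rows = annotations[annotations["transcript_id"] == site.transcript_id]
    for _, row in rows.iterrows():
        if int(row["start"]) <= site.start and site.end <= int(row["end"]):
            return str(row["region_label"])
    return "unannotated"


def scan_fasta(
    mirna: MatureMiRNA,
    records: list[tuple[str, str]],
    params: ScoringParams | None = None,
    annotations: pd.DataFrame | None = None,
) -> tuple[list[TargetSite], int]:
    """Scan multiple transcripts and optionally assign region labels.

    Parameters
    ----------
    records : list of (transcript_id, sequence)
        Parsed FASTA records; duplicate ids are rejected.
    annotations : DataFrame, optional
        Columns transcript_id, region_label, start, end (1-based
        inclusive); a site fully contained in an interval gets its label.

    Returns
    -------
    (sites, n_transcripts_with_site)
    """
    params = params or ScoringParams()
    ids = [rid for rid, _ in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dupes}")
    all_sites: list[TargetSite] = []
    hit_transcripts = set()
    for rid, seq in records:
        sites = scan_transcript(mirna, seq, params, transcript_id=rid)
        if annotations is not None and len(annotations):
            sites = [
                TargetSite(
                    s.transcript_id, s.start, s.end, s.site_sequence,
                    s.score, _label_region(s, annotations),
                )
                for s in sites
            ]
        if sites:
            hit_transcripts.add(rid)
        all_sites.extend(sites)
    return all_sites, len(hit_transcripts)


def sites_to_table(sites: list[TargetSite]) -> pd.DataFrame:
    """Flatten sites into the standard TSV-ready table."""
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "site_sequence": s.site_sequence,
                "total": s.score.total,
                "critical_score": s.score.critical_score,
                "mismatch_positions": ",".join(map(str, s.score.mismatch_positions)),
                "half_positions": ",".join(map(str, s.score.half_positions)),
                "region_label": s.region_label,
                "mode": s.score.mode,
            }
        )
    cols = [
        "transcript_id", "start", "end", "site_sequence", "total",
        "critical_score", "mismatch_positions", "half_positions",
        "region_label", "mode",
    ]
    return pd.DataFrame(rows, columns=cols)
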