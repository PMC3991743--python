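"""Overexpressor differential expression, set overlaps, and promoter motifs.

The experimental design emulated here is the classic two-line
overexpression comparison: for each gene construct, two independent
transgenic lines (each with biological replicates) are profiled against a
wild-type control, and a gene is called differentially expressed only when
the fold-change criterion holds in *both* lines - a simple guard against
line-specific (insertion-site) artefacts.  Calls across several
overexpressed genes are then intersected (Venn analysis) and cross-tabbed
against an external drought-responsiveness annotation to quantify
sign reversal (genes up in the overexpressor but down under drought, and
vice versa).

Promoter analysis is a generic exact IUPAC-pattern scan of upstream
sequences on both strands; the motifs (e.g. NAC recognition sequences) are
supplied by the user.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "ExpressionMatrix",
    "DECall",
    "MotifHit",
    "call_de",
    "venn_counts",
    "drought_crosstab",
    "category_crosstab",
    "scan_promoters",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample signal matrix with sample metadata.

    ``signals`` is a genes x samples DataFrame of positive reals;
    ``samples`` has one row per sample with columns sample, group
    (WT or OE), line, replicate.  Signals below ``floor`` are raised to it
    before any ratio is formed, preventing division blow-ups on
    background-level probes; the floor is recorded here and echoed in
    outputs.
    """

    signals: pd.DataFrame
    samples: pd.DataFrame
    floor: float = 1.0

    def __post_init__(self) -> None:
        required = {"sample", "group", "line", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        unknown = set(self.samples["sample"]) - set(self.signals.columns)
        if unknown:
            raise ValueError(f"samples absent from signal matrix: {sorted(unknown)}")
        groups = set(self.samples["group"])
        if "WT" not in groups:
            raise ValueError("design error: no WT samples")
        if "OE" not in groups:
            raise ValueError("design error: no OE samples")
        self.signals = self.signals.clip(lower=self.floor)

    def wt_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == "WT", "sample"])

    def oe_lines(self) -> dict[str, list[str]]:
        oe = self.samples[self.samples["group"] == "OE"]
        return {
            line: list(sub["sample"]) for line, sub in oe.groupby("line", sort=True)
        }


@dataclass(frozen=True)
class DECall:
    """Per-gene differential-expression call under the two-line rule."""

    gene_id: str
    ratios: dict  # line_id -> OE/WT ratio
    call: str  # UP | DOWN | NONE


def call_de(
    matrix: ExpressionMatrix,
    fold: float = 2.0,
    ratio_mode: str = "mean",
) -> list[DECall]:
    """Call UP/DOWN/NONE per gene under the every-line fold rule.

    UP iff the OE/WT ratio is >= ``fold`` in every line; DOWN iff <=
    1/``fold`` in every line; otherwise NONE (a change in a single line is
    insufficient).  Thresholds are inclusive.

    ratio_mode
        "mean" (default): ratio per line = mean of the line's replicates /
        mean of WT replicates.  "per_replicate" (stricter): every replicate
        of every line must individually satisfy the threshold against the
        WT mean; the reported ratio per line is its least extreme
        replicate ratio.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if ratio_mode not in ("mean", "per_replicate"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    wt_mean = matrix.signals[matrix.wt_samples()].mean(axis=1)
    lines = matrix.oe_lines()
    line_ratios = {}
    for line, cols in lines.items():
        if ratio_mode == "mean":
            line_ratios[line] = matrix.signals[cols].mean(axis=1) / wt_mean
        else:
            rep = matrix.signals[cols].div(wt_mean, axis=0)
            # least extreme replicate: closest to 1 in log space
            import numpy as np

            logr = np.log(rep)
            least = logr.abs().idxmin(axis=1)
            line_ratios[line] = pd.Series(
                [rep.at[g, least[g]] for g in rep.index], index=rep.index
            )
    calls = []
    for gene in matrix.signals.index:
        r = {line: float(line_ratios[line][gene]) for line in lines}
        if all(v >= fold for v in r.values()):
            verdict = "UP"
        elif all(v <= 1.0 / fold for v in r.values()):
            verdict = "DOWN"
        else:
            verdict = "NONE"
        calls.append(DECall(gene_id=str(gene), ratios=r, call=verdict))
    return calls


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for all non-empty combinations of named sets.

    For n named sets, every non-empty subset of names keys the count of
    elements belonging to exactly those sets (the Venn diagram regions).
    Region counts sum to the size of the union.
    """
    names = list(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = len(inside - outside)
    return regions


def drought_crosstab(
    calls_by_genotype: dict[str, list[DECall]],
    annotation: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cross-tab OE calls against drought response, per genotype.

    Genes absent from the annotation are treated as drought-NONE.  The
    reversal fraction per genotype is the share of called (UP or DOWN)
    genes whose drought response has the opposite sign:
    (OE-UP & drought-DOWN plus OE-DOWN & drought-UP) / called genes.

    Returns the long-format contingency table (genotype, oe_call,
    drought_response, count) and a genotype -> reversal-fraction dict.
    """
    rows = []
    reversal = {}
    for genotype, calls in calls_by_genotype.items():
        tab: dict[tuple[str, str], int] = {}
        n_called = 0
        n_rev = 0
        for c in calls:
            if c.call == "NONE":
                continue
            dr = annotation.get(c.gene_id, "NONE")
            tab[(c.call, dr)] = tab.get((c.call, dr), 0) + 1
            n_called += 1
            if (c.call, dr) in (("UP", "DOWN"), ("DOWN", "UP")):
                n_rev += 1
        for oe_call in ("UP", "DOWN"):
            for dr in ("UP", "DOWN", "NONE"):
                rows.append(
                    {
                        "genotype": genotype,
                        "oe_call": oe_call,
                        "drought_response": dr,
                        "count": tab.get((oe_call, dr), 0),
                    }
                )
        reversal[genotype] = n_rev / n_called if n_called else float("nan")
    table = pd.DataFrame(
        rows, columns=["genotype", "oe_call", "drought_response", "count"]
    )
    return table, reversal


def category_crosstab(
    calls: list[DECall], categories: dict[str, str]
) -> pd.DataFrame:
    """Counts of UP/DOWN calls per user-supplied functional category.

    A desk-scale stand-in for external functional-classification services:
    the user supplies any gene -> category table; uncategorised genes fall
    into 'unassigned'.  No enrichment statistics are computed.
    """
    rows = []
    for c in calls:
        if c.call == "NONE":
            continue
        rows.append(
            {"category": categories.get(c.gene_id, "unassigned"), "call": c.call}
        )
    if not rows:
        return pd.DataFrame(columns=["category", "UP", "DOWN"])
    df = pd.DataFrame(rows)
    out = df.pivot_table(
        index="category", columns="call", aggfunc="size", fill_value=0
    ).reset_index()
    for col in ("UP", "DOWN"):
        if col not in out:
            out[col] = 0
    return out[["category", "UP", "DOWN"]]


@dataclass(frozen=True)
class MotifHit:
    """One exact IUPAC motif match on a promoter sequence."""

    promoter_id: str
    motif_id: str
    start: int  # 1-based on the given (+) sequence
    strand: str  # '+' or '-'
    matched_sequence: str


_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        # "X" is in biopython's table but is not an IUPAC nucleotide code
        if ch == "X" or ch not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif")
        opts = ambiguous_dna_values[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def scan_promoters(
    promoters: list[tuple[str, str]],
    motifs: dict[str, str],
) -> list[MotifHit]:
    """All exact IUPAC matches of each motif on both strands.

    Promoters are (id, DNA sequence) pairs, typically 1 kb upstream of the
    start codon.  Overlapping matches are all reported.  Minus-strand hits
    report the 1-based start of the matched segment on the given sequence;
    the matched sequence is the reverse complement of that segment (the
    motif as read on the minus strand).
    """
    compiled = {mid: _iupac_regex(pat) for mid, pat in motifs.items()}
    hits = []
    for pid, seq in promoters:
        seq = seq.upper().replace("U", "T")
        for mid, rx in compiled.items():
            for m in _overlapping_finditer(rx, seq):
                hits.append(MotifHit(pid, mid, m[0] + 1, "+", m[1]))
            rc = _revcomp_dna(seq)
            L = len(seq)
            for m in _overlapping_finditer(rx, rc):
                # position of the match, mapped back onto the + sequence
                start_plus = L - (m[0] + len(m[1])) + 1
                hits.append(MotifHit(pid, mid, start_plus, "-", m[1]))
    hits.sort(key=lambda h: (h.promoter_id, h.start, h.motif_id, h.strand))
    return hits


def _overlapping_finditer(rx: re.Pattern, seq: str):
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return
        yield m.start(), m.group(0)
        pos = m.start() + 1
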