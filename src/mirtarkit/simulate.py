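"""Seeded generators for every input the analysis pipeline consumes.

Each generator plants known ground truth - target sites with prescribed
mismatch profiles, SNPs at prescribed miRNA positions and frequencies,
RACE clones with a dominant canonical cleavage point, expression matrices
with prescribed fold changes - and emits a machine-readable truth table so
recovery tests compare pipeline output to the planted truth rather than to
hard-coded numbers.

Defaults mirror the study design the package targets: a ~21-nt mature
miRNA, germplasm panels of 122-158 varieties, 24 RACE clones, and a
two-line / two-replicate overexpressor microarray design.

One integer seed drives one pseudo-random stream per generator, derived as
``default_rng([stream, seed])`` with fixed stream indices (transcriptome 0,
panel 1, RACE 2, expression 3), so adding a generator never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavage import RaceClone
from .duplex import (
    STANDARD_MIR164,
    MatureMiRNA,
    ScoringParams,
    reconstruct_site,
    score_duplex,
)
from .expression import ExpressionMatrix
from .conservation import GermplasmPanel
from .scan import TargetSite

__all__ = [
    "PlantedSite",
    "TranscriptomeSpec",
    "SNPSpec",
    "HaplotypeSpec",
    "PanelSpec",
    "RaceSpec",
    "ExpressionSpec",
    "SimSpec",
    "gen_transcriptome",
    "gen_panel",
    "gen_race_clones",
    "gen_expression",
]

_STREAMS = {"transcriptome": 0, "panel": 1, "race": 2, "expression": 3}
_BASES = np.array(list("ACGU"))


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[generator], seed])


def _random_rna(rng: np.random.Generator, length: int) -> str:
    # uniform base composition (25% each)
    return "".join(rng.choice(_BASES, size=length))


@dataclass(frozen=True)
class PlantedSite:
    """A site to plant: transcript, 1-based offset, and mismatch profile."""

    transcript_id: str
    offset: int
    full_mismatch_positions: frozenset = frozenset()
    half_positions: frozenset = frozenset()


@dataclass(frozen=True)
class TranscriptomeSpec:
    """Synthetic transcriptome: random backbones with planted sites.

    ``n_decoys`` extra transcripts each carry one planted decoy site with
    ``decoy_n_mismatches`` full mismatches (default 6, rejected by the
    four-mismatch rule).
    """

    n_transcripts: int = 6
    length: int = 1000
    planted_sites: tuple = ()
    n_decoys: int = 0
    decoy_n_mismatches: int = 6


def gen_transcriptome(
    spec: TranscriptomeSpec,
    seed: int,
    mirna: MatureMiRNA = STANDARD_MIR164,
    params: ScoringParams | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate transcripts with planted sites plus a truth table.

    Returns (records, truth) where truth has one row per planted site with
    its transcript, offset, and the score the scanner should report.
    """
    params = params or ScoringParams()
    rng = _rng(seed, "transcriptome")
    L = len(mirna)
    if spec.length < L:
        raise ValueError(f"transcript length {spec.length} < miRNA length {L}")
    by_transcript: dict[str, list[PlantedSite]] = {}
    for ps in spec.planted_sites:
        if ps.offset < 1 or ps.offset + L - 1 > spec.length:
            raise ValueError(
                f"planted site at offset {ps.offset} exceeds transcript "
                f"bounds 1..{spec.length}"
            )
        by_transcript.setdefault(ps.transcript_id, []).append(ps)
    records = []
    truth_rows = []
    ids = [f"tx{i+1:04d}" for i in range(spec.n_transcripts)]
    for tid in ids:
        seq = list(_random_rna(rng, spec.length))
        for ps in by_transcript.get(tid, []):
            site = reconstruct_site(
                mirna, ps.full_mismatch_positions, ps.half_positions, params
            )
            seq[ps.offset - 1 : ps.offset - 1 + L] = site
            score = score_duplex(mirna, site, params)
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "offset": ps.offset,
                    "total": score.total,
                    "critical_score": score.critical_score,
                    "is_decoy": False,
                }
            )
        records.append((tid, "".join(seq)))
    for d in range(spec.n_decoys):
        tid = f"decoy{d+1:04d}"
        seq = list(_random_rna(rng, spec.length))
        positions = frozenset(
            int(p) + 1
            for p in rng.choice(L, size=spec.decoy_n_mismatches, replace=False)
        )
        site = reconstruct_site(mirna, positions, frozenset(), params)
        offset = int(rng.integers(1, spec.length - L + 2))
        seq[offset - 1 : offset - 1 + L] = site
        score = score_duplex(mirna, site, params)
        truth_rows.append(
            {
                "transcript_id": tid,
                "offset": offset,
                "total": score.total,
                "critical_score": score.critical_score,
                "is_decoy": True,
            }
        )
        records.append((tid, "".join(seq)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "offset", "total", "critical_score", "is_decoy"],
    )
    return records, truth


@dataclass(frozen=True)
class SNPSpec:
    """A biallelic SNP to plant: miRNA position, site-strand minor allele,
    and minor-allele frequency."""

    position: int
    minor_allele: str
    minor_freq: float


@dataclass(frozen=True)
class HaplotypeSpec:
    """A named variety carrying prescribed substitutions
    (miRNA position -> site-strand allele)."""

    variety_id: str
    substitutions: tuple  # of (position, allele)


@dataclass(frozen=True)
class PanelSpec:
    """Germplasm panel: reference site profile, planted SNPs, haplotypes.

    ``n_varieties`` is the total panel size including named haplotype
    carriers; default 135 valid sequences, in the range obtained from a
    158-variety mini-core germplasm collection.
    """

    gene_id: str = "gene"
    n_varieties: int = 135
    reference_full_mismatches: frozenset = frozenset()
    reference_half_positions: frozenset = frozenset()
    snps: tuple = ()
    haplotypes: tuple = ()


def gen_panel(
    spec: PanelSpec,
    seed: int,
    mirna: MatureMiRNA = STANDARD_MIR164,
    params: ScoringParams | None = None,
) -> tuple[GermplasmPanel, pd.DataFrame]:
    """Generate a variety panel with planted SNPs plus a truth table.

    Each SNP's carrier count is drawn binomially at the planted frequency
    and clipped to [1, n-1] so the position is guaranteed polymorphic.
    Named haplotype varieties are added on top of the regular varieties
    within the stated panel size.
    """
    params = params or ScoringParams()
    rng = _rng(seed, "panel")
    if spec.n_varieties < 1 + len(spec.haplotypes):
        raise ValueError("panel too small for the requested haplotypes")
    reference = reconstruct_site(
        mirna, spec.reference_full_mismatches, spec.reference_half_positions, params
    )
    L = len(mirna)
    n_regular = spec.n_varieties - len(spec.haplotypes)
    entries = {f"var{i+1:04d}": list(reference) for i in range(n_regular)}
    truth_rows = []
    for snp in spec.snps:
        idx = L - snp.position
        ref_allele = reference[idx]
        if snp.minor_allele == ref_allele:
            raise ValueError(
                f"planted allele {snp.minor_allele!r} equals the reference "
                f"base at miRNA position {snp.position}"
            )
        n_carriers = int(
            np.clip(rng.binomial(n_regular, snp.minor_freq), 1, n_regular - 1)
        )
        carriers = rng.choice(n_regular, size=n_carriers, replace=False)
        vids = list(entries)
        for c in carriers:
            entries[vids[c]][idx] = snp.minor_allele
        truth_rows.append(
            {
                "position": snp.position,
                "ref_allele": ref_allele,
                "alt_allele": snp.minor_allele,
                "planted_carriers": n_carriers,
                "source": "snp",
            }
        )
    for hap in spec.haplotypes:
        site = list(reference)
        for pos, allele in hap.substitutions:
            site[L - pos] = allele
            truth_rows.append(
                {
                    "position": pos,
                    "ref_allele": reference[L - pos],
                    "alt_allele": allele,
                    "planted_carriers": 1,
                    "source": hap.variety_id,
                }
            )
        entries[hap.variety_id] = site
    panel = GermplasmPanel(
        gene_id=spec.gene_id,
        reference_site=reference,
        entries={vid: "".join(s) for vid, s in entries.items()},
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["position", "ref_allele", "alt_allele", "planted_carriers", "source"],
    )
    return panel, truth


@dataclass(frozen=True)
class RaceSpec:
    """RACE clone set against a planted perfect-complement site.

    ``purity`` is the fraction of clones placed exactly at the canonical
    slicing product start (the base paired to miRNA nucleotide 10);
    the remainder fall uniformly within the site.  Defaults emulate a
    24-clone sequencing run.
    """

    n_clones: int = 24
    purity: float = 0.8
    transcript_id: str = "target_tx"
    site_offset: int = 100
    transcript_length: int = 500


def gen_race_clones(
    spec: RaceSpec,
    seed: int,
    mirna: MatureMiRNA = STANDARD_MIR164,
) -> tuple[list[RaceClone], TargetSite, pd.DataFrame]:
    """Generate clones, the planted site, and per-position truth counts.

    The canonical clone count is ``round(purity * n_clones)`` exactly; the
    remaining clones draw uniform in-site positions.
    """
    if not 0.0 <= spec.purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    rng = _rng(seed, "race")
    L = len(mirna)
    site_seq = reconstruct_site(mirna)
    start = spec.site_offset
    end = start + L - 1
    if start < 1 or end > spec.transcript_length:
        raise ValueError("planted site exceeds transcript bounds")
    site = TargetSite(
        transcript_id=spec.transcript_id,
        start=start,
        end=end,
        site_sequence=site_seq,
        score=score_duplex(mirna, site_seq),
    )
    canonical_coord = end - 9  # base paired to miRNA nucleotide 10
    n_canon = int(round(spec.purity * spec.n_clones))
    coords = [canonical_coord] * n_canon + [
        int(c) for c in rng.integers(start, end + 1, size=spec.n_clones - n_canon)
    ]
    clones = [
        RaceClone(f"clone{i+1:03d}", spec.transcript_id, c)
        for i, c in enumerate(coords)
    ]
    positions = [end - c + 1 for c in coords]
    counts = pd.Series(positions).value_counts().sort_index()
    truth = pd.DataFrame(
        {"position": counts.index, "count": counts.values}
    )
    return clones, site, truth


@dataclass(frozen=True)
class ExpressionSpec:
    """Multi-genotype overexpressor expression design with planted truth.

    Per genotype: two independent OE lines, each with ``n_replicates``
    biological replicates, against a shared WT with ``n_replicates``
    replicates.  ``n_common_up``/``n_common_down`` genes are planted as
    changed in every genotype; ``n_up``/``n_down`` more per genotype are
    genotype-specific.  Lognormal multiplicative noise with log-scale sigma
    ``sigma``; planted DE genes get a drought annotation of the opposite
    sign with probability ``reversal_prob`` (else NONE).
    """

    n_genes: int = 2000
    genotypes: tuple = ("OE1", "OE2", "OE3", "OE4")
    n_up: int = 50
    n_down: int = 80
    n_common_up: int = 0
    n_common_down: int = 0
    fold: float = 4.0
    sigma: float = 0.1
    reversal_prob: float = 0.8
    n_replicates: int = 2
    baseline_mean: float = 100.0


def gen_expression(
    spec: ExpressionSpec, seed: int
) -> tuple[dict[str, ExpressionMatrix], dict[str, str], pd.DataFrame]:
    """Generate per-genotype expression matrices, a drought annotation,
    and a truth table of planted calls.

    Planted direction is global per gene (a gene common or specific to any
    genotype is always planted in the same direction), so a single drought
    annotation is coherent across genotypes.
    """
    rng = _rng(seed, "expression")
    genes = [f"g{i+1:05d}" for i in range(spec.n_genes)]
    need = (
        spec.n_common_up
        + spec.n_common_down
        + len(spec.genotypes) * (spec.n_up + spec.n_down)
    )
    if need > spec.n_genes:
        raise ValueError("planted sets exceed the number of genes")
    perm = rng.permutation(spec.n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        sel = [genes[i] for i in perm[cursor : cursor + k]]
        cursor += k
        return sel

    common_up = take(spec.n_common_up)
    common_down = take(spec.n_common_down)
    planted: dict[str, dict[str, str]] = {g: {} for g in spec.genotypes}
    truth_rows = []
    for gt in spec.genotypes:
        ups = common_up + take(spec.n_up)
        downs = common_down + take(spec.n_down)
        for g in ups:
            planted[gt][g] = "UP"
        for g in downs:
            planted[gt][g] = "DOWN"
        truth_rows.extend(
            {"genotype": gt, "gene_id": g, "planted_call": c}
            for g, c in planted[gt].items()
        )
    baseline = spec.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=spec.n_genes))
    matrices = {}
    for gt in spec.genotypes:
        sample_rows = []
        data = {}
        for rep in range(1, spec.n_replicates + 1):
            name = f"{gt}_WT_r{rep}"
            data[name] = baseline * np.exp(rng.normal(0.0, spec.sigma, spec.n_genes))
            sample_rows.append(
                {"sample": name, "group": "WT", "line": "WT", "replicate": rep}
            )
        foldvec = np.ones(spec.n_genes)
        for i, g in enumerate(genes):
            call = planted[gt].get(g)
            if call == "UP":
                foldvec[i] = spec.fold
            elif call == "DOWN":
                foldvec[i] = 1.0 / spec.fold
        for line in ("L1", "L2"):
            for rep in range(1, spec.n_replicates + 1):
                name = f"{gt}_{line}_r{rep}"
                data[name] = (
                    baseline
                    * foldvec
                    * np.exp(rng.normal(0.0, spec.sigma, spec.n_genes))
                )
                sample_rows.append(
                    {"sample": name, "group": "OE", "line": line, "replicate": rep}
                )
        matrices[gt] = ExpressionMatrix(
            signals=pd.DataFrame(data, index=genes),
            samples=pd.DataFrame(sample_rows),
        )
    drought: dict[str, str] = {}
    directions = {g: c for gt in spec.genotypes for g, c in planted[gt].items()}
    for g in genes:
        call = directions.get(g)
        if call and rng.random() < spec.reversal_prob:
            drought[g] = "DOWN" if call == "UP" else "UP"
        else:
            drought[g] = "NONE"
    truth = pd.DataFrame(truth_rows, columns=["genotype", "gene_id", "planted_call"])
    return matrices, drought, truth


@dataclass(frozen=True)
class SimSpec:
    """Top-level simulation spec: one seed plus one sub-spec per generator."""

    seed: int = 0
    transcriptome: TranscriptomeSpec = field(default_factory=TranscriptomeSpec)
    panel: PanelSpec = field(default_factory=PanelSpec)
    race: RaceSpec = field(default_factory=RaceSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
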