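"""Pairing model and mismatch scoring for plant miRNA-target duplexes.

Plant miRNAs recognise their mRNA targets through near-perfect antiparallel
base pairing.  The scoring model used throughout this package counts one
penalty unit per non-complementary juxtaposition, with a configurable class
of "wobble" pairs counted as half a mismatch (G:U by default).  A candidate
site is accepted when the total score does not exceed a cut-off (default
4.0) and the score restricted to the critical recognition region of the
miRNA (positions 2-8 from the 5' end) stays below 1.0, i.e. at most one
wobble and no full mismatch in the region that nucleates recognition and
guides cleavage.

All positions are 1-based coordinates on the mature miRNA counted from its
5' end.  The miRNA pairs antiparallel to the site, so miRNA position ``i``
faces site position ``L - i + 1`` when the site is read 5'->3' on the mRNA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "AlphabetError",
    "DuplexLengthError",
    "MatureMiRNA",
    "STANDARD_MIR164",
    "PairClass",
    "ScoringParams",
    "DuplexScore",
    "AcceptanceResult",
    "normalize_sequence",
    "reverse_complement",
    "pair_class",
    "score_duplex",
    "accept_site",
    "reconstruct_site",
]

RNA_BASES = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class AlphabetError(ValueError):
    """A sequence contains a character outside the unambiguous RNA alphabet."""


class DuplexLengthError(ValueError):
    """miRNA and site lengths differ, so no duplex can be formed."""


def normalize_sequence(raw: str) -> str:
    """Normalise nucleotide text to the uppercase unambiguous RNA alphabet.

    Lowercase is folded to uppercase and T is replaced by U.  IUPAC
    ambiguity codes (N, R, Y, ...) and any other character are rejected.

    Parameters
    ----------
    raw : str
        Non-empty nucleotide text in DNA or RNA alphabet.

    Returns
    -------
    str
        The sequence over {A, C, G, U}.

    Raises
    ------
    AlphabetError
        If the text is empty or contains a non-ACGTU character; the message
        names the 1-based offending position.
    """
    if not raw:
        raise AlphabetError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _COMPLEMENT:
            raise AlphabetError(
                f"non-nucleotide character {ch!r} at position {pos}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalised RNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3', in the RNA alphabet.

    The mature sequence is the coordinate origin for every position
    reported by this package: position 1 is the miRNA 5' end.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 15:
            raise ValueError(
                f"mature miRNA {self.id!r} is {len(self.sequence)} nt; "
                "a mature plant miRNA is expected to be >= 15 nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based miRNA position."""
        return self.sequence[position - 1]


#: The mature miR164 sequence shared by most plant family members, used as
#: the default guide in examples and simulations.
STANDARD_MIR164 = MatureMiRNA("miR164", "UGGAGAAGCAGGGCACGUGCA")


class PairClass(enum.Enum):
    """Classification of one miRNA-base / site-base juxtaposition."""

    COMPLEMENT = "complement"
    HALF_PENALTY = "half_penalty"
    MISMATCH = "mismatch"


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the mismatch-scoring and site-acceptance rule.

    Attributes
    ----------
    half_penalty_pairs : frozenset of (base, base)
        Unordered base pairs scored as 0.5 instead of 1.0.  Default is the
        standard G:U wobble; ``literal_paper`` mode uses U:U instead, the
        variant sometimes printed in the plant-miRNA literature.
    max_total : float
        Acceptance cut-off on the total score (default 4.0).
    total_inclusive : bool
        If True (default), a site scoring exactly ``max_total`` is accepted.
    critical_region : (int, int)
        Inclusive miRNA-position interval in which mismatches are barely
        tolerated; default (2, 8).
    critical_max : float
        Bound on the score restricted to the critical region (default 1.0).
    critical_strict : bool
        If True (default), the critical score must be strictly below
        ``critical_max`` (a single wobble passes, a full mismatch fails).
    mode : str
        Label recorded in outputs ("standard" or "literal_paper").
    """

    half_penalty_pairs: frozenset = frozenset({("G", "U")})
    max_total: float = 4.0
    total_inclusive: bool = True
    critical_region: tuple[int, int] = (2, 8)
    critical_max: float = 1.0
    critical_strict: bool = True
    mode: str = "standard"

    def __post_init__(self) -> None:
        pairs = frozenset(_canonical_pair(*p) for p in self.half_penalty_pairs)
        object.__setattr__(self, "half_penalty_pairs", pairs)
        lo, hi = self.critical_region
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid critical region {self.critical_region}")
        if self.max_total < 0:
            raise ValueError("max_total must be >= 0")

    @classmethod
    def standard(cls, **kwargs) -> "ScoringParams":
        """G:U-wobble half penalty (the field-standard reading)."""
        return cls(mode="standard", **kwargs)

    @classmethod
    def literal_paper(cls, **kwargs) -> "ScoringParams":
        """U:U half penalty, as printed verbatim in some descriptions."""
        kwargs.setdefault("half_penalty_pairs", frozenset({("U", "U")}))
        return cls(mode="literal_paper", **kwargs)

    def with_overrides(self, **kwargs) -> "ScoringParams":
        return replace(self, **kwargs)


def pair_class(mirna_base: str, target_base: str, params: ScoringParams) -> PairClass:
    """Classify one juxtaposition of a miRNA base against a site base.

    Watson-Crick pairs are complementary; pairs in the configured
    half-penalty set score 0.5; everything else is a full mismatch.  The
    half-penalty membership test is symmetric in the two bases.
    """
    if mirna_base not in _COMPLEMENT or target_base not in _COMPLEMENT:
        raise AlphabetError(
            f"bases must be A/C/G/U, got {mirna_base!r}:{target_base!r}"
        )
    if _COMPLEMENT[mirna_base] == target_base:
        return PairClass.COMPLEMENT
    if _canonical_pair(mirna_base, target_base) in params.half_penalty_pairs:
        return PairClass.HALF_PENALTY
    return PairClass.MISMATCH


_PENALTY = {
    PairClass.COMPLEMENT: 0.0,
    PairClass.HALF_PENALTY: 0.5,
    PairClass.MISMATCH: 1.0,
}


@dataclass(frozen=True)
class DuplexScore:
    """Per-position classification and mismatch score of one duplex.

    ``per_position[i-1]`` is the class at miRNA position ``i``; ``total``
    is the sum of penalties in half-unit steps, ``critical_score`` the same
    sum restricted to the critical region.
    """

    per_position: tuple
    total: float
    critical_score: float
    mismatch_positions: tuple
    half_positions: tuple
    mode: str = "standard"

    @property
    def length(self) -> int:
        return len(self.per_position)


def score_duplex(mirna: MatureMiRNA, site: str, params: ScoringParams | None = None) -> DuplexScore:
    """Score an antiparallel duplex between a miRNA and a candidate site.

    The site is read 5'->3' on the mRNA and must have the miRNA's length;
    miRNA position ``i`` is juxtaposed with site position ``L - i + 1``.
    The score is a pure per-position sum: 1 per mismatch, 0.5 per
    half-penalty (wobble) pair.

    Raises
    ------
    DuplexLengthError
        If the site length differs from the miRNA length.
    """
    params = params or ScoringParams()
    site = normalize_sequence(site)
    L = len(mirna)
    if len(site) != L:
        raise DuplexLengthError(
            f"site length {len(site)} != miRNA length {L}"
        )
    lo, hi = params.critical_region
    classes = []
    mismatches: list[int] = []
    halves: list[int] = []
    total = 0.0
    critical = 0.0
    for i in range(1, L + 1):
        cls = pair_class(mirna.base(i), site[L - i], params)
        classes.append(cls)
        pen = _PENALTY[cls]
        total += pen
        if lo <= i <= hi:
            critical += pen
        if cls is PairClass.MISMATCH:
            mismatches.append(i)
        elif cls is PairClass.HALF_PENALTY:
            halves.append(i)
    return DuplexScore(
        per_position=tuple(classes),
        total=total,
        critical_score=critical,
        mismatch_positions=tuple(mismatches),
        half_positions=tuple(halves),
        mode=params.mode,
    )


@dataclass(frozen=True)
class AcceptanceResult:
    """Outcome of the site-acceptance rule with the failed rule named."""

    accepted: bool
    reason: str  # "ok", "total-cutoff", or "critical-region"


def accept_site(score: DuplexScore, params: ScoringParams | None = None) -> AcceptanceResult:
    """Apply the acceptance rule to a computed duplex score.

    Accepted iff the total score is within the cut-off (<= 4.0 by default)
    and the critical-region score is below the critical bound (< 1.0 by
    default, so one wobble is tolerated but a full mismatch is not).  When
    both rules fail the critical-region rule is reported, as it is the
    biologically decisive one.
    """
    params = params or ScoringParams()
    total_ok = (
        score.total <= params.max_total
        if params.total_inclusive
        else score.total < params.max_total
    )
    critical_ok = (
        score.critical_score < params.critical_max
        if params.critical_strict
        else score.critical_score <= params.critical_max
    )
    if not critical_ok:
        return AcceptanceResult(False, "critical-region")
    if not total_ok:
        return AcceptanceResult(False, "total-cutoff")
    return AcceptanceResult(True, "ok")


def _mismatch_base_for(mirna_base: str, params: ScoringParams) -> str:
    # first base in fixed order A,C,G,U that is neither complementary nor
    # in the half-penalty set for this miRNA base
    for b in RNA_BASES:
        if _COMPLEMENT[mirna_base] == b:
            continue
        if _canonical_pair(mirna_base, b) in params.half_penalty_pairs:
            continue
        return b
    raise ValueError(f"no full-mismatch base exists opposite {mirna_base!r}")


def _half_base_for(mirna_base: str, params: ScoringParams) -> str:
    # first base in fixed order A,C,G,U forming a half-penalty pair
    for b in RNA_BASES:
        if _canonical_pair(mirna_base, b) in params.half_penalty_pairs:
            return b
    raise ValueError(
        f"no half-penalty partner exists for base {mirna_base!r} under "
        f"half-penalty set {sorted(params.half_penalty_pairs)}"
    )


def reconstruct_site(
    mirna: MatureMiRNA,
    full_mismatch_positions: set[int] | frozenset[int] = frozenset(),
    half_positions: set[int] | frozenset[int] = frozenset(),
    params: ScoringParams | None = None,
) -> str:
    """Build a site with prescribed mismatch classes at given miRNA positions.

    Starts from the exact reverse complement of the miRNA and substitutes,
    at each requested miRNA position, a deterministic base: for a full
    mismatch the first base in fixed order (A, C, G, U) that is neither
    complementary nor in the half-penalty set; for a half penalty the first
    base in that order forming a half-penalty pair.  The result scores
    exactly ``len(full) + 0.5 * len(half)`` against the miRNA.

    This is how worked examples with printed mismatch positions (e.g. the
    rice OMTN sites) are rebuilt when the genomic sequence is not at hand.
    """
    params = params or ScoringParams()
    full = frozenset(full_mismatch_positions)
    half = frozenset(half_positions)
    if full & half:
        raise ValueError(
            f"overlapping position sets: {sorted(full & half)}"
        )
    L = len(mirna)
    for p in full | half:
        if not 1 <= p <= L:
            raise ValueError(f"position {p} outside miRNA coordinates 1..{L}")
    site = list(reverse_complement(mirna.sequence))
    for p in full:
        site[L - p] = _mismatch_base_for(mirna.base(p), params)
    for p in half:
        site[L - p] = _half_base_for(mirna.base(p), params)
    return "".join(site)
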