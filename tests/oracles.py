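"""Independent brute-force re-implementations used as test oracles.

These deliberately use a different formulation (precomputed 16-entry pair
penalty tables, explicit window enumeration) from the package code so that
agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def penalty_table(half_pairs: set[frozenset] | None = None) -> dict:
    """Penalty for every ordered (miRNA base, site base) pair."""
    half = half_pairs if half_pairs is not None else {frozenset({"G", "U"})}
    table = {}
    for a, b in itertools.product("ACGU", repeat=2):
        if (a, b) in _WC:
            table[(a, b)] = 0.0
        elif frozenset({a, b}) in half:
            table[(a, b)] = 0.5
        else:
            table[(a, b)] = 1.0
    return table


def naive_score(mirna_seq: str, site: str, half_pairs=None):
    """(total, critical, mismatch_positions, half_positions) by table lookup.

    miRNA position i pairs the site base counted from the site 3' end.
    """
    table = penalty_table(half_pairs)
    total = 0.0
    critical = 0.0
    mismatches, halves = [], []
    rev_site = site[::-1]
    for i, (mb, sb) in enumerate(zip(mirna_seq, rev_site), start=1):
        pen = table[(mb, sb)]
        total += pen
        if 2 <= i <= 8:
            critical += pen
        if pen == 1.0:
            mismatches.append(i)
        elif pen == 0.5:
            halves.append(i)
    return total, critical, tuple(mismatches), tuple(halves)


def naive_accept(total: float, critical: float) -> bool:
    return total <= 4.0 and critical < 1.0


def naive_scan(mirna_seq: str, transcript: str, half_pairs=None):
    """Enumerate every window; return [(start, total, critical)] accepted."""
    L = len(mirna_seq)
    out = []
    for start in range(1, len(transcript) - L + 2):
        window = transcript[start - 1 : start - 1 + L]
        total, critical, _, _ = naive_score(mirna_seq, window, half_pairs)
        if naive_accept(total, critical):
            out.append((start, total, critical))
    return out
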