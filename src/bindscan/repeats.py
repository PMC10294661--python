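"""Degenerate-consensus scanning and de novo direct-repeat discovery.

Direct repeats — same-strand, same-orientation copies of a short unit — are a
common architecture for bacterial transcription-factor operators.  This module
scans a sequence for matches to a degenerate IUPAC consensus (``X`` is accepted
as a synonym for ``N``), discovers repeat families de novo in short regulatory
regions, and derives a degenerate consensus from a set of aligned hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_SETS",
    "RepeatHit",
    "RepeatFamily",
    "scan_consensus",
    "find_direct_repeats",
    "consensus_of",
    "shannon_entropy",
]

IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "X": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items() if k != "X"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNX", "TGCAYRSWMKVHDBNX")


@dataclass
class RepeatHit:
    """One match of a consensus within a sequence (0-based, same strand)."""

    start: int
    length: int
    matched_seq: str
    mismatches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.matched_seq) != self.length:
            raise ValueError("matched_seq length disagrees with length field")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class RepeatFamily:
    """Two or more same-strand repeat copies and their derived consensus."""

    members: list[RepeatHit]
    unit_length: int
    consensus: str
    spacings: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a repeat family needs at least 2 members")
        if not self.spacings:
            starts = [m.start for m in self.members]
            self.spacings = [b - a for a, b in zip(starts, starts[1:])]


def _validate_consensus(consensus: str) -> str:
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"invalid IUPAC codes in consensus: {sorted(bad)}")
    if not consensus:
        raise ValueError("consensus must be non-empty")
    return consensus


def _match_window(window: str, consensus: str, max_mismatch: int) -> int | None:
    """Mismatch count if the window matches, else None.

    Fully degenerate columns (N/X) always match.  Partially degenerate columns
    (R, Y, ...) must be satisfied outright.  Only single-base columns count
    toward the mismatch budget.
    """
    mismatches = 0
    for base, code in zip(window, consensus):
        allowed = IUPAC_SETS[code]
        if len(allowed) == 4:
            continue
        if base in allowed:
            continue
        if len(allowed) == 1:
            mismatches += 1
            if mismatches > max_mismatch:
                return None
        else:
            return None
    return mismatches


def scan_consensus(
    seq: str,
    consensus: str,
    max_mismatch: int = 0,
    both_strands: bool = False,
) -> list[RepeatHit]:
    """All matches of a degenerate consensus, ordered by start position.

    ``X`` in the consensus is read as ``N`` (any base).  With
    ``both_strands=True`` the reverse complement of the consensus is also
    scanned and hits are reported on the input coordinates with strand '-'.
    """
    seq = seq.upper()
    consensus = _validate_consensus(consensus)
    k = len(consensus)
    hits: list[RepeatHit] = []
    queries = [(consensus, "+")]
    if both_strands:
        rc = consensus.translate(_COMPLEMENT)[::-1]
        queries.append((rc, "-"))
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        for query, strand in queries:
            mm = _match_window(window, query, max_mismatch)
            if mm is not None:
                hits.append(RepeatHit(i, k, window, mm, strand))
                break
    return hits


def shannon_entropy(unit: str) -> float:
    """Per-base Shannon entropy (bits) of a sequence's base composition."""
    n = len(unit)
    ent = 0.0
    for b in "ACGT":
        p = unit.count(b) / n
        if p > 0:
            ent -= p * math.log2(p)
    return ent


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_direct_repeats(
    seq: str,
    min_len: int = 8,
    max_len: int = 14,
    min_copies: int = 2,
    max_mismatch: int = 1,
    max_span: int = 100,
    entropy_min: float = 1.0,
) -> list[RepeatFamily]:
    """Discover direct-repeat families de novo in a short sequence.

    For every unit length in [min_len, max_len], same-strand occurrences are
    grouped greedily left to right: a candidate joins a family if it starts
    within ``max_span`` of the previous member, does not overlap it, and its
    Hamming distance to every current member is at most ``max_mismatch``.
    Units with base-composition entropy below ``entropy_min`` bits/base are
    suppressed as low-complexity.  Families that are subsets of another family
    of the same unit length, or whose every member interval is contained in a
    member of a longer-unit family, are dropped as redundant.  Output order is
    deterministic: unit length descending, then first start ascending.

    Intended for regulatory regions; sequences above 10 kb are rejected.
    """
    seq = seq.upper()
    if len(seq) > 10_000:
        raise ValueError("find_direct_repeats is intended for regions <= 10 kb")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    L = len(seq)

    families: list[list[int]] = []  # (unit_length, member starts) via parallel list
    family_lengths: list[int] = []
    for k in range(max_len, min_len - 1, -1):
        candidates: list[tuple[int, ...]] = []
        for anchor in range(0, L - k + 1):
            unit = seq[anchor : anchor + k]
            if shannon_entropy(unit) < entropy_min:
                continue
            members = [anchor]
            units = [unit]
            j = anchor + k
            while j <= L - k and j - members[-1] <= max_span:
                cand = seq[j : j + k]
                if (
                    shannon_entropy(cand) >= entropy_min
                    and all(_hamming(cand, u) <= max_mismatch for u in units)
                ):
                    members.append(j)
                    units.append(cand)
                    j += k
                else:
                    j += 1
            if len(members) >= min_copies:
                candidates.append(tuple(members))
        # drop same-length families whose member set is a subset of another
        kept: list[tuple[int, ...]] = []
        for mem in sorted(set(candidates), key=lambda m: (-len(m), m[0])):
            ms = set(mem)
            if any(ms <= set(other) for other in kept):
                continue
            kept.append(mem)
        for mem in kept:
            families.append(list(mem))
            family_lengths.append(k)

    # cross-length redundancy: every member interval contained in a member of a
    # longer-unit family
    def contained(mem: list[int], k: int, other: list[int], ok: int) -> bool:
        return all(
            any(os <= s and s + k <= os + ok for os in other) for s in mem
        )

    final: list[RepeatFamily] = []
    order = sorted(range(len(families)), key=lambda i: (-family_lengths[i], families[i][0]))
    for idx in order:
        mem, k = families[idx], family_lengths[idx]
        redundant = any(
            family_lengths[j] > k and contained(mem, k, families[j], family_lengths[j])
            for j in order
            if j != idx
        )
        if redundant:
            continue
        hits = [RepeatHit(s, k, seq[s : s + k], 0) for s in mem]
        final.append(RepeatFamily(hits, k, consensus_of(hits)))
    return final


def consensus_of(
    hits: list[RepeatHit], policy: str = "minimal-iupac", majority: float = 0.75
) -> str:
    """Column-wise degenerate consensus of equal-length hits.

    ``minimal-iupac`` emits the smallest IUPAC code covering the observed
    bases.  ``strict-majority-else-X`` emits a base only when its column
    frequency reaches ``majority`` (default 0.75) and ``X`` otherwise — the
    notation used when a consensus is written with X placeholders.
    """
    if len(hits) < 2:
        raise ValueError("consensus requires at least 2 hits")
    lengths = {len(h.matched_seq) for h in hits}
    if len(lengths) != 1:
        raise ValueError("all hits must have equal length")
    if policy not in ("minimal-iupac", "strict-majority-else-X"):
        raise ValueError(f"unknown consensus policy {policy!r}")

    out = []
    n = len(hits)
    for col in zip(*(h.matched_seq for h in hits)):
        observed = frozenset(col)
        if len(observed) == 1:
            out.append(next(iter(observed)))
            continue
        if policy == "minimal-iupac":
            out.append(_SET_TO_CODE[observed])
        else:
            best = max("ACGT", key=lambda b: col.count(b))
            out.append(best if col.count(best) / n >= majority else "X")
    return "".join(out)
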