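"""Canonical monomer representation under rotation and reverse complement.

A satellite monomer is rotationally arbitrary: any rotation of the unit, on
either strand, describes the same tandem array.  To compare and cluster
monomers we map every unit to a canonical representative — the
lexicographically smallest string (A<C<G<T) among all rotations of the
sequence and of its reverse complement — and measure identity between units
as the best global-alignment identity over all relative rotations and
strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_MONOMER = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-paired)."""
    return seq.translate(_COMP)[::-1]


def least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm).

    Linear scan over the doubled string; deterministic, returns the smallest
    such index when several rotations are equal.
    """
    if not s:
        raise ValueError("empty input")
    ss = s + s
    n = len(ss)
    f = [-1] * n  # failure function of the least rotation candidate
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_monomer(seq: str) -> str:
    """Canonical representative of ``seq`` under rotation and strand.

    Returns the lexicographically smallest string among all rotations of
    ``seq`` and all rotations of its reverse complement (alphabet A<C<G<T).
    Idempotent; output length equals input length.

    Raises ``ValueError`` on empty input or characters outside {A,C,G,T}.
    """
    if not seq:
        raise ValueError("empty input")
    s = seq.upper()
    if not _VALID_MONOMER.issuperset(s):
        bad = sorted(set(s) - _VALID_MONOMER)
        raise ValueError(f"non-ACGT characters in monomer: {bad}")
    k = least_rotation(s)
    fwd = s[k:] + s[:k]
    rc = reverse_complement(s)
    k2 = least_rotation(rc)
    rev = rc[k2:] + rc[:k2]
    return min(fwd, rev)


def _identity_from_distance(dist: int, la: int, lb: int) -> float:
    # columns taken as the minimal possible alignment length max(la, lb);
    # indels therefore always count against identity
    cols = max(la, lb)
    return (cols - dist) / cols if cols else 0.0


def best_orientation(a: str, b: str) -> tuple[float, str, int, str]:
    """Best-scoring orientation of ``b`` against ``a``.

    Considers every rotation of ``b`` and of its reverse complement and
    returns ``(identity, oriented_b, rotation_offset, strand)`` where
    ``oriented_b`` is the rotation of ``b`` (or of its reverse complement,
    ``strand == "-"``) with the highest global-alignment identity to ``a``.
    Ties resolve to the forward strand, then the smallest rotation offset.
    """
    if not a or not b:
        raise ValueError("empty input")
    a = a.upper()
    b = b.upper()
    la = len(a)
    best = (-1.0, "", 0, "+")
    for strand, bs in (("+", b), ("-", reverse_complement(b))):
        lb = len(bs)
        doubled = bs + bs
        for off in range(lb):
            rot = doubled[off : off + lb]
            d = edlib.align(rot, a, mode="NW", task="distance")["editDistance"]
            ident = _identity_from_distance(d, la, lb)
            if ident > best[0] + 1e-12:
                best = (ident, rot, off, strand)
    return best


def rotational_identity(a: str, b: str) -> float:
    """Maximum global-alignment identity between ``a`` and any rotation of
    ``b`` or of its reverse complement.

    Identity is 1 − editdistance / columns with columns the longer of the
    two sequence lengths, so indels count against identity.  Symmetric in
    its arguments to floating tolerance.
    """
    return best_orientation(a, b)[0]


@dataclass
class Monomer:
    """A strand/rotation-standardized repeat unit.

    ``canonical_seq`` is the canonical form of ``source_unit`` (the unit as
    detected in the assembly); ``rotation_offset`` and ``strand`` record the
    transformation; ``weight_bp`` is the total array bp this unit
    represents, used as the clustering weight.
    """

    canonical_seq: str
    source_unit: str
    rotation_offset: int
    strand: str
    weight_bp: int

    def __post_init__(self) -> None:
        if self.weight_bp < 0:
            raise ValueError("weight_bp must be >= 0")

    @classmethod
    def from_unit(cls, unit: str, weight_bp: int) -> "Monomer":
        canon = canonical_monomer(unit)
        u = unit.upper()
        doubled = u + u
        rc = reverse_complement(u)
        for strand, s in (("+", u), ("-", rc)):
            dd = s + s
            for off in range(len(s)):
                if dd[off : off + len(s)] == canon:
                    return cls(canon, u, off, strand, weight_bp)
        raise AssertionError("canonical form not a rotation of either strand")
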