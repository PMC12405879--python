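"""Tandem repeat array detection in assembly contigs.

Detection proceeds in three stages:

1. *Seeding*: within each N-free segment of a contig, exact k-mer
   recurrences at distances up to ``unit_max`` vote for candidate periods;
   runs of consistent votes become candidate regions.
2. *Refinement*: from each candidate region a unit is extracted, reduced to
   its primitive period, and the array is extended copy-by-copy in both
   directions by semi-global alignment against a running consensus,
   tolerating indels.  A majority consensus built from the first pass is
   used for a second, more accurate pass.
3. *Filtering*: arrays must satisfy the unit-length range, the minimum
   tandem copy count, the minimum adjacent-copy identity, and a minimum
   alignment score; overlapping candidates are resolved deterministically
   (best score, then smaller unit, then leftmost).

Coordinates are 0-based half-open on the forward strand throughout; strand
symmetry is folded later by monomer canonicalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class DetectorParams:
    """Tandem detector settings.

    The defaults target satellite repeat units of 20-500 bp in tandem
    arrays of at least 5 copies with >=80% identity between copies.
    """

    unit_min: int = 20
    unit_max: int = 500
    min_copies: float = 5.0
    min_identity: float = 0.8
    match_score: int = 2
    mismatch_score: int = -3
    gap_score: int = -5
    min_array_score: int = 50
    seed_k: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.unit_min <= self.unit_max):
            raise ValueError("require 1 <= unit_min <= unit_max")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class TandemArray:
    """One detected tandem array on a contig.

    ``unit_seq`` is the refined consensus unit as detected (not yet
    rotation/strand standardized); ``copies`` is the real-valued span /
    unit length; ``mean_identity`` is the mean per-copy identity to the
    array consensus.
    """

    contig_id: str
    start: int
    end: int
    unit_seq: str
    copies: float
    mean_identity: float
    score: int = 0

    @property
    def unit_len(self) -> int:
        return len(self.unit_seq)

    @property
    def array_bp(self) -> int:
        return self.end - self.start


def primitive_period(seq: str) -> int:
    """Smallest period p >= 1 with seq[i] == seq[i+p] for all valid i.

    Classical failure-function period.  For a primitive string this equals
    the string length.  Note the returned value is the *fundamental*
    period only when it divides the length; otherwise the string is
    primitive and its length is returned.
    """
    if not seq:
        raise ValueError("empty input")
    n = len(seq)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    p = n - fail[-1]
    return p if n % p == 0 else n


def _alignment_counts(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, gaps) from an edlib extended cigar."""
    m = x = g = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op in "ID":
            g += n
        else:  # 'M' should not appear with task="path", treat as mismatch-free
            m += n
    return m, x, g


def _copy_identity(copy_seq: str, unit: str) -> tuple[float, int, int, int]:
    """Identity and (match, mismatch, gap) counts of one copy vs the unit."""
    if not copy_seq or not unit:
        g = max(len(copy_seq), len(unit))
        return 0.0, 0, 0, g
    r = edlib.align(copy_seq, unit, mode="NW", task="path")
    m, x, g = _alignment_counts(r["cigar"])
    cols = max(len(copy_seq), len(unit))
    ident = (cols - r["editDistance"]) / cols
    return ident, m, x, g


def _walk(seq: str, pos: int, unit: str, min_identity: float) -> list[tuple[int, int, float]]:
    """Segment successive copies of ``unit`` rightwards from ``pos``.

    Returns (start, end, identity) per accepted copy.  Each step aligns the
    unit semi-globally against a window of unit length plus indel slack and
    accepts the best-matching prefix if its identity clears the floor.
    """
    p = len(unit)
    slack = max(4, p // 4)
    out = []
    n = len(seq)
    cur = pos
    while cur + p // 2 <= n:
        window = seq[cur : cur + p + slack]
        if len(window) < max(2, p // 2):
            break
        r = edlib.align(unit, window, mode="SHW", task="distance")
        end_loc = r["locations"][0][1]
        if end_loc is None or end_loc < 0:
            break
        copy_len = end_loc + 1
        copy = window[:copy_len]
        ident, *_ = _copy_identity(copy, unit)
        if ident < min_identity:
            break
        out.append((cur, cur + copy_len, ident))
        cur += copy_len
    return out


def _consensus_from_copies(copies: list[str], ref: str, cap: int = 50) -> str:
    """Column-majority consensus of copies aligned to the reference frame.

    Ties resolve to the earlier base in A<C<G<T.  Only the first ``cap``
    copies are used; the consensus length equals the reference length.
    """
    counts = np.zeros((len(ref), 4), dtype=np.int64)
    order = "ACGT"
    idx = {b: i for i, b in enumerate(order)}
    for copy in copies[:cap]:
        r = edlib.align(copy, ref, mode="NW", task="path")
        qi = ri = 0
        for num, op in _CIGAR_RE.findall(r["cigar"]):
            n = int(num)
            if op in "=XM":
                for j in range(n):
                    b = copy[qi + j]
                    if b in idx:
                        counts[ri + j, idx[b]] += 1
                qi += n
                ri += n
            elif op == "I":  # extra bases in the copy: no reference column
                qi += n
            else:  # 'D': copy lacks these reference columns
                ri += n
    out = []
    for j, base in enumerate(ref):
        col = counts[j]
        if col.sum() == 0:
            out.append(base)
        else:
            out.append(order[int(np.argmax(col))])  # argmax ties -> lowest index = A<C<G<T
    return "".join(out)


def _approx_fundamental(unit: str, min_identity: float) -> str:
    """Reduce a unit that is a *noisy* tandem multiple of a smaller period.

    Exact primitivity (``primitive_period``) cannot reduce e.g. a doubled
    unit whose halves carry different mutations.  The fundamental period is
    estimated as the cyclic shift maximizing self-identity (smallest shift
    within 0.01 of the maximum, provided it clears ``min_identity``), and
    the unit is rebuilt as the majority consensus of its segments.
    """
    L = len(unit)
    if L < 8:
        return unit
    doubled = unit + unit
    codes = np.frombuffer(doubled.encode(), dtype=np.uint8)
    # smallest candidate period first; accept when the unit — treated as
    # circular, hence the doubled string and phase offsets — segments into
    # tandem copies of the candidate period covering it
    for p in range(2, L // 2 + 1):
        # prescreen: circular shift self-similarity (substitutions only; a
        # frame broken by an indel still clears this permissive floor)
        if float(np.mean(codes[:L] == codes[p : p + L])) < 0.45:
            continue
        k_est = round(L / p)
        for j in range(p):
            copies = _walk(doubled, j, doubled[j : j + p], min_identity)
            within = [c for c in copies if c[0] < j + L]
            if len(within) < 2:
                continue
            cov = min(within[-1][1], j + L) - j
            if cov < 0.9 * L or len(within) < max(2, k_est - 1):
                continue
            cons = _consensus_from_copies(
                [doubled[s:e] for s, e, _ in within], doubled[j : j + p]
            )
            cons = cons[: primitive_period(cons)]
            if cons and len(cons) < L:
                return _approx_fundamental(cons, min_identity)
    return unit


def refine_array(
    contig_seq: str,
    seed_start: int,
    seed_unit: str,
    params: DetectorParams | None = None,
) -> TandemArray | None:
    """Extend a seeded tandem unit into a full array.

    Extends left and right while per-copy identity to the running consensus
    stays at or above ``min_identity`` (indels allowed), rebuilds a
    majority consensus after the first pass, then re-segments with it.
    Returns None when not even two copies survive; filtering against
    ``min_copies`` etc. happens in :func:`filter_arrays`.
    """
    params = params or DetectorParams()
    seq = contig_seq.upper()
    unit = seed_unit.upper()
    p0 = primitive_period(unit)
    unit = unit[:p0]
    if "N" in unit or not unit:
        return None
    unit = _approx_fundamental(unit, params.min_identity)

    def segment(u: str, anchor: int) -> list[tuple[int, int, float]]:
        right = _walk(seq, anchor, u, params.min_identity)
        # leftwards: walk on reversed strings
        rseq = seq[::-1]
        rstart = len(seq) - anchor
        left_rev = _walk(rseq, rstart, u[::-1], params.min_identity)
        left = [(len(seq) - e, len(seq) - s, i) for (s, e, i) in left_rev]
        left.reverse()
        return left + right

    copies = segment(unit, seed_start)
    if len(copies) < 2:
        return None
    # second pass: majority consensus from the observed copies
    consensus = _consensus_from_copies([seq[s:e] for s, e, _ in copies], unit)
    consensus = consensus[: primitive_period(consensus)]
    consensus = _approx_fundamental(consensus, params.min_identity)
    if consensus != unit:
        anchor = copies[0][0]
        copies2 = segment(consensus, anchor)
        if len(copies2) >= len(copies):
            copies = copies2
            unit = consensus
    if len(copies) < 2:
        return None

    start = copies[0][0]
    end = copies[-1][1]
    idents = []
    score = 0
    for s, e, _ in copies:
        ident, m, x, g = _copy_identity(seq[s:e], unit)
        idents.append(ident)
        score += params.match_score * m + params.mismatch_score * x + params.gap_score * g
    return TandemArray(
        contig_id="",
        start=start,
        end=end,
        unit_seq=unit,
        copies=(end - start) / len(unit),
        mean_identity=float(np.mean(idents)),
        score=score,
    )


def _seed_regions(seg: str, params: DetectorParams) -> list[tuple[int, int]]:
    """Candidate (start, period) seeds from exact k-mer recurrences."""
    k = min(params.seed_k, max(2, len(seg) // 3))
    codes = _CODE[np.frombuffer(seg.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k + 1:
        return []
    kv = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        kv = kv * 4 + codes[j : n - k + 1 + j]
    order = np.argsort(kv, kind="stable")
    kv_s = kv[order]
    same = kv_s[1:] == kv_s[:-1]
    d = order[1:] - order[:-1]
    # d is the distance to the previous occurrence of the same k-mer
    lo = max(1, min(params.unit_min, k))
    mask = same & (d >= lo) & (d <= params.unit_max)
    hits = sorted(zip(order[:-1][mask].tolist(), d[mask].tolist()))
    # cluster hits into runs of consistent period
    regions: list[tuple[int, int]] = []
    open_clusters: list[dict] = []
    for pos, dist in hits:
        placed = False
        for c in open_clusters:
            if abs(dist - c["d"]) <= max(3, int(0.15 * c["d"])) and pos <= c["end"] + 2 * c["d"]:
                c["end"] = max(c["end"], pos + dist)
                c["n"] += 1
                placed = True
                break
        if not placed:
            open_clusters.append({"first": pos, "end": pos + dist, "d": dist, "n": 1})
        # close stale clusters
        still = []
        for c in open_clusters:
            if pos > c["end"] + 2 * params.unit_max:
                if c["end"] - c["first"] >= 2 * c["d"]:
                    regions.append((c["first"], c["d"]))
            else:
                still.append(c)
        open_clusters = still
    for c in open_clusters:
        if c["end"] - c["first"] >= 2 * c["d"]:
            regions.append((c["first"], c["d"]))
    return regions


def _resolve_overlaps(arrays: list[TandemArray]) -> list[TandemArray]:
    """Keep the better of overlapping candidates.

    Order of preference: higher score, then smaller unit length, then
    leftmost start (deterministic; favors fundamental periods).
    """
    kept: list[TandemArray] = []
    for arr in sorted(arrays, key=lambda a: (-a.score, a.unit_len, a.start)):
        if all(arr.end <= k.start or arr.start >= k.end for k in kept):
            kept.append(arr)
    kept.sort(key=lambda a: a.start)
    return kept


def filter_arrays(arrays: list[TandemArray], params: DetectorParams) -> list[TandemArray]:
    """Apply the unit-range / copy-count / identity / score filters.

    Boundaries are inclusive; output is stably ordered by (contig, start).
    """
    out = [
        a
        for a in arrays
        if params.unit_min <= a.unit_len <= params.unit_max
        and a.copies >= params.min_copies
        and a.mean_identity >= params.min_identity
        and a.score >= params.min_array_score
    ]
    out.sort(key=lambda a: (a.contig_id, a.start))
    return out


def scan_contig(
    contig_seq: str,
    params: DetectorParams | None = None,
    contig_id: str = "",
) -> list[TandemArray]:
    """Detect filtered, non-overlapping tandem arrays in one contig.

    Runs of N split the contig into independently scanned segments; a
    contig shorter than two minimal units yields an empty list.
    """
    params = params or DetectorParams()
    seq = contig_seq.upper()
    if len(seq) < 2 * params.unit_min:
        return []
    candidates: list[TandemArray] = []
    for m in re.finditer(r"[ACGT]+", seq):
        seg, off = m.group(0), m.start()
        if len(seg) < 2 * params.unit_min:
            continue
        seen: set[tuple[int, int]] = set()
        refined: list[tuple[int, int, int]] = []  # (start, end, unit_len)
        for pos, dist in _seed_regions(seg, params):
            # a seed inside an already-refined array at a compatible period
            # would converge to the same interval; skip the repeat work
            if any(
                s <= pos < e and (min(dist % ul, ul - dist % ul) <= 2 or dist <= ul + 2)
                for s, e, ul in refined
            ):
                continue
            arr = refine_array(seg, pos, seg[pos : pos + dist], params)
            if arr is None:
                continue
            refined.append((arr.start, arr.end, arr.unit_len))
            key = (arr.start, arr.end)
            if key in seen:
                continue
            seen.add(key)
            arr.contig_id = contig_id
            arr.start += off
            arr.end += off
            candidates.append(arr)
    resolved = _resolve_overlaps(candidates)
    out = filter_arrays(resolved, params)
    for a in out:
        if not (0 <= a.start < a.end <= len(seq)):
            raise AssertionError("array interval exceeds contig bounds")
    return out


def scan_assembly(
    contigs: dict[str, str] | list[tuple[str, str]],
    params: DetectorParams | None = None,
) -> list[TandemArray]:
    """Scan every contig of an assembly; contigs are processed in the given
    order and results concatenated (already sorted within each contig)."""
    params = params or DetectorParams()
    items = contigs.items() if isinstance(contigs, dict) else contigs
    out: list[TandemArray] = []
    for name, seq in items:
        out.extend(scan_contig(seq, params, contig_id=name))
    return out
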