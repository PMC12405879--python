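"""FISH oligo probe design for satellite families.

Probes are 30-40-mers drawn from a family consensus, treated as circular
(monomer rotation is arbitrary, and the hybridization target is a tandem
array, so windows may wrap; for units shorter than the probe the window
tiles over consecutive unit copies — e.g. a 10 bp unit yields a probe of
three exact unit copies).

Two design modes:

* conserved family probes minimize the worst-case mismatch count against
  any family member, so one oligo detects most or all variants;
* variant-discriminating probe pairs maximize mismatches against the
  aligned sister variant, with a minimum discrimination floor (default 3
  mismatches, the separation at which competitive hybridization of an A/B
  probe pair is known to discriminate 37 bp variants).

There is no melting-temperature model; a GC-content window and a
homopolymer cap are the composition constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np

from .canon import best_orientation, reverse_complement
from .detect import _CIGAR_RE, _CODE

DEFAULT_LEN_RANGE = (30, 40)
DEFAULT_GC_RANGE = (0.15, 0.65)
MAX_HOMOPOLYMER = 8
DEFAULT_MIN_DISCRIMINATION = 3


class ProbeDesignError(ValueError):
    pass


@dataclass
class ProbeCandidate:
    probe_seq: str
    family_id: str
    variant_label: str | None
    start: int  # window start on the (circular) design consensus
    on_target_max_mismatch: int
    off_target_min_mismatch: int | None  # vs the sister variant, when applicable
    gc: float


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def validate_probe(
    seq: str,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    gc_range: tuple[float, float] | None = None,
    max_homopolymer: int = MAX_HOMOPOLYMER,
) -> list[str]:
    """Constraint violations of a probe sequence (empty list = valid)."""
    problems = []
    if not (len_range[0] <= len(seq) <= len_range[1]):
        problems.append(f"length {len(seq)} outside [{len_range[0]},{len_range[1]}]")
    if gc_range is not None:
        from .abundance import gc_content

        gc = gc_content(seq)
        if not (gc_range[0] <= gc <= gc_range[1]):
            problems.append(f"GC {gc:.3f} outside [{gc_range[0]},{gc_range[1]}]")
    if max_homopolymer and max_homopolymer_run(seq) > max_homopolymer:
        problems.append(f"homopolymer run > {max_homopolymer}")
    return problems


def _entropy(seq: str) -> float:
    n = len(seq)
    h = 0.0
    for b in "ACGT":
        p = seq.count(b) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def _member_mismatch_profile(consensus: str, member: str) -> np.ndarray:
    """Per-consensus-column mismatch indicator for one oriented member."""
    oriented = best_orientation(consensus, member)[1]
    r = edlib.align(oriented, consensus, mode="NW", task="path")
    diff = np.zeros(len(consensus), dtype=np.int32)
    qi = ri = 0
    for num, op in _CIGAR_RE.findall(r["cigar"]):
        n = int(num)
        if op in "=M":
            qi += n
            ri += n
        elif op == "X":
            diff[ri : ri + n] = 1
            qi += n
            ri += n
        elif op == "I":  # extra member bases disturb the nearest column
            diff[min(ri, len(consensus) - 1)] = 1
            qi += n
        else:
            diff[ri : ri + n] = 1
            ri += n
    return diff


def _windows(consensus_len: int, len_range: tuple[int, int]):
    """(start, length) windows on a circular consensus, deterministic order.

    For units shorter than the minimum probe length the window tiles whole
    unit copies (tandem dimer/trimer/...), so a 10 bp unit yields a probe
    of three exact concatenated copies.
    """
    lengths = list(range(len_range[0], len_range[1] + 1))
    if consensus_len < len_range[0]:
        tiled = [L for L in lengths if L % consensus_len == 0]
        lengths = tiled or lengths
    for start in range(consensus_len):
        for length in lengths:
            yield start, length


def _window_seq(consensus: str, start: int, length: int) -> str:
    reps = -(-(start + length) // len(consensus))
    return (consensus * reps)[start : start + length]


def _window_cost(profile_cols: np.ndarray, start: int, length: int) -> int:
    """Sum of a per-column profile over a circular window (columns covered
    more than once by a wrapped window count with multiplicity)."""
    L = profile_cols.shape[-1]
    idx = (np.arange(start, start + length)) % L
    return int(profile_cols[..., idx].sum(axis=-1).max()) if profile_cols.ndim == 2 else int(
        profile_cols[idx].sum()
    )


def design_family_probe(
    consensus: str,
    members: list[str] | None = None,
    family_id: str = "",
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
    max_homopolymer: int = MAX_HOMOPOLYMER,
) -> ProbeCandidate:
    """Conserved probe for a family: the feasible window minimizing the
    maximum mismatch count to any member (ties: higher entropy, then
    leftmost, then shortest)."""
    if not consensus:
        raise ProbeDesignError("empty consensus")
    profiles = (
        np.stack([_member_mismatch_profile(consensus, m) for m in members])
        if members
        else np.zeros((1, len(consensus)), dtype=np.int32)
    )
    best = None
    for start, length in _windows(len(consensus), len_range):
        seq = _window_seq(consensus, start, length)
        if validate_probe(seq, len_range, gc_range, max_homopolymer):
            continue
        cost = _window_cost(profiles, start, length)
        key = (cost, -_entropy(seq), start, length)
        if best is None or key < best[0]:
            best = (key, start, length, seq, cost)
    if best is None:
        raise ProbeDesignError("no feasible probe")
    _, start, length, seq, cost = best
    from .abundance import gc_content

    return ProbeCandidate(seq, family_id, None, start, cost, None, gc_content(seq))


def _cross_variant_diff(own: str, sister: str) -> np.ndarray:
    """Columns of ``own`` that mismatch the rotationally aligned sister."""
    oriented = best_orientation(own, sister)[1]
    return _member_mismatch_profile(own, oriented)


def design_variant_probes(
    variant_a_consensus: str,
    variant_b_consensus: str,
    family_id: str = "",
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    min_discrimination: int = DEFAULT_MIN_DISCRIMINATION,
    gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
    max_homopolymer: int = MAX_HOMOPOLYMER,
) -> tuple[ProbeCandidate, ProbeCandidate]:
    """Discriminating probe pair for two variants.

    Each probe is the feasible window of its own consensus maximizing the
    mismatch count to the aligned sister variant (ties leftmost, then
    shortest); both must reach ``min_discrimination`` mismatches.
    """
    if variant_a_consensus.upper() == variant_b_consensus.upper():
        raise ProbeDesignError("variants not discriminable at requested floor")
    out = []
    for label, own, sister in (
        ("A", variant_a_consensus, variant_b_consensus),
        ("B", variant_b_consensus, variant_a_consensus),
    ):
        diff = _cross_variant_diff(own, sister)
        best = None
        for start, length in _windows(len(own), len_range):
            seq = _window_seq(own, start, length)
            if validate_probe(seq, len_range, gc_range, max_homopolymer):
                continue
            cross = _window_cost(diff, start, length)
            key = (-cross, start, length)
            if best is None or key < best[0]:
                best = (key, start, length, seq, cross)
        if best is None:
            raise ProbeDesignError("no feasible probe")
        _, start, length, seq, cross = best
        if cross < min_discrimination:
            raise ProbeDesignError("variants not discriminable at requested floor")
        from .abundance import gc_content

        out.append(ProbeCandidate(seq, family_id, label, start, 0, cross, gc_content(seq)))
    return out[0], out[1]


@dataclass
class ProbeHit:
    seq_id: str
    position: int
    mismatches: int
    strand: str


def probe_hit_map(
    probe: str,
    sequences: dict[str, str] | list[tuple[str, str]],
    max_mismatch: int,
) -> list[ProbeHit]:
    """All sliding-window hits of the probe on either strand with at most
    ``max_mismatch`` mismatches (substitutions only, no indels)."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    p = probe.upper()
    lp = len(p)
    pcodes = _CODE[np.frombuffer(p.encode(), dtype=np.uint8)]
    hits = []
    for seq_id, seq in items:
        s = seq.upper()
        if len(s) < lp:
            continue
        for strand, target in (("+", s), ("-", reverse_complement(s))):
            tcodes = _CODE[np.frombuffer(target.encode(), dtype=np.uint8)]
            n = len(tcodes)
            mm = np.zeros(n - lp + 1, dtype=np.int32)
            for j in range(lp):
                mm += tcodes[j : n - lp + 1 + j] != pcodes[j]
            for pos in np.flatnonzero(mm <= max_mismatch):
                fwd_pos = int(pos) if strand == "+" else n - lp - int(pos)
                hits.append(ProbeHit(seq_id, fwd_pos, int(mm[pos]), strand))
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits
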