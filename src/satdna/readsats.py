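"""Profiling of simple short satellites (unit <= 20 bp) in raw reads.

Unassembled short reads are scanned for maximal *exact* tandem runs of
primitive units, the run bp is credited to the unit's canonical
(rotation/strand-folded) form, and per-sample profiles are depth-normalized
to bp per Gb of sequenced bases before tissue comparison.  Exact matching
mirrors the semantics of k-mer tandem counters used for simple satellites;
divergent long-unit satellites are the assembly detector's job instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canon import canonical_monomer
from .detect import _CODE, primitive_period

DEFAULT_MAX_UNIT = 20
DEFAULT_MIN_COPIES = 3.0
DEFAULT_MIN_SPAN_FRAC = 0.5


@dataclass
class KmerSatProfile:
    """Per-sample short-satellite profile: canonical unit -> total bp."""

    sample_id: str
    unit_bp: dict[str, int] = field(default_factory=dict)
    reads_scanned: int = 0
    total_read_bp: int = 0

    def bp_per_gb(self, unit: str, pseudocount_bp: float = 0.0) -> float:
        if self.total_read_bp == 0:
            raise ValueError("empty sample")
        return (self.unit_bp.get(unit, 0) + pseudocount_bp) * 1e9 / self.total_read_bp


def scan_read(
    read_seq: str,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span_frac: float = DEFAULT_MIN_SPAN_FRAC,
) -> dict[str, int]:
    """Exact tandem content of one read: canonical unit -> covered bp.

    Finds maximal exact tandem runs of primitive units of length
    <= ``max_unit``; a run qualifies when it spans >= ``min_copies`` units
    and >= ``min_span_frac`` of the read.  N bases terminate runs.
    """
    n = len(read_seq)
    if n == 0:
        return {}
    codes = _CODE[np.frombuffer(read_seq.upper().encode(), dtype=np.uint8)]
    valid = codes != 255
    out: dict[str, int] = {}
    min_span = min_span_frac * n
    for p in range(1, min(max_unit, n // 2) + 1):
        eq = (codes[p:] == codes[:-p]) & valid[p:] & valid[:-p]
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for i, j in zip(starts, ends):
            m = j - i  # length of the periodic-match run; covered span = m + p
            span = m + p
            if span < p * min_copies or span < min_span:
                continue
            unit = read_seq[i : i + p].upper()
            if primitive_period(unit) != p:
                continue  # covered at the fundamental period instead
            key = canonical_monomer(unit)
            out[key] = out.get(key, 0) + span
    # conservation: a unit's credited bp can never exceed the read length
    for k in out:
        out[k] = min(out[k], n)
    return out


def aggregate_profiles(
    reads,
    sample_id: str,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span_frac: float = DEFAULT_MIN_SPAN_FRAC,
) -> KmerSatProfile:
    """Sum per-unit bp over an iterable of read sequences."""
    prof = KmerSatProfile(sample_id=sample_id)
    for seq in reads:
        prof.reads_scanned += 1
        prof.total_read_bp += len(seq)
        for unit, bp in scan_read(seq, max_unit, min_copies, min_span_frac).items():
            prof.unit_bp[unit] = prof.unit_bp.get(unit, 0) + bp
    return prof


@dataclass
class EnrichedUnit:
    unit: str
    germ_kb_per_gb: float
    soma_kb_per_gb: float
    ratio: float


@dataclass
class ProfileComparison:
    germ_enriched: list[EnrichedUnit]
    soma_abundant: list[EnrichedUnit]


def compare_profiles(
    germ: KmerSatProfile,
    soma: KmerSatProfile,
    min_total_kb: float = 10.0,
    ratio_min: float = 5.0,
) -> ProfileComparison:
    """Units enriched in the germline sample vs the somatic sample.

    Abundances are depth-normalized to bp per Gb of reads; a unit is
    germ-enriched when its germ abundance is >= ``min_total_kb`` (kb per
    Gb) and the germ/soma ratio is >= ``ratio_min`` (1 bp pseudocount on
    the denominator).  The somatic units clearing the same abundance floor
    are returned alongside.
    """
    if germ.total_read_bp == 0 or soma.total_read_bp == 0:
        raise ValueError("empty sample")
    units = sorted(set(germ.unit_bp) | set(soma.unit_bp))
    enriched, soma_abundant = [], []
    for u in units:
        g_kb = germ.bp_per_gb(u) / 1000
        s_kb = soma.bp_per_gb(u) / 1000
        ratio = germ.bp_per_gb(u) / soma.bp_per_gb(u, pseudocount_bp=1.0)
        rec = EnrichedUnit(u, g_kb, s_kb, ratio)
        if g_kb >= min_total_kb and ratio >= ratio_min:
            enriched.append(rec)
        if s_kb >= min_total_kb:
            soma_abundant.append(rec)
    enriched.sort(key=lambda r: -r.germ_kb_per_gb)
    soma_abundant.sort(key=lambda r: -r.soma_kb_per_gb)
    return ProfileComparison(enriched, soma_abundant)


def profile_to_rows(profile: KmerSatProfile) -> list[dict]:
    """TSV-ready rows (unit, bp, bp_per_gb), most abundant first."""
    rows = [
        {
            "unit": u,
            "bp": bp,
            "bp_per_gb": profile.bp_per_gb(u),
        }
        for u, bp in sorted(profile.unit_bp.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return rows
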