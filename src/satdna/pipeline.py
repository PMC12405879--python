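"""End-to-end satellite discovery: scan -> canonicalize -> cluster ->
name -> abundance, with a serializable run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

from . import __version__
from .abundance import AbundanceRecord, arrays_to_bed, family_abundance, gc_content, select_abundant
from .canon import Monomer
from .cluster import (
    DEFAULT_ID_THRESHOLD,
    DEFAULT_MIN_VARIANT_SHARE,
    DEFAULT_VARIANT_THRESHOLD,
    SatelliteFamily,
    cluster_monomers,
    name_families,
)
from .detect import DetectorParams, TandemArray, scan_assembly

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; JSON round-trips identically."""

    unit_min: int = 20
    unit_max: int = 500
    min_copies: float = 5.0
    min_identity: float = 0.8
    min_array_score: int = 50
    cluster_id: float = DEFAULT_ID_THRESHOLD
    variant_threshold: float = DEFAULT_VARIANT_THRESHOLD
    min_variant_share: float = DEFAULT_MIN_VARIANT_SHARE
    abundant_kb: float = 200.0
    species_prefix: str = "Bcop"
    seed: int = 0

    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            unit_min=self.unit_min,
            unit_max=self.unit_max,
            min_copies=self.min_copies,
            min_identity=self.min_identity,
            min_array_score=self.min_array_score,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.md5(self.to_json().encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"# satdna v{__version__} config={self.config_hash()} seed={self.seed}"


@dataclass
class DiscoveryResult:
    arrays: list[TandemArray]
    assignments: list[tuple[TandemArray, str]]  # array -> family_id
    families: list[SatelliteFamily]
    records: list[AbundanceRecord]
    abundant: list[AbundanceRecord]
    assembly_bp: int

    def family_consensi(self) -> dict[str, str]:
        return {f.family_id: f.consensus for f in self.families}

    def abundance_kb(self) -> dict[str, float]:
        return {r.family_id: r.total_kb for r in self.records}

    def bed_records(self, contig_lengths: dict[str, int] | None = None):
        return arrays_to_bed(self.assignments, contig_lengths)


def discover(contigs: dict[str, str], config: RunConfig | None = None) -> DiscoveryResult:
    """Run the full discovery pipeline on an in-memory assembly."""
    config = config or RunConfig()
    params = config.detector_params()
    arrays = scan_assembly(contigs, params)
    logger.info("arrays after detection filters: %d", len(arrays))

    monomers: list[Monomer] = []
    kept_arrays: list[TandemArray] = []
    for arr in arrays:
        if "N" in arr.unit_seq:
            continue  # monomers must be unambiguous
        monomers.append(Monomer.from_unit(arr.unit_seq, arr.array_bp))
        kept_arrays.append(arr)

    families = cluster_monomers(monomers, config.cluster_id)
    name_families(families, config.species_prefix, config.variant_threshold, config.min_variant_share)
    logger.info("families: %d", len(families))

    # map each array to the family its monomer joined
    fam_of_monomer: dict[int, str] = {}
    for fam in families:
        for m in fam.members:
            fam_of_monomer[id(m)] = fam.family_id
    assignments = [
        (arr, fam_of_monomer[id(m)]) for arr, m in zip(kept_arrays, monomers)
    ]

    assembly_bp = sum(len(s) for s in contigs.values())
    unit_lens = {f.family_id: f.unit_len for f in families}
    gc_by_family = {
        f.family_id: (
            [gc_content(v.consensus) for v in f.variants]
            if f.variants
            else [gc_content(f.consensus)]
        )
        for f in families
    }
    records = family_abundance(assignments, assembly_bp, unit_lens, gc_by_family)
    abundant = select_abundant(records, config.abundant_kb)
    logger.info("abundant families (>=%.0f kb): %d", config.abundant_kb, len(abundant))
    return DiscoveryResult(kept_arrays, assignments, families, records, abundant, assembly_bp)
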