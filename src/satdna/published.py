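"""Published *Bradysia coprophila* satellite probe sequences.

The 30-40-mer FISH oligo probe sequences reported for the abundant
core-chromosome satellite families (BcopSat-37 ... BcopSat-176, including
the A/B variant pairs) and for the three L-chromosome-enriched families
(BcopSat-10, BcopSat-38, BcopSat-39).  For families with units shorter
than the oligo the probe tiles full unit copies: the BcopSat-10 probe is
three exact copies of the 10 bp unit, and the BcopSat-37 probes each span
exactly one full 37 bp monomer.
"""

from __future__ import annotations

#: probes for the eight abundant core-chromosome families (variant pairs
#: keyed by their A/B labels)
CORE_PROBES: dict[str, str] = {
    "145A": "GGGTCCTCGGACTAAGGCCGCTACTAGGGCCCTATGTGT",
    "145B": "GGGCCCTTGGACTAAGGCCGCTACTCGGCCCTAAGTGT",
    "155": "ACTGCGCACCGTTGAAACACACTAAAAACTCACTTGCCT",
    "176A": "AGCATAGGCTTAGCATACATTTTCTTAATAATT",
    "176B": "CAAGCATAGGCGTAGCAAACATTTTCTTAATA",
    "37A": "AAAATAATTAATTTAAACGTCGAAATTCGTCATTTGG",
    "37B": "AAAATAATTAATTTAAACGTCGAATTTCATCGTTTGG",
    "109": "GGAAGTTAGGAAGTGCCAGAGGAATCATCTGTCAT",
    "162": "GCCATACATTATGACCAAAAAATGGCATTGTT",
    "129": "GTCACTCACACACAAAAGCGTACACTGTGGTCAC",
    "94": "TCGGTCTCTTACATTCTCGTAAAATATTCAAAA",
}

#: probes for the three L-chromosome-enriched families
L_PROBES: dict[str, str] = {
    "10": "AAAACGTATTAAAACGTATTAAAACGTATT",
    "38": "AAAAATTTGGTCACTTTCGGTGTATGTTGGGCAGCGGG",
    "39": "AAAATTTGGTCACTTTCAGGGTTTGGTTGGGCAGCTGT",
}

#: all published probes, keyed by family/variant label
ALL_PROBES: dict[str, str] = {**CORE_PROBES, **L_PROBES}

#: unit lengths of the L-enriched satellite families
L_UNIT_LENGTHS: tuple[int, ...] = (10, 38, 39)

#: the BcopSat-37 probes each cover one full monomer, so the probe doubles
#: as the variant monomer sequence
MONOMER_37A: str = CORE_PROBES["37A"]
MONOMER_37B: str = CORE_PROBES["37B"]
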