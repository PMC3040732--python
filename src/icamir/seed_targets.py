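"""Seed extraction from mature miRNA sequences and exact 6mer seed-match
scanning of 3'UTRs.

The seed is taken from mature-sequence positions 2-7 (1-based) by default and
matched in the UTR as its reverse complement on the DNA alphabet. Overlapping
occurrences are counted; a gene is a target of a miRNA iff its UTR contains at
least one match site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA_BASES = set("ACGU")


@dataclass(frozen=True)
class SeedSite:
    """A miRNA seed and the DNA pattern searched for in UTRs."""

    mirna_id: str
    seed_rna: str
    match_dna: str

    def __post_init__(self):
        if len(self.seed_rna) != len(self.match_dna):
            raise ValueError("seed and match pattern lengths differ")


@dataclass
class TargetMap:
    """Seed-predicted targets per miRNA over a shared gene universe.

    ``gene_universe`` is the set of genes with an available 3'UTR; genes
    without a UTR are excluded from all downstream analyses rather than being
    treated as non-targets.
    """

    mirna_ids: list
    gene_universe: set
    targets: dict  # mirna_id -> set of gene ids
    site_counts: dict  # (mirna_id, gene_id) -> int >= 1
    seeds: dict = field(default_factory=dict)  # mirna_id -> SeedSite

    def __post_init__(self):
        for m, genes in self.targets.items():
            stray = genes - self.gene_universe
            if stray:
                raise ValueError(f"targets of {m!r} outside the gene universe: {sorted(stray)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna_id": m, "gene_id": g, "site_count": self.site_counts[(m, g)]}
            for m in self.mirna_ids
            for g in sorted(self.targets.get(m, ()))
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "site_count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_universe) -> "TargetMap":
        universe = set(gene_universe)
        targets: dict = {}
        counts: dict = {}
        for m, g, c in df[["mirna_id", "gene_id", "site_count"]].itertuples(index=False):
            targets.setdefault(m, set()).add(g)
            counts[(m, g)] = int(c)
        mirna_ids = list(dict.fromkeys(df["mirna_id"]))
        return cls(mirna_ids, universe, targets, counts)


def reverse_complement(seq: str, alphabet: str = "dna") -> str:
    """Reverse complement of an RNA string, emitted as DNA or RNA."""
    rc = seq.upper().replace("T", "U").translate(_RNA_COMPLEMENT)[::-1]
    return rc.replace("U", "T") if alphabet == "dna" else rc


def extract_seed(mature_sequence: str, seed_start: int = 2, seed_len: int = 6) -> tuple:
    """Extract the seed from a mature miRNA sequence.

    Returns ``(seed_rna, match_dna)`` where ``seed_rna`` is the 1-based
    ``seed_start .. seed_start+seed_len-1`` substring and ``match_dna`` is its
    reverse complement on the DNA alphabet.
    """
    if seed_start < 1 or seed_len < 1:
        raise ValueError("seed_start and seed_len must be positive")
    seq = mature_sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_BASES
    if bad:
        raise ValueError(f"invalid bases in mature sequence: {sorted(bad)}")
    if len(seq) < seed_start + seed_len - 1:
        raise ValueError(
            f"mature sequence of length {len(seq)} too short for seed "
            f"positions {seed_start}-{seed_start + seed_len - 1}"
        )
    seed_rna = seq[seed_start - 1 : seed_start - 1 + seed_len]
    return seed_rna, reverse_complement(seed_rna, "dna")


def scan_utr(utr: str, match_dna: str) -> int:
    """Count (possibly overlapping) exact occurrences of ``match_dna`` in a
    UTR. Positions containing N never match; matching is case-insensitive."""
    if not utr:
        raise ValueError("empty UTR sequence")
    hay = utr.upper().replace("U", "T")
    pat = match_dna.upper().replace("U", "T")
    count = 0
    i = hay.find(pat)
    while i != -1:
        count += 1
        i = hay.find(pat, i + 1)
    return count


def build_target_map(
    mirnas: Mapping,
    utrs: Mapping,
    seed_start: int = 2,
    seed_len: int = 6,
) -> TargetMap:
    """Scan every UTR for every miRNA's seed-match pattern.

    ``mirnas`` maps miRNA ids to mature RNA sequences; ``utrs`` maps gene ids
    to DNA (or RNA; transliterated) 3'UTR strings. Duplicate seeds across
    miRNAs are allowed but logged, since they imply identical target sets.
    """
    if not mirnas or not utrs:
        raise ValueError("mirnas and utrs must both be non-empty")
    seeds: dict = {}
    seen_patterns: dict = {}
    for mid, seq in mirnas.items():
        seed_rna, match_dna = extract_seed(seq, seed_start=seed_start, seed_len=seed_len)
        if match_dna in seen_patterns:
            logger.warning(
                "miRNAs %s and %s share the seed %s (identical target sets)",
                seen_patterns[match_dna], mid, seed_rna,
            )
        seen_patterns.setdefault(match_dna, mid)
        seeds[mid] = SeedSite(mid, seed_rna, match_dna)

    universe = set(utrs)
    targets: dict = {m: set() for m in mirnas}
    counts: dict = {}
    for gid, utr in utrs.items():
        for mid, site in seeds.items():
            n = scan_utr(utr, site.match_dna)
            if n >= 1:
                targets[mid].add(gid)
                counts[(mid, gid)] = n
    return TargetMap(list(mirnas), universe, targets, counts, seeds)
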