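"""Per-site allele tallies shared by the simulator, the somatic filters and
the mutation-reads extractor.

A :class:`PileupSite` holds one sample's observations at one reference
position: for every allele seen there, the forward- and reverse-strand read
counts plus the per-read base qualities (Phred) and mapping qualities.
SNV alleles are single bases ``A/C/G/T``; indel alleles use a compact
left-aligned notation, ``+SEQ`` for an insertion after the site and ``-SEQ``
for a deletion of SEQ starting at the next base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

SNV_ALLELES = ("A", "C", "G", "T")

SiteKey = Tuple[str, int]  # (contig, 1-based position)


@dataclass
class AlleleObs:
    """Observations supporting one allele at one site in one sample."""

    fwd: int = 0
    rev: int = 0
    base_qualities: List[int] = field(default_factory=list)
    mapping_qualities: List[int] = field(default_factory=list)

    @property
    def count(self) -> int:
        return self.fwd + self.rev

    def validate(self) -> None:
        if self.fwd < 0 or self.rev < 0:
            raise ValueError("negative allele count")
        if len(self.base_qualities) != self.count:
            raise ValueError("base-quality list length != allele count")
        if len(self.mapping_qualities) != self.count:
            raise ValueError("mapping-quality list length != allele count")


@dataclass
class PileupSite:
    """One sample's allele tallies at one 1-based reference position."""

    contig: str
    position: int
    ref_base: str
    tallies: Dict[str, AlleleObs] = field(default_factory=dict)

    @property
    def coverage(self) -> int:
        return sum(obs.count for obs in self.tallies.values())

    def obs(self, allele: str) -> AlleleObs:
        return self.tallies.get(allele, AlleleObs())

    def allele_count(self, allele: str) -> int:
        return self.obs(allele).count

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.position)

    def add(
        self,
        allele: str,
        *,
        fwd: int = 0,
        rev: int = 0,
        base_quality: int = 36,
        mapping_quality: int = 60,
    ) -> None:
        """Add ``fwd`` + ``rev`` reads of ``allele`` with uniform qualities."""
        obs = self.tallies.setdefault(allele, AlleleObs())
        obs.fwd += fwd
        obs.rev += rev
        n = fwd + rev
        obs.base_qualities.extend([base_quality] * n)
        obs.mapping_qualities.extend([mapping_quality] * n)


Pileup = Dict[SiteKey, PileupSite]


def pileup_from_reads(
    reads: Iterable,
    reference: str,
    contig: str,
    *,
    base_quality: int = 36,
    mapping_quality: int = 60,
) -> "ArrayPileup":
    """Tally base counts from simulated/aligned reads over a whole contig.

    ``reads`` must expose ``start`` (0-based leftmost reference position),
    ``strand`` (``+``/``-``) and ``sequence`` (reference-forward orientation,
    ungapped).  Qualities are uniform: the read-based path models neither
    base- nor mapping-quality artifacts (those are injected at the pileup
    level by the simulator).
    """
    length = len(reference)
    counts = np.zeros((length, 4, 2), dtype=np.int32)  # pos x base x strand
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(SNV_ALLELES):
        base_index[ord(b)] = i
    for read in reads:
        seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        idx = base_index[seq]
        pos = np.arange(read.start, read.start + len(seq))
        keep = (idx >= 0) & (pos < length)
        strand = 0 if read.strand == "+" else 1
        np.add.at(counts, (pos[keep], idx[keep], strand), 1)
    return ArrayPileup(
        contig=contig,
        reference=reference,
        counts=counts,
        base_quality=base_quality,
        mapping_quality=mapping_quality,
    )


@dataclass
class ArrayPileup:
    """Dense whole-contig base counts with uniform read qualities."""

    contig: str
    reference: str
    counts: np.ndarray  # (length, 4 bases, 2 strands)
    base_quality: int = 36
    mapping_quality: int = 60

    def candidate_loci(self, min_alt: int = 1) -> List[int]:
        """1-based positions with at least ``min_alt`` non-reference reads."""
        ref_idx = np.array(
            [SNV_ALLELES.index(b) if b in SNV_ALLELES else -1 for b in self.reference]
        )
        per_base = self.counts.sum(axis=2)
        total = per_base.sum(axis=1)
        pos = np.arange(len(self.reference))
        valid = ref_idx >= 0
        ref_counts = np.zeros(len(self.reference), dtype=np.int64)
        ref_counts[valid] = per_base[pos[valid], ref_idx[valid]]
        alt = total - ref_counts
        return [int(p) + 1 for p in np.nonzero(valid & (alt >= min_alt))[0]]

    def site(self, position: int) -> PileupSite:
        """Materialize a :class:`PileupSite` at a 1-based position."""
        if not 1 <= position <= len(self.reference):
            raise IndexError(f"position {position} outside contig {self.contig}")
        site = PileupSite(self.contig, position, self.reference[position - 1])
        for b_i, base in enumerate(SNV_ALLELES):
            fwd = int(self.counts[position - 1, b_i, 0])
            rev = int(self.counts[position - 1, b_i, 1])
            if fwd or rev:
                site.add(
                    base,
                    fwd=fwd,
                    rev=rev,
                    base_quality=self.base_quality,
                    mapping_quality=self.mapping_quality,
                )
        return site

    def sites(self, positions: Sequence[int]) -> Pileup:
        return {(self.contig, p): self.site(p) for p in positions}
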