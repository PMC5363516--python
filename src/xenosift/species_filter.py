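"""Species-of-origin classification of PDX reads on a combined reference.

Sequencing a patient-derived xenograft mixes human tumor reads with mouse
stromal reads.  Aligning every read against a single reference that contains
both genomes lets the two species compete: a read is called human when its
best alignment score on a human contig strictly beats its best score on a
mouse contig, mouse in the opposite case, ambiguous on an exact tie, and
unmapped when no placement exists.  Only human-called reads are kept for
somatic calling; ambiguous reads are discarded conservatively.

Mapping quality is deliberately ignored for the species decision — it is
reference-relative and collapses precisely when a read maps comparably well
to both genomes, which is the case the classifier must adjudicate.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's placement on a combined-reference contig."""

    read_id: str
    contig: str
    position: int  # 1-based
    strand: str
    mapping_quality: int
    alignment_score: Optional[int]
    mapped: bool = True
    mate: int = 0  # 0 = single/first, 1 = second mate
    secondary: bool = False


@dataclass(frozen=True)
class SpeciesCall:
    read_id: str
    call: str  # human | mouse | ambiguous | unmapped
    best_score_human: Optional[int] = None
    best_score_mouse: Optional[int] = None


@dataclass
class SpeciesMap:
    """Maps contig-name prefixes to species and resolves contigs."""

    prefixes: Mapping[str, str]  # prefix -> species name

    def species_of(self, contig: str) -> str:
        for prefix, species in self.prefixes.items():
            if contig.startswith(prefix):
                return species
        raise KeyError(f"contig {contig!r} matches no species prefix")


DEFAULT_SPECIES_MAP = SpeciesMap({"hs_": "human", "mm_": "mouse"})


@dataclass
class FilterSummary:
    total_reads: int = 0
    calls: Counter = field(default_factory=Counter)

    @property
    def mapped_fraction_strict(self) -> float:
        """Fraction of reads with an unambiguous species placement."""
        if not self.total_reads:
            return 0.0
        return (self.calls["human"] + self.calls["mouse"]) / self.total_reads

    @property
    def mapped_fraction_lenient(self) -> float:
        """Fraction of reads mapped anywhere (ambiguous included)."""
        if not self.total_reads:
            return 0.0
        return (self.total_reads - self.calls["unmapped"]) / self.total_reads

    def fractions(self) -> Dict[str, float]:
        n = self.total_reads or 1
        return {call: c / n for call, c in sorted(self.calls.items())}

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_reads": self.total_reads,
                "calls": dict(self.calls),
                "fractions": self.fractions(),
                "mapped_fraction_strict": self.mapped_fraction_strict,
                "mapped_fraction_lenient": self.mapped_fraction_lenient,
            },
            indent=2,
        )


def build_combined_reference(
    human_fasta,
    mouse_fasta,
    out_fasta,
    prefixes: Tuple[str, str] = ("hs_", "mm_"),
) -> SpeciesMap:
    """Concatenate two single-species FASTAs into one combined reference,
    prefixing contig names so each resolves to exactly one species."""
    from Bio import SeqIO

    records = []
    seen: Set[str] = set()
    for path, prefix in ((human_fasta, prefixes[0]), (mouse_fasta, prefixes[1])):
        n_before = len(records)
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id if rec.id.startswith(prefix) else prefix + rec.id
            if name in seen:
                raise ValueError(f"duplicate contig name after prefixing: {name}")
            seen.add(name)
            rec.id = name
            rec.description = ""
            records.append(rec)
        if len(records) == n_before:
            raise ValueError(f"no contigs found in {path}; a combined "
                             "reference requires both species")
    SeqIO.write(records, str(out_fasta), "fasta")
    return SpeciesMap({prefixes[0]: "human", prefixes[1]: "mouse"})


def group_by_read(
    records: Iterable[AlignmentRecord],
) -> Iterable[List[AlignmentRecord]]:
    """Group records by read id (order-independent; buffers in memory)."""
    groups: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.read_id].append(rec)
    for read_id in sorted(groups):
        yield groups[read_id]


def _record_score(rec: AlignmentRecord) -> int:
    if rec.alignment_score is not None:
        return rec.alignment_score
    raise ValueError(
        f"record for read {rec.read_id!r} on {rec.contig} carries no "
        "alignment score and none could be recomputed"
    )


def classify_read_group(
    group: Sequence[AlignmentRecord], species_map: SpeciesMap
) -> SpeciesCall:
    """Call one read (or read pair: mate best scores are summed)."""
    # best score per (species, mate); secondary records compete but are
    # never double counted because only the max per species/mate survives
    best: Dict[Tuple[str, int], int] = {}
    read_id = group[0].read_id
    for rec in group:
        if not rec.mapped:
            continue
        species = species_map.species_of(rec.contig)
        score = _record_score(rec)
        key = (species, rec.mate)
        if key not in best or score > best[key]:
            best[key] = score

    totals: Dict[str, int] = {}
    for (species, _mate), score in best.items():
        totals[species] = totals.get(species, 0) + score
    s_h = totals.get("human")
    s_m = totals.get("mouse")
    if s_h is None and s_m is None:
        return SpeciesCall(read_id, "unmapped")
    if s_m is None or (s_h is not None and s_h > s_m):
        return SpeciesCall(read_id, "human", s_h, s_m)
    if s_h is None or s_m > s_h:
        return SpeciesCall(read_id, "mouse", s_h, s_m)
    return SpeciesCall(read_id, "ambiguous", s_h, s_m)


def classify_reads(
    records: Iterable[AlignmentRecord],
    species_map: SpeciesMap = DEFAULT_SPECIES_MAP,
) -> Tuple[List[SpeciesCall], FilterSummary]:
    calls = [
        classify_read_group(group, species_map) for group in group_by_read(records)
    ]
    summary = FilterSummary(
        total_reads=len(calls), calls=Counter(c.call for c in calls)
    )
    return calls, summary


def filter_alignments(
    records: Iterable[AlignmentRecord],
    calls: Sequence[SpeciesCall],
    keep: Set[str] = frozenset({"human"}),
) -> Tuple[List[AlignmentRecord], Counter]:
    """Retain records of reads whose call is in ``keep``; tally removals."""
    call_by_read = {c.read_id: c.call for c in calls}
    kept: List[AlignmentRecord] = []
    removed: Counter = Counter()
    seen_removed: Set[str] = set()
    for rec in records:
        try:
            call = call_by_read[rec.read_id]
        except KeyError:
            raise ValueError(f"no species call for read {rec.read_id!r}")
        if call in keep:
            kept.append(rec)
        elif rec.read_id not in seen_removed:
            removed[call] += 1
            seen_removed.add(rec.read_id)
    return kept, removed


def filter_reads(reads: Sequence, calls: Sequence[SpeciesCall], keep={"human"}):
    """Convenience for simulator read objects: keep reads whose call is in
    ``keep`` (used by the in-memory pipeline path)."""
    call_by_read = {c.read_id: c.call for c in calls}
    return [r for r in reads if call_by_read.get(r.read_id) in keep]


# ---------------------------------------------------------------------------
# SAM front-end
# ---------------------------------------------------------------------------


def records_from_sam(path) -> List[AlignmentRecord]:
    """Read alignment records from SAM/BAM (scores from the AS tag, NM
    fallback: matches − mismatches = aligned_length − 2·NM)."""
    import pysam

    out: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                out.append(
                    AlignmentRecord(a.query_name, "*", 0, "+", 0, None, mapped=False)
                )
                continue
            if a.has_tag("AS"):
                score = int(a.get_tag("AS"))
            elif a.has_tag("NM"):
                aligned = a.query_alignment_length
                score = aligned - 2 * int(a.get_tag("NM"))
            else:
                score = None
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    contig=a.reference_name,
                    position=a.reference_start + 1,
                    strand="-" if a.is_reverse else "+",
                    mapping_quality=a.mapping_quality,
                    alignment_score=score,
                    mapped=True,
                    mate=1 if a.is_read2 else 0,
                    secondary=a.is_secondary or a.is_supplementary,
                )
            )
    return out


def classify_sam(
    in_sam,
    out_sam,
    calls_tsv=None,
    species_map: SpeciesMap = DEFAULT_SPECIES_MAP,
    keep: Set[str] = frozenset({"human"}),
) -> FilterSummary:
    """Classify every read in a SAM file and write the cleaned SAM plus an
    optional per-read call table."""
    import pysam

    records = records_from_sam(in_sam)
    calls, summary = classify_reads(records, species_map)
    keep_ids = {c.read_id for c in calls if c.call in keep}
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as src:
        with pysam.AlignmentFile(str(out_sam), "w", template=src) as dst:
            for a in src:
                if a.query_name in keep_ids:
                    dst.write(a)
    if calls_tsv is not None:
        with open(calls_tsv, "w") as fh:
            fh.write("read_id\tcall\tbest_score_human\tbest_score_mouse\n")
            for c in calls:
                fh.write(
                    f"{c.read_id}\t{c.call}\t"
                    f"{'' if c.best_score_human is None else c.best_score_human}\t"
                    f"{'' if c.best_score_mouse is None else c.best_score_mouse}\n"
                )
    return summary
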