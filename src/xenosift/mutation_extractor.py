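"""Revisit every unique somatic mutation in primary and PDX samples.

Once somatic calls exist for the primary tumor and the (cleaned) PDX, every
unique mutation from either call set is re-examined in *both* samples'
pileups to tabulate mutant and non-mutant read counts, compute coverage and
variant allele fraction (VAF), and classify sharing status: ``common`` when
the mutant allele is supported in both samples, ``primary_only`` /
``pdx_only`` otherwise.  Sites with under 20x coverage in either sample are
flagged, since absence of evidence at shallow depth is weak evidence of
absence — "unique" labels at low coverage additionally carry an
``uncertain`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .pileup import Pileup

VariantKey = Tuple[str, int, str, str]  # contig, 1-based position, ref, alt

LOW_COVERAGE_CUTOFF = 20


@dataclass
class SampleObservation:
    coverage: int
    alt_count: int

    @property
    def vaf(self) -> Optional[float]:
        # undefined (not 0) at zero coverage: no-coverage is not no-mutation
        if self.coverage == 0:
            return None
        return self.alt_count / self.coverage


@dataclass
class MutationComparison:
    contig: str
    position: int
    ref: str
    alt: str
    primary: SampleObservation
    pdx: SampleObservation
    sharing: Optional[str] = None
    low_coverage_flag: bool = False
    uncertain: bool = False
    error: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.position, self.ref, self.alt)


def union_sites(
    primary_calls: Iterable[VariantKey], pdx_calls: Iterable[VariantKey]
) -> List[VariantKey]:
    """Deterministically sorted union of two call sets keyed by
    (contig, position, ref, alt); conflicting ref alleles at one position are
    a reference mismatch and abort."""
    merged = set(primary_calls) | set(pdx_calls)
    ref_at: Dict[Tuple[str, int], str] = {}
    for contig, pos, ref, _alt in merged:
        prev = ref_at.setdefault((contig, pos), ref)
        if prev != ref:
            raise ValueError(
                f"reference mismatch at {contig}:{pos} ({prev!r} vs {ref!r})"
            )
    return sorted(merged)


def extract_mutation_reads(
    sites: Sequence[VariantKey],
    primary: Pileup,
    pdx: Pileup,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> List[MutationComparison]:
    """Count mutant and total reads for every site in both samples.

    A site beyond a known contig end produces a per-site error record and
    the run continues; a site simply absent from a pileup counts as zero
    coverage there.
    """
    out: List[MutationComparison] = []
    for contig, pos, ref, alt in sites:
        if contig_lengths is not None and contig in contig_lengths and (
            pos < 1 or pos > contig_lengths[contig]
        ):
            out.append(
                MutationComparison(
                    contig, pos, ref, alt,
                    SampleObservation(0, 0), SampleObservation(0, 0),
                    error=f"position {pos} beyond contig {contig} end",
                )
            )
            continue
        obs = []
        for pileup in (primary, pdx):
            site = pileup.get((contig, pos))
            if site is None:
                obs.append(SampleObservation(0, 0))
            else:
                obs.append(
                    SampleObservation(site.coverage, site.allele_count(alt))
                )
        out.append(MutationComparison(contig, pos, ref, alt, obs[0], obs[1]))
    return out


def classify_sharing(
    comparison: MutationComparison,
    min_alt_reads: int = 2,
    min_coverage: int = LOW_COVERAGE_CUTOFF,
) -> MutationComparison:
    """Assign the sharing label in place and set the coverage flags."""
    in_primary = comparison.primary.alt_count >= min_alt_reads
    in_pdx = comparison.pdx.alt_count >= min_alt_reads
    if in_primary and in_pdx:
        comparison.sharing = "common"
    elif in_primary:
        comparison.sharing = "primary_only"
    elif in_pdx:
        comparison.sharing = "pdx_only"
    else:
        comparison.sharing = "absent"
    comparison.low_coverage_flag = (
        comparison.primary.coverage < min_coverage
        or comparison.pdx.coverage < min_coverage
    )
    comparison.uncertain = (
        comparison.sharing in ("primary_only", "pdx_only")
        and comparison.low_coverage_flag
    )
    return comparison


def classify_all(
    comparisons: Iterable[MutationComparison],
    min_alt_reads: int = 2,
    min_coverage: int = LOW_COVERAGE_CUTOFF,
) -> List[MutationComparison]:
    return [
        classify_sharing(c, min_alt_reads, min_coverage) for c in comparisons
    ]


def sharing_summary(comparisons: Sequence[MutationComparison]) -> pd.DataFrame:
    """Per-group counts and percentages over classified sites."""
    groups = ("common", "primary_only", "pdx_only")
    counts = {g: 0 for g in groups}
    for c in comparisons:
        if c.sharing in counts:
            counts[c.sharing] += 1
    total = sum(counts.values())
    rows = [
        {
            "group": g,
            "count": counts[g],
            "percent": 100.0 * counts[g] / total if total else 0.0,
        }
        for g in groups
    ]
    return pd.DataFrame(rows)


def comparison_table(comparisons: Sequence[MutationComparison]) -> pd.DataFrame:
    """MAF-like one-row-per-site table covering both samples."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "contig": c.contig,
                "position": c.position,
                "ref": c.ref,
                "alt": c.alt,
                "primary_coverage": c.primary.coverage,
                "primary_alt_count": c.primary.alt_count,
                "primary_vaf": c.primary.vaf,
                "pdx_coverage": c.pdx.coverage,
                "pdx_alt_count": c.pdx.alt_count,
                "pdx_vaf": c.pdx.vaf,
                "sharing": c.sharing,
                "low_coverage": c.low_coverage_flag,
                "uncertain": c.uncertain,
                "error": c.error,
            }
        )
    return pd.DataFrame(rows)


def scatter_table(comparisons: Sequence[MutationComparison]) -> pd.DataFrame:
    """Scatter-ready primary-VAF vs PDX-VAF table (the low-coverage column is
    the highlight flag); undefined VAFs are dropped."""
    df = comparison_table(comparisons)
    if df.empty:
        return df
    df = df.dropna(subset=["primary_vaf", "pdx_vaf"])
    return df[["contig", "position", "ref", "alt", "primary_vaf", "pdx_vaf",
               "low_coverage", "sharing"]].reset_index(drop=True)
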