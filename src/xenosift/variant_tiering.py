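"""Knowledge-based variant tiering and display binning.

Nonsynonymous variants are tiered by membership in frozen knowledge
fixtures: ``known`` when the exact (gene, protein change) pair has been
reported clinically relevant (ClinVar/COSMIC-style catalogue),
``novel_cancer_gene`` when the gene belongs to the Cancer Gene Census subset
or the bladder-cancer recurrently-mutated gene list, and ``other``
otherwise.  Protein effects in the short HGVS-like notation are split into
truncating (nonsense ``*``, frameshift ``fs``, splice ``_splice``) versus
altering (missense, in-frame indel) classes, and per-sample coverage is
binned for display (0-9X / 10-29X / >=30X).

The shipped fixtures are deliberately small frozen subsets — live database
queries are version-unstable and out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Set, Tuple

import pandas as pd

COVERAGE_BINS = ("0-9X", "10-29X", ">=30X")

_RE_NONSENSE = re.compile(r"^[A-Z]\d+\*$")
_RE_FRAMESHIFT = re.compile(r"^[A-Z]\d+fs$")
_RE_SPLICE = re.compile(r"^[A-Z]?\d+_splice$", re.IGNORECASE)
_RE_MISSENSE = re.compile(r"^[A-Z]\d+[A-Z]$")
_RE_INFRAME = re.compile(r"^[A-Z]?\d+(_[A-Z]?\d+)?(del|ins|dup)[A-Z]*$")


@dataclass(frozen=True)
class KnowledgeFixture:
    known_variants: frozenset  # of (GENE, CHANGE), case-normalized upper
    census_genes: frozenset
    bladder_recurrent_genes: frozenset

    def is_known(self, gene: str, change: str) -> bool:
        return (gene.upper(), change.upper()) in self.known_variants

    def is_cancer_gene(self, gene: str) -> bool:
        g = gene.upper()
        return g in self.census_genes or g in self.bladder_recurrent_genes


def load_fixture(directory=None) -> KnowledgeFixture:
    """Load the packaged knowledge fixtures (or from a directory of the same
    three files: known_variants.tsv, census_genes.txt, bladder_genes.txt)."""

    def read(name: str) -> str:
        if directory is not None:
            return (directory / name).read_text() if hasattr(directory, "joinpath") else open(
                f"{directory}/{name}"
            ).read()
        return resources.files("xenosift.data").joinpath(name).read_text()

    known = set()
    for line in read("known_variants.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        gene, change = line.split("\t")[:2]
        known.add((gene.upper(), change.upper()))
    census = {
        l.strip().upper()
        for l in read("census_genes.txt").splitlines()
        if l.strip() and not l.startswith("#")
    }
    bladder = {
        l.strip().upper()
        for l in read("bladder_genes.txt").splitlines()
        if l.strip() and not l.startswith("#")
    }
    return KnowledgeFixture(frozenset(known), frozenset(census), frozenset(bladder))


def classify_effect(protein_change: str) -> str:
    """``truncating`` (nonsense / frameshift / splice) or ``altering``
    (missense / in-frame indel) from the short protein notation."""
    token = protein_change.strip()
    if not token:
        raise ValueError("empty protein change")
    if _RE_NONSENSE.match(token) or _RE_FRAMESHIFT.match(token) or _RE_SPLICE.match(token):
        return "truncating"
    if _RE_MISSENSE.match(token) or _RE_INFRAME.match(token):
        return "altering"
    raise ValueError(f"unparseable protein change: {token!r}")


def assign_tier(gene: str, protein_change: str, fixture: KnowledgeFixture) -> str:
    if fixture.is_known(gene, protein_change):
        return "known"
    if fixture.is_cancer_gene(gene):
        return "novel_cancer_gene"
    return "other"


def coverage_bin(coverage: int) -> str:
    """Display bin for a per-sample coverage value."""
    if coverage < 0:
        raise ValueError(f"negative coverage: {coverage}")
    if coverage <= 9:
        return "0-9X"
    if coverage <= 29:
        return "10-29X"
    return ">=30X"


@dataclass
class TieredVariant:
    gene: str
    protein_change: str
    effect: str
    tier: str
    vaf_primary: Optional[float] = None
    vaf_pdx: Optional[float] = None
    coverage_bin_primary: Optional[str] = None
    coverage_bin_pdx: Optional[str] = None


def tier_variant(
    gene: str,
    protein_change: str,
    fixture: KnowledgeFixture,
    coverage_primary: Optional[int] = None,
    coverage_pdx: Optional[int] = None,
    vaf_primary: Optional[float] = None,
    vaf_pdx: Optional[float] = None,
) -> TieredVariant:
    return TieredVariant(
        gene=gene,
        protein_change=protein_change,
        effect=classify_effect(protein_change),
        tier=assign_tier(gene, protein_change, fixture),
        vaf_primary=vaf_primary,
        vaf_pdx=vaf_pdx,
        coverage_bin_primary=(
            coverage_bin(coverage_primary) if coverage_primary is not None else None
        ),
        coverage_bin_pdx=(
            coverage_bin(coverage_pdx) if coverage_pdx is not None else None
        ),
    )


def tier_table(df: pd.DataFrame, fixture: KnowledgeFixture) -> pd.DataFrame:
    """Tier an annotated table with ``gene`` and ``protein_change`` columns
    (plus optional per-sample coverage/VAF columns); output is ready for a
    circos-style display."""
    rows = []
    for _, row in df.iterrows():
        tv = tier_variant(
            str(row["gene"]),
            str(row["protein_change"]),
            fixture,
            coverage_primary=(
                int(row["primary_coverage"]) if "primary_coverage" in row else None
            ),
            coverage_pdx=int(row["pdx_coverage"]) if "pdx_coverage" in row else None,
            vaf_primary=row.get("primary_vaf"),
            vaf_pdx=row.get("pdx_vaf"),
        )
        rows.append(vars(tv))
    return pd.DataFrame(rows)


def write_tier_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tier_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
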