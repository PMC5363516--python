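"""Synthetic dual-species exome benchmark generator.

Builds everything the downstream stages need without external data: a toy
"human" and "mouse" chromosome pair differing by i.i.d. substitutions, reads
sampled from a contaminated PDX-like mixture with deterministic alignment
scores against both species, and multi-sample pileups (matched normal,
primary tumor, PDX) that realize a diploid purity model plus the classic
artifact classes a somatic caller must reject.

The count model is intentionally simple: per-site depth is Poisson around the
mean, and the alt-read count at a clonal somatic site is binomial with
success probability ``purity * multiplicity / 2`` (multiplicity 1 for
heterozygous, 2 for homozygous mutations, total copy number fixed at two).
That is exactly the model under which a het cluster at VAF 0.25 implies
purity 0.5 and a hom cluster at VAF 1.0 implies purity 1.0.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .pileup import Pileup, PileupSite
from .species_filter import AlignmentRecord

HUMAN_CONTIG = "hs_chrT"
MOUSE_CONTIG = "mm_chrT"

ARTIFACT_CLASSES = (
    "germline_leak",
    "strand_bias",
    "low_bq",
    "low_mq",
    "homopolymer_indel",
)

SHARING_GROUPS = ("common", "primary_only", "pdx_only")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Alt fraction used for non-germline artifact sites: high enough to clear any
# sane putative-variant threshold so the dedicated filter, not the detector,
# has to reject them.
_ARTIFACT_ALT_FRACTION = 0.30
_LOW_BQ = 12
_LOW_MQ = 5
_NORMAL_BQ = 36
_NORMAL_MQ = 60


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the modeled study design
    (paired primary/PDX/normal exomes, deep targeted coverage, a primary
    tumor of moderate purity and a purer PDX)."""

    seed: int = 0
    genome_length: int = 20_000
    species_divergence: float = 0.15
    read_length: int = 100
    depth: float = 200.0
    error_rate: float = 0.0
    contamination_fraction: float = 0.10
    purity_primary: float = 0.5
    purity_pdx: float = 1.0
    n_common: int = 100
    n_primary_only: int = 10
    n_pdx_only: int = 10
    hom_fraction: float = 0.0
    artifact_spec: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fracs = {
            "species_divergence": self.species_divergence,
            "error_rate": self.error_rate,
            "contamination_fraction": self.contamination_fraction,
            "purity_primary": self.purity_primary,
            "purity_pdx": self.purity_pdx,
            "hom_fraction": self.hom_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        if self.depth < 0:
            raise ConfigurationError("depth must be non-negative")
        if self.read_length > self.genome_length:
            raise ConfigurationError("read_length exceeds genome_length")
        if self.genome_length < 10 * self.read_length:
            raise ConfigurationError("genome_length must be >= 10 * read_length")
        for n in (self.n_common, self.n_primary_only, self.n_pdx_only):
            if n < 0:
                raise ConfigurationError("mutation counts must be non-negative")
        for cls, n in self.artifact_spec.items():
            if cls not in ARTIFACT_CLASSES:
                raise ConfigurationError(f"unknown artifact class {cls!r}")
            if n < 0:
                raise ConfigurationError("artifact counts must be non-negative")

    def purity(self, sample: str) -> float:
        if sample == "primary":
            return self.purity_primary
        if sample == "pdx":
            return self.purity_pdx
        if sample == "normal":
            return 0.0
        raise ValueError(f"unknown sample {sample!r}")


@dataclass(frozen=True)
class Mutation:
    """One injected variant; ``alt`` is a base for SNVs or a ``+SEQ``/``-SEQ``
    indel descriptor (left-aligned)."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    sharing: str  # common | primary_only | pdx_only
    zygosity: str  # het | hom
    artifact: Optional[str] = None

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith(("+", "-"))

    @property
    def multiplicity(self) -> int:
        return 2 if self.zygosity == "hom" else 1

    def in_sample(self, sample: str) -> bool:
        if self.artifact == "germline_leak":
            return True
        if sample == "normal":
            return False
        if self.sharing == "common":
            return True
        return (sample == "primary") == (self.sharing == "primary_only")


@dataclass
class DualReference:
    human: str
    mouse: str
    human_contig: str = HUMAN_CONTIG
    mouse_contig: str = MOUSE_CONTIG

    def sequence(self, contig: str) -> str:
        if contig == self.human_contig:
            return self.human
        if contig == self.mouse_contig:
            return self.mouse
        raise KeyError(contig)

    def write(self, human_path, mouse_path, combined_path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        hum = SeqRecord(Seq(self.human), id=self.human_contig, description="")
        mus = SeqRecord(Seq(self.mouse), id=self.mouse_contig, description="")
        SeqIO.write([hum], str(human_path), "fasta")
        SeqIO.write([mus], str(mouse_path), "fasta")
        SeqIO.write([hum, mus], str(combined_path), "fasta")


@dataclass
class SimulationTruth:
    """Ground-truth ledger: per-read species labels and injected mutations."""

    read_labels: Dict[str, str] = field(default_factory=dict)
    mutations: List[Mutation] = field(default_factory=list)

    @property
    def snvs(self) -> List[Mutation]:
        return [m for m in self.mutations if not m.is_indel]

    def true_mutations(self) -> List[Mutation]:
        return [m for m in self.mutations if m.artifact is None]

    def artifacts(self, cls: Optional[str] = None) -> List[Mutation]:
        return [
            m
            for m in self.mutations
            if m.artifact is not None and (cls is None or m.artifact == cls)
        ]

    def sample_mutations(self, sample: str) -> List[Mutation]:
        return [m for m in self.mutations if m.in_sample(sample)]

    def sharing_counts(self, include_artifacts: bool = False) -> Counter:
        pool = self.mutations if include_artifacts else self.true_mutations()
        return Counter(m.sharing for m in pool)

    def write_tsv(self, path) -> None:
        import pandas as pd

        rows = [dataclasses.asdict(m) for m in self.mutations]
        pd.DataFrame(
            rows,
            columns=["contig", "position", "ref", "alt", "sharing", "zygosity", "artifact"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def generate_dual_reference(
    length: int, divergence: float, seed: int
) -> DualReference:
    """Random toy human chromosome plus a mouse homolog that differs by
    i.i.d. substitutions at an expected ``divergence`` fraction of sites
    (each substituted site is forced to a different base)."""
    if length <= 0:
        raise ConfigurationError("reference length must be positive")
    if not 0.0 <= divergence <= 1.0:
        raise ConfigurationError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    human = rng.choice(_BASES, size=length)
    mouse = human.copy()
    flip = rng.random(length) < divergence
    # substitute by a non-zero offset in base space => always a different base
    offsets = rng.integers(1, 4, size=int(flip.sum()))
    idx = np.searchsorted(_BASES, human[flip])
    mouse[flip] = _BASES[(idx + offsets) % 4]
    return DualReference(human=human.tobytes().decode(), mouse=mouse.tobytes().decode())


def _plant_homopolymers(
    seq: np.ndarray, n_runs: int, run_length: int, margin: int, rng
) -> List[int]:
    """Overwrite ``n_runs`` disjoint windows with single-base runs; returns
    the 1-based start of each run."""
    starts: List[int] = []
    length = len(seq)
    taken: set = set()
    attempts = 0
    while len(starts) < n_runs:
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError("could not place homopolymer runs")
        start = int(rng.integers(margin, length - margin - run_length))
        window = range(start - run_length, start + 2 * run_length)
        if any(p in taken for p in window):
            continue
        base = _BASES[rng.integers(0, 4)]
        seq[start : start + run_length] = base
        # guard flanks so the run length is exactly run_length
        flank_choices = _BASES[_BASES != base]
        seq[start - 1] = rng.choice(flank_choices)
        seq[start + run_length] = rng.choice(flank_choices)
        taken.update(window)
        starts.append(start + 1)
    return starts


_PYR_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_mutations(
    human: np.ndarray,
    config: SimulationConfig,
    rng,
    homopolymer_starts: Sequence[int],
    homopolymer_len: int,
    class_weights: Optional[Mapping[str, float]] = None,
) -> List[Mutation]:
    margin = config.read_length
    length = len(human)
    blocked = set()
    for s in homopolymer_starts:
        blocked.update(range(s - 2, s + homopolymer_len + 2))

    candidates = [
        p
        for p in range(margin + 1, length - margin + 1)
        if p not in blocked
    ]
    rng.shuffle(candidates)
    pool = iter(candidates)

    def next_position(want_ref: Optional[set] = None) -> int:
        for p in pool:
            ref = chr(human[p - 1])
            if want_ref is None or ref in want_ref:
                return p
        raise ConfigurationError("toy genome too small for requested mutations")

    weights = None
    if class_weights is not None:
        ws = np.array([class_weights.get(c, 0.0) for c in _PYR_CLASSES], float)
        if ws.sum() <= 0:
            raise ConfigurationError("class weights must not all be zero")
        weights = ws / ws.sum()

    muts: List[Mutation] = []

    def draw_snv(sharing: str, artifact: Optional[str] = None) -> Mutation:
        zyg = "hom" if rng.random() < config.hom_fraction else "het"
        if artifact is not None:
            zyg = "het"
        if weights is None:
            pos = next_position()
            ref = chr(human[pos - 1])
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
        else:
            cls = _PYR_CLASSES[int(rng.choice(6, p=weights))]
            pyr_ref, pyr_alt = cls[0], cls[2]
            pos = next_position({pyr_ref, _COMPLEMENT[pyr_ref]})
            ref = chr(human[pos - 1])
            alt = pyr_alt if ref == pyr_ref else _COMPLEMENT[pyr_alt]
        return Mutation(HUMAN_CONTIG, pos, ref, alt, sharing, zyg, artifact)

    for _ in range(config.n_common):
        muts.append(draw_snv("common"))
    for _ in range(config.n_primary_only):
        muts.append(draw_snv("primary_only"))
    for _ in range(config.n_pdx_only):
        muts.append(draw_snv("pdx_only"))

    spec = dict(config.artifact_spec)
    for cls in ("germline_leak", "strand_bias", "low_bq", "low_mq"):
        for _ in range(spec.get(cls, 0)):
            muts.append(draw_snv("common", artifact=cls))
    run_iter = iter(homopolymer_starts)
    for _ in range(spec.get("homopolymer_indel", 0)):
        start = next(run_iter)
        base = chr(human[start - 1])
        # 1-bp deletion anchored at the base before the run (left-aligned)
        muts.append(
            Mutation(
                HUMAN_CONTIG,
                start - 1,
                chr(human[start - 2]),
                f"-{base}",
                "common",
                "het",
                "homopolymer_indel",
            )
        )
    return muts


def simulate_cohort(
    config: SimulationConfig,
    class_weights: Optional[Mapping[str, float]] = None,
    homopolymer_run_length: int = 8,
) -> Tuple[DualReference, SimulationTruth]:
    """Build the reference pair and the mutation ledger for one synthetic
    patient (reads and pileups are drawn separately so each stage can be
    exercised in isolation)."""
    rng = np.random.default_rng([config.seed, 0])
    human = np.random.default_rng([config.seed, 1]).choice(
        _BASES, size=config.genome_length
    )
    n_runs = dict(config.artifact_spec).get("homopolymer_indel", 0)
    starts = (
        _plant_homopolymers(
            human, n_runs, homopolymer_run_length, config.read_length, rng
        )
        if n_runs
        else []
    )
    # derive the mouse homolog from the final (run-containing) human sequence
    flip = rng.random(config.genome_length) < config.species_divergence
    mouse = human.copy()
    offsets = rng.integers(1, 4, size=int(flip.sum()))
    idx = np.searchsorted(_BASES, human[flip])
    mouse[flip] = _BASES[(idx + offsets) % 4]
    refs = DualReference(
        human=human.tobytes().decode(), mouse=mouse.tobytes().decode()
    )
    muts = _draw_mutations(
        human, config, rng, starts, homopolymer_run_length, class_weights
    )
    return refs, SimulationTruth(mutations=muts)


# ---------------------------------------------------------------------------
# pileup simulation (count model)
# ---------------------------------------------------------------------------


def _split_strands(n: int, rng) -> Tuple[int, int]:
    fwd = int(rng.binomial(n, 0.5)) if n else 0
    return fwd, n - fwd


def _site_for(
    mut: Mutation,
    sample: str,
    config: SimulationConfig,
    rng,
    reference: Optional[str],
) -> PileupSite:
    ref = mut.ref
    site = PileupSite(mut.contig, mut.position, ref)
    depth = int(rng.poisson(config.depth))
    if depth == 0:
        return site

    if mut.artifact is None:
        p_alt = (
            config.purity(sample) * mut.multiplicity / 2.0
            if mut.in_sample(sample)
            else 0.0
        )
    elif mut.artifact == "germline_leak":
        p_alt = 0.5  # het germline leaking through as a somatic candidate
    else:
        p_alt = _ARTIFACT_ALT_FRACTION if mut.in_sample(sample) else 0.0

    alt_n = int(rng.binomial(depth, p_alt)) if p_alt > 0 else 0
    ref_n = depth - alt_n

    # sequencing errors only perturb ref-intended reads (SNV alleles only)
    err_n = int(rng.binomial(ref_n, config.error_rate)) if config.error_rate else 0
    ref_n -= err_n
    others = [b for b in "ACGT" if b != ref]
    err_counts = rng.multinomial(err_n, [1 / 3] * 3) if err_n else [0, 0, 0]

    fwd, rev = _split_strands(ref_n, rng)
    site.add(ref, fwd=fwd, rev=rev, base_quality=_NORMAL_BQ, mapping_quality=_NORMAL_MQ)
    for base, n in zip(others, err_counts):
        if n:
            fwd, rev = _split_strands(int(n), rng)
            site.add(base, fwd=fwd, rev=rev, base_quality=_NORMAL_BQ,
                     mapping_quality=_NORMAL_MQ)

    if alt_n:
        bq, mq = _NORMAL_BQ, _NORMAL_MQ
        if mut.artifact == "low_bq":
            bq = _LOW_BQ
        if mut.artifact == "low_mq":
            mq = _LOW_MQ
        if mut.artifact == "strand_bias":
            fwd, rev = alt_n, 0
        else:
            fwd, rev = _split_strands(alt_n, rng)
        site.add(mut.alt, fwd=fwd, rev=rev, base_quality=bq, mapping_quality=mq)
    return site


def simulate_pileups(
    truth: SimulationTruth,
    config: SimulationConfig,
    samples: Sequence[str] = ("normal", "primary", "pdx"),
) -> Dict[str, Pileup]:
    """Draw per-site allele counts for every ledger site in every sample
    under the binomial purity model; artifact classes are realized with
    their defining signatures (one-strand alts, depressed base qualities,
    low mapping qualities, germline leakage into the normal)."""
    rng = np.random.default_rng([config.seed, 2])
    out: Dict[str, Pileup] = {s: {} for s in samples}
    for mut in truth.mutations:
        for sample in samples:
            site = _site_for(mut, sample, config, rng, None)
            out[sample][(mut.contig, mut.position)] = site
    return out


# ---------------------------------------------------------------------------
# read simulation (alignment model)
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    read_id: str
    species: str  # true origin
    start: int  # 0-based on its homologous locus (shared coordinate frame)
    strand: str
    sequence: str  # reference-forward orientation


def simulate_sample_reads(
    refs: DualReference,
    truth: SimulationTruth,
    config: SimulationConfig,
    sample: str,
    contamination: Optional[float] = None,
) -> Tuple[List[SimulatedRead], Dict[str, str]]:
    """Sample single-end reads for one sample.

    Mouse contamination applies to the PDX sample by default.  Human tumor
    reads carry each overlapping somatic mutation independently with
    probability ``purity * multiplicity / 2``.  Read-level realization is
    limited to SNVs; indel and quality-artifact classes live in the
    pileup-level simulator.
    """
    if contamination is None:
        contamination = config.contamination_fraction if sample == "pdx" else 0.0
    rng = np.random.default_rng([config.seed, 3, _sample_index(sample)])
    length = config.genome_length
    rl = config.read_length
    n_reads = int(round(config.depth * length / rl))
    purity = config.purity(sample)

    sample_muts = [
        m for m in truth.mutations if m.in_sample(sample) and not m.is_indel
    ]
    mut_pos = np.array(sorted(m.position for m in sample_muts), dtype=np.int64)
    by_pos = {m.position: m for m in sample_muts}

    human = np.frombuffer(refs.human.encode(), dtype=np.uint8)
    mouse = np.frombuffer(refs.mouse.encode(), dtype=np.uint8)

    species = np.where(rng.random(n_reads) < contamination, "mouse", "human")
    starts = rng.integers(0, length - rl + 1, size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    reads: List[SimulatedRead] = []
    labels: Dict[str, str] = {}
    for i in range(n_reads):
        sp = species[i]
        start = int(starts[i])
        seq = (human if sp == "human" else mouse)[start : start + rl].copy()
        if sp == "human" and mut_pos.size:
            lo = np.searchsorted(mut_pos, start + 1)
            hi = np.searchsorted(mut_pos, start + rl, side="right")
            for pos in mut_pos[lo:hi]:
                m = by_pos[int(pos)]
                p = 0.5 if m.artifact == "germline_leak" else purity * m.multiplicity / 2
                if rng.random() < p:
                    seq[int(pos) - 1 - start] = ord(m.alt)
        if config.error_rate:
            err = rng.random(rl) < config.error_rate
            if err.any():
                idx = np.searchsorted(_BASES, seq[err])
                seq[err] = _BASES[(idx + rng.integers(1, 4, size=int(err.sum()))) % 4]
        rid = f"{sample}_r{i:07d}"
        reads.append(SimulatedRead(rid, str(sp), start, str(strands[i]), seq.tobytes().decode()))
        labels[rid] = str(sp)
    truth.read_labels.update(labels)
    return reads, labels


def _sample_index(sample: str) -> int:
    return {"normal": 0, "primary": 1, "pdx": 2}[sample]


def score_read(read: SimulatedRead, refs: DualReference) -> Tuple[int, int]:
    """Ungapped match/mismatch score (+1/-1) of the read at its locus on each
    species' contig; the locus is shared because divergence is substitution
    only."""
    seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
    scores = []
    for ref in (refs.human, refs.mouse):
        window = np.frombuffer(ref.encode(), dtype=np.uint8)[
            read.start : read.start + len(seq)
        ]
        matches = int((window == seq).sum())
        scores.append(2 * matches - len(seq))
    return scores[0], scores[1]


def alignments_for_reads(
    reads: Iterable[SimulatedRead], refs: DualReference
) -> List[AlignmentRecord]:
    """Two alignment records per read (one per species contig) with the
    documented deterministic scores; the better-scoring placement is primary."""
    records: List[AlignmentRecord] = []
    for read in reads:
        s_h, s_m = score_read(read, refs)
        human_primary = s_h >= s_m
        for contig, score, primary in (
            (refs.human_contig, s_h, human_primary),
            (refs.mouse_contig, s_m, not human_primary),
        ):
            records.append(
                AlignmentRecord(
                    read_id=read.read_id,
                    contig=contig,
                    position=read.start + 1,
                    strand=read.strand,
                    mapping_quality=_NORMAL_MQ,
                    alignment_score=score,
                    mapped=True,
                    mate=0,
                    secondary=not primary,
                )
            )
    return records


def write_sam(
    reads: Sequence[SimulatedRead],
    refs: DualReference,
    path,
    records: Optional[Sequence[AlignmentRecord]] = None,
) -> None:
    """Write the simulated alignments as plain-text SAM with AS score tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": refs.human_contig, "LN": len(refs.human)},
            {"SN": refs.mouse_contig, "LN": len(refs.mouse)},
        ],
    }
    tid = {refs.human_contig: 0, refs.mouse_contig: 1}
    seqs = {r.read_id: r.sequence for r in reads}
    if records is None:
        records = alignments_for_reads(reads, refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = seqs[rec.read_id]
            a.reference_id = tid[rec.contig]
            a.reference_start = rec.position - 1
            a.mapping_quality = rec.mapping_quality
            a.cigarstring = f"{len(seqs[rec.read_id])}M"
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.secondary:
                flag |= 256
            a.flag = flag
            a.set_tag("AS", rec.alignment_score)
            out.write(a)
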