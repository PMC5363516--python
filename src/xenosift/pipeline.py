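"""End-to-end orchestration: simulate → classify → call → extract →
spectrum → purity, with a flat-file run configuration and a machine-readable
JSON run report.

Two entry points matter: :func:`run_pipeline` executes the full synthetic
study under the binomial count model (deep pileups for normal, primary and
PDX, somatic calling in both tumors, sharing classification, spectra, purity
estimates), and :func:`uncleaned_vs_cleaned_report` runs read-level PDX
somatic calling twice — with and without mouse-read decontamination — to
quantify what host contamination does to a naive caller.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from typing import Dict, List, Mapping, Optional, Tuple

from . import __version__
from .mutation_extractor import (
    classify_all,
    comparison_table,
    extract_mutation_reads,
    scatter_table,
    sharing_summary,
    union_sites,
)
from .pileup import pileup_from_reads
from .purity_model import purity_from_vafs
from .signature_spectrum import spectrum_from_comparisons
from .somatic_filters import FilterThresholds, call_somatic
from .species_filter import classify_reads, filter_reads
from .synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    alignments_for_reads,
    simulate_cohort,
    simulate_pileups,
    simulate_sample_reads,
)

logger = logging.getLogger("xenosift")


@dataclass(frozen=True)
class RunConfig:
    """Flat union of every stage's knobs plus the seed.

    ``from_file`` reads a plain ``key: value`` text file; unknown keys are
    rejected so silent typos cannot change a run.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    presence_min_alt_reads: int = 2
    min_coverage: int = 20

    @staticmethod
    def defaults_text() -> str:
        cfg = RunConfig()
        lines = []
        for f in fields(SimulationConfig):
            if f.name == "artifact_spec":
                continue
            lines.append(f"{f.name}: {getattr(cfg.simulation, f.name)}")
        for cls in ("germline_leak", "strand_bias", "low_bq", "low_mq",
                    "homopolymer_indel"):
            lines.append(f"artifact_{cls}: 0")
        for f in fields(FilterThresholds):
            lines.append(f"{f.name}: {getattr(cfg.thresholds, f.name)}")
        lines.append(f"presence_min_alt_reads: {cfg.presence_min_alt_reads}")
        lines.append(f"min_coverage: {cfg.min_coverage}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise ConfigurationError(f"malformed config line: {line!r}")
                key, value = (part.strip() for part in line.split(":", 1))
                if key in raw:
                    raise ConfigurationError(f"duplicate config key: {key}")
                raw[key] = value
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, str]) -> "RunConfig":
        sim_fields = {f.name: f for f in fields(SimulationConfig)}
        thr_fields = {f.name: f for f in fields(FilterThresholds)}
        sim_kwargs: Dict[str, object] = {}
        thr_kwargs: Dict[str, object] = {}
        extras: Dict[str, int] = {}
        artifact_spec: Dict[str, int] = {}
        for key, value in raw.items():
            if key.startswith("artifact_"):
                artifact_spec[key[len("artifact_"):]] = int(value)
            elif key in sim_fields and key != "artifact_spec":
                typ = sim_fields[key].type
                sim_kwargs[key] = float(value) if typ == "float" else int(value)
            elif key in thr_fields:
                typ = thr_fields[key].type
                thr_kwargs[key] = float(value) if typ == "float" else int(value)
            elif key in ("presence_min_alt_reads", "min_coverage"):
                extras[key] = int(value)
            else:
                raise ConfigurationError(f"unknown config key: {key}")
        from .synthetic_data import ARTIFACT_CLASSES

        for cls_name in artifact_spec:
            if cls_name not in ARTIFACT_CLASSES:
                raise ConfigurationError(f"unknown artifact class {cls_name!r}")
        artifact_spec = {k: v for k, v in artifact_spec.items() if v != 0}
        if artifact_spec:
            sim_kwargs["artifact_spec"] = artifact_spec
        return cls(
            simulation=SimulationConfig(**sim_kwargs),
            thresholds=FilterThresholds(**thr_kwargs),
            **extras,
        )

    def echo(self) -> Dict[str, object]:
        sim = dataclasses.asdict(self.simulation)
        sim["artifact_spec"] = dict(sim.get("artifact_spec") or {})
        return {
            "simulation": sim,
            "thresholds": dataclasses.asdict(self.thresholds),
            "presence_min_alt_reads": self.presence_min_alt_reads,
            "min_coverage": self.min_coverage,
        }


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Full synthetic study under the count model; returns the run report
    (a JSON-serializable dict; no timestamps, so identical configs reproduce
    identical reports)."""
    sim = config.simulation
    logger.info("simulating cohort (seed=%d)", sim.seed)
    refs, truth = simulate_cohort(sim)
    pileups = simulate_pileups(truth, sim)

    logger.info("somatic calling: primary")
    kept_primary, _, tally_primary = call_somatic(
        pileups["primary"], pileups["normal"], config.thresholds, refs.human
    )
    logger.info("somatic calling: pdx")
    kept_pdx, _, tally_pdx = call_somatic(
        pileups["pdx"], pileups["normal"], config.thresholds, refs.human
    )

    sites = union_sites(
        [v.key for v in kept_primary], [v.key for v in kept_pdx]
    )
    comparisons = classify_all(
        extract_mutation_reads(
            sites, pileups["primary"], pileups["pdx"],
            {refs.human_contig: len(refs.human)},
        ),
        min_alt_reads=config.presence_min_alt_reads,
        min_coverage=config.min_coverage,
    )
    summary = sharing_summary(comparisons)
    spect = spectrum_from_comparisons(comparisons)

    scatter = scatter_table(comparisons)
    purity_est: Dict[str, Optional[float]] = {}
    for sample, col in (("primary", "primary_vaf"), ("pdx", "pdx_vaf")):
        vafs = scatter.loc[~scatter["low_coverage"], col] if not scatter.empty else []
        try:
            est, _mode = purity_from_vafs(list(vafs))
            purity_est[sample] = round(est, 4)
        except ValueError as exc:
            purity_est[sample] = None
            logger.warning("purity estimate unavailable for %s: %s", sample, exc)

    report = {
        "tool": "xenosift",
        "version": __version__,
        "config": config.echo(),
        "stages": {
            "simulate": {
                "n_mutations": len(truth.mutations),
                "n_artifacts": len(truth.artifacts()),
                "true_sharing_counts": dict(truth.sharing_counts()),
            },
            "call_primary": {
                "kept": len(kept_primary),
                "rejections": dict(tally_primary),
            },
            "call_pdx": {"kept": len(kept_pdx), "rejections": dict(tally_pdx)},
            "extract": {"n_sites": len(sites)},
            "sharing": summary.to_dict(orient="records"),
            "spectrum": spect.fillna(-1).to_dict(orient="records"),
            "tier": {"skipped": "no gene/protein-change annotations supplied"},
            "purity": purity_est,
        },
    }
    return report


@dataclass
class PipelineResult:
    """In-memory artifacts of a full synthetic run, for library callers."""

    refs: object
    truth: object
    pileups: Dict[str, dict]
    comparisons: List
    report: Dict[str, object]


def run_pipeline_detailed(config: RunConfig) -> PipelineResult:
    sim = config.simulation
    refs, truth = simulate_cohort(sim)
    pileups = simulate_pileups(truth, sim)
    kept_primary, _, _ = call_somatic(
        pileups["primary"], pileups["normal"], config.thresholds, refs.human
    )
    kept_pdx, _, _ = call_somatic(
        pileups["pdx"], pileups["normal"], config.thresholds, refs.human
    )
    sites = union_sites([v.key for v in kept_primary], [v.key for v in kept_pdx])
    comparisons = classify_all(
        extract_mutation_reads(sites, pileups["primary"], pileups["pdx"]),
        min_alt_reads=config.presence_min_alt_reads,
        min_coverage=config.min_coverage,
    )
    report = run_pipeline(config)
    return PipelineResult(refs, truth, pileups, comparisons, report)


def _call_snvs_from_reads(reads, normal_reads, refs, thresholds):
    tumor_arr = pileup_from_reads(reads, refs.human, refs.human_contig)
    normal_arr = pileup_from_reads(normal_reads, refs.human, refs.human_contig)
    loci = tumor_arr.candidate_loci(min_alt=thresholds.min_alt_reads)
    tumor = tumor_arr.sites(loci)
    normal = normal_arr.sites(loci)
    kept, verdicts, tally = call_somatic(tumor, normal, thresholds)
    return kept, tally


def uncleaned_vs_cleaned_report(config: RunConfig) -> Dict[str, object]:
    """Somatic calling on a contaminated synthetic PDX, with and without the
    species filter, compared Venn-style against the primary tumor's calls
    and the truth ledger."""
    sim = config.simulation
    refs, truth = simulate_cohort(sim)

    normal_reads, _ = simulate_sample_reads(refs, truth, sim, "normal")
    primary_reads, _ = simulate_sample_reads(refs, truth, sim, "primary")
    pdx_reads, _ = simulate_sample_reads(refs, truth, sim, "pdx")

    # species classification of PDX reads on the combined reference
    records = alignments_for_reads(pdx_reads, refs)
    calls, summary = classify_reads(records)
    cleaned_reads = filter_reads(pdx_reads, calls)
    call_by_read = {c.read_id: c.call for c in calls}
    n_wrong = sum(
        1
        for r in pdx_reads
        if call_by_read[r.read_id] in ("human", "mouse")
        and call_by_read[r.read_id] != r.species
    )

    kept_primary, _ = _call_snvs_from_reads(
        primary_reads, normal_reads, refs, config.thresholds
    )
    kept_uncleaned, _ = _call_snvs_from_reads(
        pdx_reads, normal_reads, refs, config.thresholds
    )
    kept_cleaned, _ = _call_snvs_from_reads(
        cleaned_reads, normal_reads, refs, config.thresholds
    )

    primary_set = {v.key for v in kept_primary}
    uncleaned_set = {v.key for v in kept_uncleaned}
    cleaned_set = {v.key for v in kept_cleaned}
    truth_pdx = {
        (m.contig, m.position, m.ref, m.alt)
        for m in truth.sample_mutations("pdx")
        if not m.is_indel and m.artifact is None
    }

    return {
        "tool": "xenosift",
        "version": __version__,
        "config": config.echo(),
        "species_summary": {
            "total_reads": summary.total_reads,
            "calls": dict(summary.calls),
            "misclassified_reads": n_wrong,
            "mapped_fraction_strict": summary.mapped_fraction_strict,
            "mapped_fraction_lenient": summary.mapped_fraction_lenient,
        },
        "primary_calls": len(primary_set),
        "uncleaned": {
            "calls": len(uncleaned_set),
            "overlap_with_primary": len(uncleaned_set & primary_set),
            "excess_over_truth": len(uncleaned_set - truth_pdx),
        },
        "cleaned": {
            "calls": len(cleaned_set),
            "overlap_with_primary": len(cleaned_set & primary_set),
            "excess_over_truth": len(cleaned_set - truth_pdx),
            "missed_truth": len(truth_pdx - cleaned_set),
        },
        "truth_pdx_mutations": len(truth_pdx),
    }


def write_report(report: Dict[str, object], path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
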