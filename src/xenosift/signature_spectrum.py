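"""Six-class substitution spectra per sharing group.

Each SNV is collapsed onto a pyrimidine reference base: a substitution whose
reference is a purine (A or G) is reported as its reverse complement, giving
the standard six classes C>A, C>G, C>T, T>A, T>C, T>G.  Spectra are tabulated
separately for the common / primary-only / PDX-only sharing groups so shifts
in mutational process between primary tumor and xenograft become visible.
Indels are excluded; only trinucleotide-free class-level spectra are
computed.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

GROUPS = ("common", "primary_only", "pdx_only")


def substitution_class(ref: str, alt: str) -> str:
    """Collapse an SNV to its pyrimidine-referenced class (G>A → C>T etc.)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("indels are excluded from substitution spectra")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum(
    mutations: Iterable[Tuple[str, str, str]],
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Per-group class counts and fractions.

    ``mutations`` yields (ref, alt, group) triples; non-SNV entries are
    skipped.  Groups with zero SNVs produce zero-count rows with NaN
    fractions rather than division errors.
    """
    counts = {g: {c: 0 for c in SUBSTITUTION_CLASSES} for g in groups}
    for ref, alt, group in mutations:
        if group not in counts:
            continue
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            continue
        counts[group][substitution_class(ref, alt)] += 1
    rows = []
    for g in groups:
        total = sum(counts[g].values())
        for cls in SUBSTITUTION_CLASSES:
            rows.append(
                {
                    "group": g,
                    "class": cls,
                    "count": counts[g][cls],
                    "fraction": counts[g][cls] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def spectrum_from_comparisons(comparisons) -> pd.DataFrame:
    """Spectrum straight from classified MutationComparison records."""
    triples = [
        (c.ref, c.alt, c.sharing)
        for c in comparisons
        if c.sharing in GROUPS and len(c.ref) == 1 and not c.alt.startswith(("+", "-"))
    ]
    return spectrum(triples)


def fraction_vector(table: pd.DataFrame, group: str) -> np.ndarray:
    sub = table[table["group"] == group].set_index("class")
    vec = sub.loc[list(SUBSTITUTION_CLASSES), "fraction"].to_numpy(dtype=float)
    if np.isnan(vec).all():
        raise ValueError(f"group {group!r} has no SNVs")
    return np.nan_to_num(vec)


def compare_spectra(frac_a: np.ndarray, frac_b: np.ndarray) -> float:
    """Cosine similarity of two spectrum fraction vectors, in [0, 1]."""
    a = np.asarray(frac_a, dtype=float)
    b = np.asarray(frac_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("spectra must be non-empty and of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot compare an all-zero spectrum")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def write_spectrum(table: pd.DataFrame, tsv_path, plot_path=None) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    if plot_path is not None:
        plot_spectrum(table, plot_path)


def plot_spectrum(table: pd.DataFrame, path) -> None:
    """Stacked-bar class fractions, one bar per sharing group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g in GROUPS if g in set(table["group"])]
    fig, ax = plt.subplots(figsize=(5, 4))
    bottom = np.zeros(len(groups))
    for cls in SUBSTITUTION_CLASSES:
        vals = np.array(
            [
                float(
                    table[(table["group"] == g) & (table["class"] == cls)][
                        "fraction"
                    ].fillna(0.0).iloc[0]
                )
                for g in groups
            ]
        )
        ax.bar(groups, vals, bottom=bottom, label=cls)
        bottom += vals
    ax.set_ylabel("fraction of SNVs")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
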