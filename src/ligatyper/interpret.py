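"""Inheritance-aware interpretation of genotype call matrices.

Per-sample diagnosis applies the gene's inheritance mode: autosomal
recessive genes explain the phenotype only with two mutant alleles (a
homozygote, or two heterozygous variants in the same gene whose phase is
unknown without parental data); a homoplasmic mitochondrial variant,
one dominant-gene variant, or an X-linked variant is sufficient on its
own; a single recessive het is a carrier finding.  Cohort summaries count
variant-carrier "entries" — one per (sample, variant) with a non-reference
call — which is the tally that keeps per-variant frequencies, per-gene
counts, the overall detection rate and the het/hom split mutually
consistent; deduplicated patient-level counts are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .panel import Panel

__all__ = [
    "CATEGORIES",
    "DiagnosticReport",
    "CohortSummary",
    "InterpretError",
    "classify_sample",
    "classify_matrix",
    "summarize_cohort",
    "compound_het_table",
    "gene_share",
]

CATEGORIES = (
    "confirmed_homozygous",
    "confirmed_mt",
    "possible_compound_het_phase_unknown",
    "ad_positive",
    "xl_positive",
    "carrier_monoallelic",
    "negative",
)

_HET = ("0/1", "0/2")
_HOM = ("1/1", "2/2")


class InterpretError(ValueError):
    """Raised for empty cohorts or missing loci."""


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-sample diagnosis: exactly one category plus the calls behind it."""

    sample_id: str
    category: str
    supporting: tuple[tuple[str, str], ...] = ()  # (variant name, GT)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InterpretError(f"unknown category {self.category!r}")


def classify_sample(calls: pd.Series, panel: Panel) -> DiagnosticReport:
    """Classify one sample's GT vector (indexed by variant name).

    Precedence: recessive homozygote > homoplasmic mitochondrial >
    same-gene double het (possible compound het, phase unknown) >
    dominant-gene positive > X-linked positive > single recessive het
    (carrier) > negative.  A heteroplasmic mitochondrial call counts at
    carrier level.  Every panel locus must be present (no-calls are
    allowed and contribute nothing).
    """
    missing = [n for n in panel.variant_names if n not in calls.index]
    if missing:
        raise InterpretError(f"calls missing panel loci: {missing}")
    sample_id = str(calls.name) if calls.name is not None else ""

    hom = [(v.name, calls[v.name]) for v in panel.variants if calls[v.name] in _HOM]
    het = [(v.name, calls[v.name]) for v in panel.variants if calls[v.name] in _HET]
    mode = {v.name: v.inheritance for v in panel.variants}

    ar_hom = [x for x in hom if mode[x[0]] == "AR"]
    if ar_hom:
        return DiagnosticReport(sample_id, "confirmed_homozygous", tuple(ar_hom))
    mt_hom = [x for x in hom if mode[x[0]] == "MT"]
    if mt_hom:
        return DiagnosticReport(sample_id, "confirmed_mt", tuple(mt_hom))

    ar_het = [x for x in het if mode[x[0]] == "AR"]
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for name, gt in ar_het:
        by_gene.setdefault(panel.gene_of(name), []).append((name, gt))
    doubled = [g for g, members in by_gene.items() if len(members) >= 2]
    if doubled:
        support = tuple(x for g in doubled for x in by_gene[g])
        return DiagnosticReport(
            sample_id, "possible_compound_het_phase_unknown", support
        )

    ad = [x for x in hom + het if mode[x[0]] == "AD"]
    if ad:
        return DiagnosticReport(sample_id, "ad_positive", tuple(ad))
    xl = [x for x in hom + het if mode[x[0]] == "XL"]
    if xl:
        return DiagnosticReport(sample_id, "xl_positive", tuple(xl))

    carrier = ar_het + [x for x in het if mode[x[0]] == "MT"]
    if carrier:
        return DiagnosticReport(sample_id, "carrier_monoallelic", tuple(carrier))
    return DiagnosticReport(sample_id, "negative")


def classify_matrix(calls: pd.DataFrame, panel: Panel) -> pd.Series:
    """Category per sample for a sample-by-variant GT matrix."""
    return pd.Series(
        {
            sid: classify_sample(row, panel).category
            for sid, row in calls.iterrows()
        },
        name="category",
    )


@dataclass
class CohortSummary:
    """Cohort-level tallies over a call matrix.

    ``per_variant`` has one row per panel variant (gene, chromosome, hom
    and het entry counts, frequency % = (hom+het)/n).  Rates are entry
    counts over the cohort size, in percent; ``diagnostic_yield`` is the
    share of samples whose genotype alone confirms the phenotype
    (recessive homozygote or homoplasmic mitochondrial).
    """

    n: int
    per_variant: pd.DataFrame
    per_gene: pd.Series
    compound_pairs: list[tuple[str, str, str, int]]
    detection_rate: float
    diagnostic_yield: float
    het_entry_rate: float
    hom_entry_rate: float
    n_carrier_samples: int  # deduplicated patient-level carrier count
    categories: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def total_entries(self) -> int:
        return int(self.per_variant["hom"].sum() + self.per_variant["het"].sum())

    def to_tsv(self) -> str:
        lines = ["Gene\tChromosome\tNucleotide change\tHomozygous\tHeterozygous\tFrequency"]
        for name, row in self.per_variant.iterrows():
            lines.append(
                f"{row['gene']}\t{row['chromosome']}\t{name}\t"
                f"{int(row['hom'])}\t{int(row['het'])}\t{row['frequency']:.2f}%"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "detection_rate": self.detection_rate,
            "diagnostic_yield": self.diagnostic_yield,
            "het_entry_rate": self.het_entry_rate,
            "hom_entry_rate": self.hom_entry_rate,
            "n_carrier_samples": self.n_carrier_samples,
            "total_entries": self.total_entries,
            "per_variant": {
                name: {
                    "gene": row["gene"],
                    "hom": int(row["hom"]),
                    "het": int(row["het"]),
                    "frequency": row["frequency"],
                }
                for name, row in self.per_variant.iterrows()
            },
            "per_gene": {g: int(c) for g, c in self.per_gene.items()},
            "compound_het": [
                {"variant_a": a, "variant_b": b, "gene": g, "count": k}
                for a, b, g, k in self.compound_pairs
            ],
            "categories": {
                str(c): int(k) for c, k in self.categories.value_counts().items()
            },
        }


def summarize_cohort(calls: pd.DataFrame, panel: Panel) -> CohortSummary:
    """Tally a sample-by-variant GT matrix into a cohort summary."""
    n = len(calls)
    if n == 0:
        raise InterpretError("empty cohort")
    missing = [v for v in panel.variant_names if v not in calls.columns]
    if missing:
        raise InterpretError(f"call matrix missing panel loci: {missing}")

    rows = []
    for v in panel.variants:
        col = calls[v.name]
        hom = int(col.isin(_HOM).sum())
        het = int(col.isin(_HET).sum())
        rows.append(
            {
                "gene": v.gene,
                "chromosome": v.chromosome,
                "hom": hom,
                "het": het,
                "frequency": 100.0 * (hom + het) / n,
            }
        )
    per_variant = pd.DataFrame(rows, index=panel.variant_names)
    entries = per_variant["hom"] + per_variant["het"]
    per_gene = entries.groupby(per_variant["gene"]).sum().astype(int)

    categories = classify_matrix(calls, panel)
    confirmed = categories.isin(["confirmed_homozygous", "confirmed_mt"]).sum()
    carrier_mask = calls.isin(_HET + _HOM).any(axis=1)

    return CohortSummary(
        n=n,
        per_variant=per_variant,
        per_gene=per_gene,
        compound_pairs=compound_het_table(calls, panel),
        detection_rate=100.0 * int(entries.sum()) / n,
        diagnostic_yield=100.0 * int(confirmed) / n,
        het_entry_rate=100.0 * int(per_variant["het"].sum()) / n,
        hom_entry_rate=100.0 * int(per_variant["hom"].sum()) / n,
        n_carrier_samples=int(carrier_mask.sum()),
        categories=categories,
    )


def compound_het_table(
    calls: pd.DataFrame, panel: Panel
) -> list[tuple[str, str, str, int]]:
    """Count samples heterozygous at both members of each same-gene pair.

    Returns (variantA, variantB, gene, count), sorted by gene then count
    descending; pairs with zero dual-het samples are omitted.
    """
    out = []
    by_gene: dict[str, list[str]] = {}
    for v in panel.variants:
        if v.name in calls.columns:
            by_gene.setdefault(v.gene, []).append(v.name)
    for gene, names in by_gene.items():
        for a, b in combinations(names, 2):
            k = int((calls[a].isin(_HET) & calls[b].isin(_HET)).sum())
            if k:
                out.append((a, b, gene, k))
    out.sort(key=lambda t: (t[2], -t[3], t[0], t[1]))
    return out


def gene_share(summary: CohortSummary, gene: str, variant: str) -> float:
    """Percent of a gene's variant entries attributable to one variant."""
    if variant not in summary.per_variant.index:
        raise InterpretError(f"unknown variant {variant!r}")
    total = int(summary.per_gene.get(gene, 0))
    if total == 0:
        raise InterpretError(f"gene {gene!r} has no variant entries")
    row = summary.per_variant.loc[variant]
    if row["gene"] != gene:
        raise InterpretError(f"{variant!r} is not a {gene} variant")
    return 100.0 * (int(row["hom"]) + int(row["het"])) / total
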