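"""Domain model of a multiplex ligation-genotyping panel.

A panel is a set of target variants, each assayed by a triple of ligation
probes (two allele-specific 5' probes carrying dye tags, one common 3'
probe).  A successful double ligation yields one dye-labelled fragment per
allele; the pair (dye channel, electrophoretic size) is the 2-D address by
which a product is decoded.  Four dye channels (B, G, Y, R) and a stuffer
sequence on the 3' probe give the layout designer two axes to keep all
products of a panel separable on a capillary run.

This module holds the panel data model, layout validity checking, JSON
round-trip I/O, and the built-in 32-variant hereditary hearing-loss panel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "DYES",
    "INHERITANCE_MODES",
    "Variant",
    "LigationProbeSet",
    "LigationProduct",
    "Panel",
    "PanelError",
    "builtin_panel_hl32",
    "validate_layout",
    "expected_products",
    "load_panel",
    "write_panel",
    "panel_to_dict",
    "panel_from_dict",
    "panel_to_tsv",
]

#: the four fluorescence channels of a standard 4-dye fragment run,
#: in canonical order (blue, green, yellow, red)
DYES = ("B", "G", "Y", "R")

#: recognised inheritance modes: autosomal recessive / dominant,
#: X-linked, mitochondrial (maternal)
INHERITANCE_MODES = ("AR", "AD", "XL", "MT")


class PanelError(ValueError):
    """Raised for invalid panel definitions (schema, duplicates, layout)."""


@dataclass(frozen=True)
class Variant:
    """One panel target locus.

    Variants are keyed by their printed nucleotide-change name (HGVS-like
    or legacy intron notation); no genomic coordinates are modelled.
    ``alt_alleles`` usually holds one allele; a tri-allelic locus (one site,
    two pathogenic changes) holds two.  ``"-"`` denotes a deletion allele.
    """

    gene: str
    chromosome: str
    name: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    dbsnp_id: str | None = None
    inheritance: str = "AR"

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise PanelError(
                f"{self.name}: unknown inheritance {self.inheritance!r}"
            )
        if not self.alt_alleles:
            raise PanelError(f"{self.name}: no alt allele")
        for alt in self.alt_alleles:
            if alt == self.ref_allele:
                raise PanelError(f"{self.name}: ref and alt alleles are equal")
        if (self.chromosome == "mtDNA") != (self.inheritance == "MT"):
            raise PanelError(
                f"{self.name}: mtDNA chromosome and MT inheritance must agree"
            )

    @property
    def alt_allele(self) -> str:
        """Primary alternate allele (first of ``alt_alleles``)."""
        return self.alt_alleles[0]

    @property
    def is_mitochondrial(self) -> bool:
        return self.inheritance == "MT"

    def allele_keys(self) -> tuple[str, ...]:
        """Product slots for this locus: ``ref``, ``alt`` [, ``alt2``]."""
        keys = ["ref", "alt"]
        if len(self.alt_alleles) > 1:
            keys.append("alt2")
        return tuple(keys)

    def allele_seq(self, key: str) -> str:
        if key == "ref":
            return self.ref_allele
        if key == "alt":
            return self.alt_alleles[0]
        if key == "alt2" and len(self.alt_alleles) > 1:
            return self.alt_alleles[1]
        raise KeyError(key)


@dataclass(frozen=True)
class LigationProbeSet:
    """The probe triple assaying one variant (design-level object).

    Each 5' probe is a dye tag followed by an allele-specific anneal region
    whose 3' terminus sits on the variant site; the common 3' probe anneals
    immediately downstream and carries the size-shifting stuffer.
    """

    variant: Variant
    probe5_by_allele: dict[str, dict[str, str]]  # allele key -> {dye_tag_seq, allele_specific_seq}
    probe3_anneal_seq: str
    stuffer_len: int = 0
    amplicon_id: str = ""

    def __post_init__(self) -> None:
        if self.stuffer_len < 0:
            raise PanelError(f"{self.variant.name}: negative stuffer length")
        tags = [p["dye_tag_seq"] for p in self.probe5_by_allele.values()]
        if len(set(tags)) != len(tags):
            raise PanelError(
                f"{self.variant.name}: allele probes share a dye tag"
            )
        seqs = [p["allele_specific_seq"] for p in self.probe5_by_allele.values()]
        if len(set(seqs)) != len(seqs):
            raise PanelError(
                f"{self.variant.name}: allele probes do not differ at the 3' end"
            )

    def natural_length(self, allele: str) -> int:
        """Ligation-product length before any stuffer is added."""
        p5 = self.probe5_by_allele[allele]
        return (
            len(p5["dye_tag_seq"])
            + len(p5["allele_specific_seq"])
            + len(self.probe3_anneal_seq)
        )


@dataclass(frozen=True)
class LigationProduct:
    """One decodable fragment: a (dye, expected size) point for one allele."""

    variant_name: str
    allele: str  # "ref" | "alt" | "alt2"
    dye: str
    expected_size: float

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise PanelError(f"{self.variant_name}: unknown dye {self.dye!r}")
        if self.expected_size <= 0:
            raise PanelError(f"{self.variant_name}: non-positive product size")


@dataclass
class Panel:
    """A complete, decodable multiplex panel.

    ``layout`` maps variant name -> allele key -> (dye, expected size).
    ``amplicons`` groups variant names into the multiplex-PCR fragments
    that cover them.  ``tolerance`` is the sizing tolerance (nt) at which
    the layout must be collision-free: two products on the same dye must
    be at least ``2 * tolerance`` apart.
    """

    name: str
    variants: list[Variant]
    layout: dict[str, dict[str, tuple[str, float]]]
    size_range: tuple[float, float] = (80.0, 260.0)
    tolerance: float = 1.5
    dye_set: tuple[str, ...] = DYES
    amplicons: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    probesets: dict[str, LigationProbeSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variants]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise PanelError(f"duplicate variant names: {sorted(dups)}")
        missing = [n for n in names if n not in self.layout]
        if missing:
            raise PanelError(f"variants without layout: {missing}")

    def variant(self, name: str) -> Variant:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(f"unknown variant {name!r}")

    @property
    def variant_names(self) -> list[str]:
        return [v.name for v in self.variants]

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for v in self.variants:
            if v.gene not in seen:
                seen.append(v.gene)
        return seen

    @property
    def products(self) -> list[LigationProduct]:
        out: list[LigationProduct] = []
        for v in self.variants:
            for key in v.allele_keys():
                dye, size = self.layout[v.name][key]
                out.append(LigationProduct(v.name, key, dye, size))
        return out

    def gene_of(self, variant_name: str) -> str:
        return self.variant(variant_name).gene


def validate_layout(
    panel: Panel, size_tolerance: float | None = None
) -> list[dict]:
    """Check the dye/size layout for decoding collisions.

    Returns one record per pair of products sharing a dye whose expected
    sizes differ by less than ``2 * size_tolerance`` (at that spacing a
    measured peak within +/- tolerance of one product could also match the
    other).  An empty list means the layout is decodable.  Products lying
    outside ``panel.size_range`` raise :class:`PanelError`.
    """
    tol = panel.tolerance if size_tolerance is None else size_tolerance
    lo, hi = panel.size_range
    products = panel.products
    for p in products:
        if not (lo <= p.expected_size <= hi):
            raise PanelError(
                f"product {p.variant_name}/{p.allele} at {p.expected_size} nt "
                f"outside size range [{lo}, {hi}]"
            )
    collisions: list[dict] = []
    by_dye: dict[str, list[LigationProduct]] = {}
    for p in products:
        by_dye.setdefault(p.dye, []).append(p)
    for dye, group in by_dye.items():
        group = sorted(group, key=lambda p: (p.expected_size, p.variant_name, p.allele))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.expected_size - a.expected_size >= 2 * tol:
                    break  # sorted: no later product can collide with a
                collisions.append(
                    {
                        "dye": dye,
                        "a": (a.variant_name, a.allele, a.expected_size),
                        "b": (b.variant_name, b.allele, b.expected_size),
                        "delta": abs(b.expected_size - a.expected_size),
                    }
                )
    return collisions


def expected_products(
    panel: Panel, variant_name: str
) -> tuple[LigationProduct, ...]:
    """The expected fragments for one variant: (ref, alt[, alt2])."""
    v = panel.variant(variant_name)  # raises KeyError if unknown
    out = []
    for key in v.allele_keys():
        dye, size = panel.layout[v.name][key]
        out.append(LigationProduct(v.name, key, dye, size))
    return tuple(out)


# ---------------------------------------------------------------------------
# JSON serialisation


def panel_to_dict(panel: Panel) -> dict:
    variants = []
    for v in panel.variants:
        keys = v.allele_keys()
        alt_keys = keys[1:]
        entry = {
            "gene": v.gene,
            "chrom": v.chromosome,
            "name": v.name,
            "ref": v.ref_allele,
            "alt": list(v.alt_alleles) if len(v.alt_alleles) > 1 else v.alt_allele,
            "rs": v.dbsnp_id,
            "inheritance": v.inheritance,
            "dye_ref": panel.layout[v.name]["ref"][0],
            "size_ref": panel.layout[v.name]["ref"][1],
            "dye_alt": [panel.layout[v.name][k][0] for k in alt_keys]
            if len(alt_keys) > 1
            else panel.layout[v.name]["alt"][0],
            "size_alt": [panel.layout[v.name][k][1] for k in alt_keys]
            if len(alt_keys) > 1
            else panel.layout[v.name]["alt"][1],
            "amplicon": _amplicon_of(panel, v.name),
        }
        variants.append(entry)
    return {
        "name": panel.name,
        "size_range": list(panel.size_range),
        "tolerance": panel.tolerance,
        "dyes": list(panel.dye_set),
        "variants": variants,
        "notes": list(panel.notes),
    }


def _amplicon_of(panel: Panel, variant_name: str) -> str:
    for amp, names in panel.amplicons.items():
        if variant_name in names:
            return amp
    return ""


def panel_from_dict(doc: dict) -> Panel:
    for req in ("name", "size_range", "tolerance", "dyes", "variants"):
        if req not in doc:
            raise PanelError(f"panel JSON missing field {req!r}")
    variants: list[Variant] = []
    layout: dict[str, dict[str, tuple[str, float]]] = {}
    amplicons: dict[str, list[str]] = {}
    for i, entry in enumerate(doc["variants"]):
        for req in ("gene", "chrom", "name", "ref", "alt", "inheritance",
                    "dye_ref", "dye_alt", "size_ref", "size_alt"):
            if req not in entry:
                raise PanelError(f"variant #{i}: missing field {req!r}")
        alts = entry["alt"]
        alts = tuple(alts) if isinstance(alts, list) else (alts,)
        v = Variant(
            gene=entry["gene"],
            chromosome=entry["chrom"],
            name=entry["name"],
            ref_allele=entry["ref"],
            alt_alleles=alts,
            dbsnp_id=entry.get("rs"),
            inheritance=entry["inheritance"],
        )
        if v.name in layout:
            raise PanelError(f"duplicate variant name {v.name!r}")
        dyes_alt = entry["dye_alt"]
        sizes_alt = entry["size_alt"]
        if not isinstance(dyes_alt, list):
            dyes_alt, sizes_alt = [dyes_alt], [sizes_alt]
        lay = {"ref": (entry["dye_ref"], float(entry["size_ref"]))}
        for key, dye, size in zip(v.allele_keys()[1:], dyes_alt, sizes_alt):
            lay[key] = (dye, float(size))
        variants.append(v)
        layout[v.name] = lay
        amp = entry.get("amplicon") or ""
        if amp:
            amplicons.setdefault(amp, []).append(v.name)
    panel = Panel(
        name=doc["name"],
        variants=variants,
        layout=layout,
        size_range=tuple(doc["size_range"]),
        tolerance=float(doc["tolerance"]),
        dye_set=tuple(doc["dyes"]),
        amplicons=amplicons,
        notes=list(doc.get("notes", [])),
    )
    collisions = validate_layout(panel)  # also range-checks products
    if collisions:
        raise PanelError(
            f"layout has {len(collisions)} same-dye size collision(s) at "
            f"tolerance {panel.tolerance}; first: {collisions[0]}"
        )
    return panel


def write_panel(panel: Panel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(panel_to_dict(panel), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_panel(path) -> Panel:
    with open(path, encoding="utf-8") as fh:
        return panel_from_dict(json.load(fh))


def panel_to_tsv(panel: Panel) -> str:
    """Tab-separated export mirroring a published panel table's columns."""
    lines = ["Gene\tChromosome\tNucleotide change\tAllelic Change\tdbSNP rs#"]
    for v in panel.variants:
        change = ";".join(f"{v.ref_allele}/{a}" for a in v.alt_alleles)
        lines.append(
            f"{v.gene}\t{v.chromosome}\t{v.name}\t{change}\t{v.dbsnp_id or ''}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Built-in 32-variant hereditary hearing-loss panel
#
# Gene, chromosome label, printed variant name, ref, alt allele(s), rs id.
# Inheritance: AR for GJB2/GJB3/SLC26A4, MT for MT-RNR1, AD for the
# Waardenburg genes (PAX3/MITF/SOX10) and COCH/CEACAM16, XL for POU3F4.
# The COCH c.1625 row is one tri-allelic locus (G>A and G>T at one site).

_HL32_ROWS: list[tuple[str, str, str, str, tuple[str, ...], str | None, str]] = [
    ("GJB2", "13", "IVS1+1G>A", "G", ("A",), "rs80338940", "AR"),
    ("GJB2", "13", "c.35delG", "G", ("-",), "rs80338939", "AR"),
    ("GJB2", "13", "c.71G>A", "G", ("A",), "rs104894396", "AR"),
    ("GJB2", "13", "c.139G>T", "G", ("T",), "rs104894398", "AR"),
    ("GJB2", "13", "c.167delT", "T", ("-",), "rs80338942", "AR"),
    ("GJB2", "13", "c.176_191del16", "GCTGCAAGAACGTGTG", ("-",), None, "AR"),
    ("GJB2", "13", "c.235delC", "C", ("-",), "rs80338943", "AR"),
    ("GJB2", "13", "c.299_300delAT", "AT", ("-",), None, "AR"),
    ("GJB2", "13", "c.571T>G", "T", ("G",), None, "AR"),
    ("GJB2", "13", "c.596C>T", "C", ("T",), None, "AR"),
    ("GJB3", "1", "c.538C>T", "C", ("T",), "rs74315319", "AR"),
    ("GJB3", "1", "c.547G>A", "G", ("A",), None, "AR"),
    ("GJB3", "1", "c.580G>A", "G", ("A",), "rs121908852", "AR"),
    ("SLC26A4", "7", "c.281C>T", "C", ("T",), None, "AR"),
    ("SLC26A4", "7", "IVS7-2A>G", "A", ("G",), None, "AR"),
    ("SLC26A4", "7", "c.1174A>T", "A", ("T",), None, "AR"),
    ("SLC26A4", "7", "c.1226G>A", "G", ("A",), None, "AR"),
    ("SLC26A4", "7", "c.1229C>T", "C", ("T",), None, "AR"),
    ("SLC26A4", "7", "IVS15+5G>A", "G", ("A",), None, "AR"),
    ("SLC26A4", "7", "c.2027T>A", "T", ("A",), None, "AR"),
    ("SLC26A4", "7", "c.2168A>G", "A", ("G",), "rs121908362", "AR"),
    ("MT-RNR1", "mtDNA", "c.1494C>T", "C", ("T",), None, "MT"),
    ("MT-RNR1", "mtDNA", "c.1555A>G", "A", ("G",), None, "MT"),
    ("COCH", "14", "c.151C>T", "C", ("T",), "rs28938175", "AD"),
    ("COCH", "14", "c.1625G>A,c.1625G>T", "G", ("A", "T"), "rs121908933", "AD"),
    ("POU3F4", "X", "c.967C>G", "C", ("G",), "rs104894924", "XL"),
    ("PAX3", "2", "c.812G>A", "G", ("A",), None, "AD"),
    ("MITF", "3", "c.650G>T", "G", ("T",), None, "AD"),
    ("MITF", "3", "c.648_650delAAG", "AAG", ("-",), None, "AD"),
    ("SOX10", "22", "c.113delG", "G", ("-",), None, "AD"),
    ("CEACAM16", "19", "c.505G>A", "G", ("A",), None, "AD"),
    ("CEACAM16", "19", "c.418A>C", "A", ("C",), None, "AD"),
]

# Relative genomic placements (contig, offset in nt) used only to derive the
# 18 multiplex-PCR amplicon groups; the spacings follow the cDNA numbering
# and intron structure, not real coordinates.
_HL32_POSITIONS: dict[str, tuple[str, int]] = {
    "IVS1+1G>A": ("chr13", 0),
    "c.35delG": ("chr13", 3035),
    "c.71G>A": ("chr13", 3071),
    "c.139G>T": ("chr13", 3139),
    "c.167delT": ("chr13", 3167),
    "c.176_191del16": ("chr13", 3176),
    "c.235delC": ("chr13", 3235),
    "c.299_300delAT": ("chr13", 3299),
    "c.571T>G": ("chr13", 3571),
    "c.596C>T": ("chr13", 3596),
    "c.538C>T": ("chr1", 538),
    "c.547G>A": ("chr1", 547),
    "c.580G>A": ("chr1", 580),
    "c.281C>T": ("chr7", 281),
    "IVS7-2A>G": ("chr7", 5000),
    "c.1174A>T": ("chr7", 9000),
    "c.1226G>A": ("chr7", 11000),
    "c.1229C>T": ("chr7", 11003),
    "IVS15+5G>A": ("chr7", 14000),
    "c.2027T>A": ("chr7", 17000),
    "c.2168A>G": ("chr7", 17141),
    "c.1494C>T": ("chrM", 1494),
    "c.1555A>G": ("chrM", 1555),
    "c.151C>T": ("chr14", 151),
    "c.1625G>A,c.1625G>T": ("chr14", 8000),
    "c.967C>G": ("chrX", 967),
    "c.812G>A": ("chr2", 812),
    "c.650G>T": ("chr3", 650),
    "c.648_650delAAG": ("chr3", 648),
    "c.113delG": ("chr22", 113),
    "c.505G>A": ("chr19", 505),
    "c.418A>C": ("chr19", 3418),
}

_HL32_NOTES = [
    "c.571T>G: the source table prints allelic change T/C; the panel uses "
    "T>G per the variant name, which is used consistently elsewhere.",
    "c.1625G>A,c.1625G>T: one tri-allelic COCH locus (ref, altA, altT "
    "products); counted as a single panel target.",
    "Variant names with internal spaces in the source table are normalised "
    "(c.35delG, c.547G>A).",
]

_hl32_cache: Panel | None = None


def builtin_panel_hl32() -> Panel:
    """The built-in 32-variant, 10-gene hereditary hearing-loss panel.

    28 of the targets are nonsyndromic hearing-loss variants and 4 are
    common syndromic (Waardenburg) variants.  The dye/size layout is a
    deterministic first-fit assignment (same-size alleles separated by
    dye, loci separated by size); the 32 targets are covered by 18
    multiplex-PCR amplicon groups.
    """
    global _hl32_cache
    if _hl32_cache is None:
        _hl32_cache = _build_hl32()
    return _hl32_cache


def _build_hl32() -> Panel:
    from .design import DesignParams, assign_layout, group_amplicons

    variants = [
        Variant(gene=g, chromosome=c, name=n, ref_allele=r,
                alt_alleles=a, dbsnp_id=rs, inheritance=inh)
        for g, c, n, r, a, rs, inh in _HL32_ROWS
    ]
    params = DesignParams()
    layout = assign_layout(variants, params)
    with_pos = [
        (v, _HL32_POSITIONS[v.name][0], _HL32_POSITIONS[v.name][1])
        for v in variants
    ]
    groups = group_amplicons(with_pos, max_amplicon_len=600)
    amplicons = {
        amp: [v.name for v in members] for amp, members in groups.items()
    }
    return Panel(
        name="HL32",
        variants=variants,
        layout=layout,
        size_range=(80.0, 260.0),
        tolerance=1.5,
        amplicons=amplicons,
        notes=list(_HL32_NOTES),
    )


def panel_fingerprint(panel: Panel) -> str:
    """SHA-256 of the canonical JSON serialisation (byte-stability checks)."""
    doc = json.dumps(panel_to_dict(panel), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()
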