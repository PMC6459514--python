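"""Probe-set construction and dye/size multiplex layout design.

Each target locus is assayed by two allele-specific 5' probes (dye tag +
anneal region ending on the allele base) and one common 3' probe.  The
layout solver places every ligation product at a (dye channel, size slot)
address so that no two products on the same dye are closer than the
minimum separation — the condition under which a sized peak decodes to a
unique product.  Size is shifted by a stuffer appended to the 3' probe;
Fig-style convention pairs the two alleles of one locus at the same size
on different dyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import SeqIO

from .panel import DYES, LigationProbeSet, PanelError, Variant

__all__ = [
    "DesignParams",
    "DesignError",
    "melting_temperature",
    "design_probe_set",
    "assign_layout",
    "group_amplicons",
    "read_flanks",
]


class DesignError(ValueError):
    """Raised when a probe set or multiplex layout cannot be constructed."""


_DEFAULT_TAGS = (
    "ACGGTCAGTCAA",  # -> dye B
    "TGCACTGACTGG",  # -> dye G
    "CATGGACTTCAG",  # -> dye Y
    "GTACCTGAGGTC",  # -> dye R
)


@dataclass(frozen=True)
class DesignParams:
    """Tunable parameters of probe design and multiplex layout.

    Temperatures in degrees Celsius, lengths in nucleotides.  The four
    ``dye_tag_seqs`` are the fixed 5' tag sequences that route a product
    onto the B/G/Y/R channels via the labelling ligation.
    """

    target_tm: float = 62.0
    tm_window: float = 3.0
    min_probe_len: int = 18
    max_probe_len: int = 35
    dye_tag_seqs: tuple[str, str, str, str] = _DEFAULT_TAGS
    stuffer_step: int = 2
    size_range: tuple[float, float] = (80.0, 260.0)
    min_separation: float = 3.0
    na_mM: float = 50.0
    oligo_nM: float = 250.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_probe_len < 8:
            raise DesignError("min_probe_len must be >= 8")
        if self.stuffer_step < 1:
            raise DesignError("stuffer_step must be >= 1")
        if len(set(self.dye_tag_seqs)) != 4:
            raise DesignError("need 4 distinct dye tag sequences")

    @property
    def slot_pitch(self) -> int:
        """Size-slot spacing: smallest stuffer-step multiple covering the
        minimum same-dye separation."""
        return int(math.ceil(self.min_separation / self.stuffer_step)) * self.stuffer_step


# ---------------------------------------------------------------------------
# Nearest-neighbor melting temperature

# Unified nearest-neighbor parameters (Allawi & SantaLucia 1997):
# (delta-H kcal/mol, delta-S cal/mol/K) per dinucleotide step, 5'->3',
# with the complementary step sharing the same values.
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal (initiation) penalties per duplex end
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)  # self-complementary symmetry correction

_R = 1.987  # gas constant, cal/mol/K

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def melting_temperature(
    seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0
) -> float:
    """Duplex melting temperature (deg C) of ``seq`` with its complement.

    Nearest-neighbor thermodynamics with the unified dinucleotide table,
    terminal A/T and G/C initiation penalties, and the entropic monovalent
    salt correction dS += 0.368 (N-1) ln[Na+].  ``oligo_nM`` is the
    per-strand concentration; for non-self-complementary duplexes the
    effective annealing concentration is half of it.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise DesignError(f"sequence too short for Tm ({len(seq)} < 8 nt)")
    bad = set(seq) - set("ACGT")
    if bad:
        raise DesignError(f"invalid characters in sequence: {sorted(bad)}")

    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = _INIT_AT if end in "AT" else _INIT_GC
        dh += h
        ds += s
    selfcomp = seq == _revcomp(seq)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
        k = oligo_nM * 1e-9
    else:
        k = oligo_nM * 1e-9 / 2.0
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# Probe-set construction


def _fit_anneal(
    candidates: list[str], params: DesignParams, what: str
) -> str:
    """Pick the shortest candidate whose Tm falls in the target window."""
    lo = params.target_tm - params.tm_window
    hi = params.target_tm + params.tm_window
    achieved: list[float] = []
    for cand in candidates:
        tm = melting_temperature(cand, params.na_mM, params.oligo_nM)
        achieved.append(tm)
        if lo <= tm <= hi:
            return cand
    raise DesignError(
        f"{what}: no probe length in [{params.min_probe_len}, "
        f"{params.max_probe_len}] reaches Tm {lo:.1f}-{hi:.1f} C "
        f"(achieved {min(achieved):.1f}-{max(achieved):.1f} C)"
    )


def design_probe_set(
    flank5: str,
    flank3: str,
    variant: Variant,
    params: DesignParams | None = None,
) -> LigationProbeSet:
    """Construct the probe triple for one variant from its flanks.

    ``flank5`` ends immediately 5' of the variant site; ``flank3`` begins
    immediately 3' of it.  SNV alleles are discriminated by the 3'-terminal
    base of the 5' probe; deletion alleles by a probe spanning the deletion
    junction (flank5 followed by the first downstream bases).  Dye tags are
    provisional (allele order); the final dye is set by the layout.
    """
    params = params or DesignParams()
    flank5, flank3 = flank5.upper(), flank3.upper()
    candidates5 = [
        flank5[-n:]
        for n in range(params.min_probe_len, min(params.max_probe_len, len(flank5)) + 1)
    ]
    if not candidates5:
        raise DesignError(f"{variant.name}: 5' flank shorter than min_probe_len")
    anneal5 = _fit_anneal(candidates5, params, f"{variant.name} 5' probe")

    junction = max(1, min(3, len(variant.ref_allele)))
    probe5: dict[str, dict[str, str]] = {}
    for idx, key in enumerate(variant.allele_keys()):
        allele = variant.allele_seq(key)
        if allele == "-":
            # deletion: the allele-specific probe reads across the junction
            if len(flank3) < junction:
                raise DesignError(
                    f"{variant.name}: 3' flank too short for junction probe"
                )
            spec = anneal5 + flank3[:junction]
        else:
            spec = anneal5 + allele
        probe5[key] = {
            "dye_tag_seq": params.dye_tag_seqs[idx],
            "allele_specific_seq": spec,
        }

    candidates3 = [
        flank3[:n]
        for n in range(params.min_probe_len, min(params.max_probe_len, len(flank3)) + 1)
    ]
    if not candidates3:
        raise DesignError(f"{variant.name}: 3' flank shorter than min_probe_len")
    anneal3 = _fit_anneal(candidates3, params, f"{variant.name} 3' probe")

    return LigationProbeSet(
        variant=variant,
        probe5_by_allele=probe5,
        probe3_anneal_seq=anneal3,
    )


# ---------------------------------------------------------------------------
# Multiplex layout


def _loci_from(items: list) -> list[tuple[Variant, dict[str, int]]]:
    """Normalise layout input: Variants or LigationProbeSets.

    Returns (variant, natural product length per allele); bare variants
    (no probe sequences yet) get zero natural lengths, meaning any size
    slot in range is admissible.
    """
    out = []
    for item in items:
        if isinstance(item, LigationProbeSet):
            v = item.variant
            nat = {k: item.natural_length(k) for k in v.allele_keys()}
        elif isinstance(item, Variant):
            v = item
            nat = {k: 0 for k in v.allele_keys()}
        else:
            raise TypeError(f"cannot lay out {type(item).__name__}")
        out.append((v, nat))
    return out


def assign_layout(
    items: list, params: DesignParams | None = None
) -> dict[str, dict[str, tuple[str, float]]]:
    """Assign every ligation product a collision-free (dye, size) address.

    Greedy first-fit over discrete size slots: slots are spaced by the
    slot pitch (a stuffer-step multiple covering the minimum same-dye
    separation) across the panel size range; each slot holds up to four
    products on distinct dyes, and the alleles of one locus always land in
    the same slot on different dyes (ties broken by variant order, then
    dye order B < G < Y < R).  Deterministic given the parameters.

    Raises :class:`DesignError` if the products cannot fit, reporting
    required versus available capacity.
    """
    params = params or DesignParams()
    loci = _loci_from(items)
    lo, hi = params.size_range
    pitch = params.slot_pitch
    n_slots = int((hi - lo) // pitch) + 1
    slots = [lo + i * pitch for i in range(n_slots)]
    free: list[list[str]] = [list(DYES) for _ in slots]

    n_products = sum(len(nat) for _, nat in loci)
    if n_products > n_slots * len(DYES):
        raise DesignError(
            f"infeasible layout: {n_products} products need "
            f"{math.ceil(n_products / len(DYES))} size slots, only "
            f"{n_slots} available in {params.size_range} at pitch {pitch}"
        )

    layout: dict[str, dict[str, tuple[str, float]]] = {}
    for v, nat in loci:
        keys = v.allele_keys()
        need = len(keys)
        min_size = max(nat.values())  # stuffers must be non-negative
        placed = False
        for i, size in enumerate(slots):
            if size < min_size or len(free[i]) < need:
                continue
            layout[v.name] = {
                k: (free[i][j], float(size)) for j, k in enumerate(keys)
            }
            del free[i][:need]
            placed = True
            break
        if not placed:
            # brute-force fallback: allow the locus to straddle two
            # adjacent slots (alleles still on distinct dyes)
            placed = _place_split(v, keys, min_size, slots, free, layout)
        if not placed:
            raise DesignError(
                f"infeasible layout: no slot fits {v.name} "
                f"(needs {need} dyes at size >= {min_size})"
            )
    return layout


def _place_split(v, keys, min_size, slots, free, layout) -> bool:
    for i in range(len(slots) - 1):
        if slots[i] < min_size:
            continue
        pool = [(i, d) for d in free[i]] + [(i + 1, d) for d in free[i + 1]]
        # alleles of one locus must differ in dye
        chosen: list[tuple[int, str]] = []
        used_dyes: set[str] = set()
        for slot_i, dye in pool:
            if dye in used_dyes:
                continue
            chosen.append((slot_i, dye))
            used_dyes.add(dye)
            if len(chosen) == len(keys):
                break
        if len(chosen) < len(keys):
            continue
        layout[v.name] = {
            k: (dye, float(slots[slot_i]))
            for k, (slot_i, dye) in zip(keys, chosen)
        }
        for slot_i, dye in chosen:
            free[slot_i].remove(dye)
        return True
    return False


def group_amplicons(
    variants_with_positions: list[tuple[Variant, str, int]],
    max_amplicon_len: int,
) -> dict[str, list[Variant]]:
    """Group targets into multiplex-PCR amplicons by genomic proximity.

    Single-linkage over per-contig offsets: consecutive variants closer
    than ``max_amplicon_len`` share an amplicon.  A greedy sweep over
    sorted offsets yields the minimum number of groups for this interval
    structure.  Group ids are ``A01``, ``A02``, ... in (contig, offset)
    order.
    """
    ordered = sorted(
        variants_with_positions, key=lambda t: (t[1], t[2], t[0].name)
    )
    groups: list[list[Variant]] = []
    prev_contig, prev_off = None, None
    for v, contig, off in ordered:
        if (
            groups
            and contig == prev_contig
            and off - prev_off <= max_amplicon_len
        ):
            groups[-1].append(v)
        else:
            groups.append([v])
        prev_contig, prev_off = contig, off
    return {f"A{i + 1:02d}": members for i, members in enumerate(groups)}


# ---------------------------------------------------------------------------
# Flank FASTA I/O


def read_flanks(path) -> dict[str, dict[str, str]]:
    """Read variant flanking sequences from FASTA.

    Record id is the variant name; the variant site is a bracketed
    ``[ref/alt]`` token at the junction, e.g. ``ACG[C/-]TTA``.  Returns
    ``{name: {"flank5", "flank3", "ref", "alt"}}``.
    """
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        lb, rb = seq.find("["), seq.find("]")
        if lb < 0 or rb < lb or "/" not in seq[lb:rb]:
            raise DesignError(
                f"record {rec.id!r}: expected a [ref/alt] token in the sequence"
            )
        ref, alt = seq[lb + 1 : rb].split("/", 1)
        out[rec.id] = {
            "flank5": seq[:lb],
            "flank3": seq[rb + 1 :],
            "ref": ref,
            "alt": alt,
        }
    return out
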