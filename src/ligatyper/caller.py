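"""Decode capillary peak tables into per-locus genotype calls.

The pipeline is: ladder-based size calling (local Southern), assignment of
sized peaks to the panel's expected (dye, size) products, and allele-ratio
zygosity calling per locus.  Batch helpers produce a sample-by-variant
genotype matrix and concordance statistics against a truth matrix.

Genotype strings follow VCF GT notation: ``0/0`` hom-ref, ``0/1`` het,
``1/1`` hom-alt, ``0/2``/``2/2`` for the second alternate allele of a
tri-allelic locus, ``./.`` no-call.  Mitochondrial loci are called on the
homoplasmy fraction (alt share of the locus signal): near-1 homoplasmic
alt maps to ``1/1``, near-0 to ``0/0``, anything between is reported as
heteroplasmic (``0/1``) with the fraction attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import Panel, Variant

__all__ = [
    "Peak",
    "PeakTable",
    "GenotypeCall",
    "CallThresholds",
    "CallerError",
    "size_call",
    "match_products",
    "call_locus",
    "call_sample",
    "call_batch",
    "concordance",
]


class CallerError(ValueError):
    """Raised for invalid peak tables or mismatched matrices."""


@dataclass(frozen=True)
class Peak:
    """One fluorescence peak on one dye channel.

    ``raw_units`` is the instrument migration coordinate; ``size`` is the
    nucleotide size after ladder calibration (None until sized).
    """

    dye: str
    height: float
    raw_units: float | None = None
    size: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise CallerError("peak height must be positive")


@dataclass
class PeakTable:
    """One sample's read-out: peaks plus the co-run size ladder.

    ``ladder`` is a list of (raw_units, known size nt) pairs, strictly
    increasing in both coordinates, with at least 4 points.
    """

    sample_id: str
    peaks: list[Peak]
    ladder: list[tuple[float, float]] = field(default_factory=list)

    def validate_ladder(self) -> None:
        if len(self.ladder) < 4:
            raise CallerError(
                f"{self.sample_id}: ladder needs >= 4 points, got {len(self.ladder)}"
            )
        raws = [m for m, _ in self.ladder]
        sizes = [s for _, s in self.ladder]
        if not (all(a < b for a, b in zip(raws, raws[1:]))
                and all(a < b for a, b in zip(sizes, sizes[1:]))):
            raise CallerError(f"{self.sample_id}: ladder must be strictly increasing")


_CALLS = ("hom_ref", "het", "hom_alt", "no_call")


@dataclass(frozen=True)
class GenotypeCall:
    """Decoded zygosity at one locus.

    ``allele_ratio`` is alt/(ref+alt) peak height; for mitochondrial loci
    the same quantity is reported as ``mt_fraction`` (homoplasmy fraction).
    ``alt_key`` names which alternate allele carries the signal at a
    tri-allelic locus ("alt" or "alt2").
    """

    variant_name: str
    call: str
    ref_height: float = 0.0
    alt_height: float = 0.0
    allele_ratio: float | None = None
    mt_fraction: float | None = None
    alt_key: str = "alt"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call not in _CALLS:
            raise CallerError(f"unknown call {self.call!r}")

    @property
    def gt(self) -> str:
        """VCF-style genotype string."""
        if self.call == "no_call":
            return "./."
        idx = "2" if self.alt_key == "alt2" else "1"
        return {"hom_ref": "0/0", "het": f"0/{idx}", "hom_alt": f"{idx}/{idx}"}[
            self.call
        ]


@dataclass(frozen=True)
class CallThresholds:
    """Zygosity-calling thresholds.

    ``min_height`` (RFU) is the detection threshold: matched peaks below
    it do not count as allele signal.  A two-allele locus is called het
    when the allele ratio lies in ``het_band``; ratios beyond the
    ``hom_override`` bounds revert to the majority homozygote; the dead
    zones in between are no-calls.  Mitochondrial loci are homoplasmic
    alt at fraction >= ``mt_homoplasmy_min`` and reference below its
    complement.
    """

    min_height: float = 100.0
    het_band: tuple[float, float] = (0.25, 0.75)
    hom_override: tuple[float, float] = (0.1, 0.9)
    mt_homoplasmy_min: float = 0.95
    size_tolerance: float | None = None  # None: use the panel's tolerance

    def __post_init__(self) -> None:
        if self.min_height <= 0:
            raise CallerError("min_height must be positive")


# ---------------------------------------------------------------------------
# Size calling


def _southern_fit(pts: list[tuple[float, float]], m: float) -> float | None:
    """Evaluate the local Southern reciprocal fit L = L0 + c/(m - m0)
    through three ladder points at migration ``m``; None if degenerate."""
    (m1, l1), (m2, l2), (m3, l3) = pts
    # pairwise differences of (L - L0)(m - m0) = c give a linear 2x2 system
    a = np.array([[l1 - l2, m1 - m2], [l2 - l3, m2 - m3]], dtype=float)
    b = np.array([l1 * m1 - l2 * m2, l2 * m2 - l3 * m3], dtype=float)
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    scale = max(abs(a).max(), 1.0)
    if abs(det) < 1e-12 * scale * scale:
        return None
    m0, l0 = np.linalg.solve(a, b)
    c = (l2 - l0) * (m2 - m0)
    if abs(m - m0) < 1e-12:
        return None
    return float(l0 + c / (m - m0))


def size_call(
    raw_peaks: list[Peak], ladder: list[tuple[float, float]]
) -> list[Peak]:
    """Convert raw migration units to nucleotide sizes against the ladder.

    Each peak inside the ladder span is sized by the local Southern method
    (reciprocal fit through the bracketing segment's three neighbouring
    ladder points); the first segment and degenerate (collinear) fits fall
    back to linear interpolation.  Using one fixed point triple per ladder
    segment makes the raw-to-size map continuous and strictly monotone.
    Peaks outside the span are linearly extrapolated and flagged
    ``off_size``.
    """
    tbl = PeakTable("", [], list(ladder))
    tbl.validate_ladder()
    raws = [m for m, _ in ladder]
    sizes = [s for _, s in ladder]
    n = len(ladder)

    out: list[Peak] = []
    for p in raw_peaks:
        if p.raw_units is None:
            raise CallerError("peak has no raw_units to size")
        m = p.raw_units
        flags = list(p.flags)
        if m < raws[0] or m > raws[-1]:
            # extrapolate from the terminal segment
            i = 0 if m < raws[0] else n - 2
            t = (m - raws[i]) / (raws[i + 1] - raws[i])
            size = sizes[i] + t * (sizes[i + 1] - sizes[i])
            flags.append("off_size")
        else:
            i = int(np.searchsorted(raws, m, side="right")) - 1
            i = min(max(i, 0), n - 2)
            if i == 0:
                size = _linear(raws, sizes, 0, m)
            else:
                fit = _southern_fit(
                    [ladder[i - 1], ladder[i], ladder[i + 1]], m
                )
                size = fit if fit is not None else _linear(raws, sizes, i, m)
        out.append(replace(p, size=float(size), flags=tuple(flags)))
    return out


def _linear(raws, sizes, i, m) -> float:
    t = (m - raws[i]) / (raws[i + 1] - raws[i])
    return sizes[i] + t * (sizes[i + 1] - sizes[i])


# ---------------------------------------------------------------------------
# Product matching


def match_products(
    panel: Panel,
    sized_peaks: list[Peak],
    size_tolerance: float | None = None,
) -> dict[str, dict[str, list[Peak]]]:
    """Assign sized peaks to the panel's expected products.

    A peak is assigned to the product on the same dye whose expected size
    lies within the tolerance; the panel layout guarantees at most one
    such product.  Multiple peaks hitting one product are kept
    tallest-first (the extras make the locus ``ambiguous``).  Off-size or
    unmatched peaks are left unassigned.  Returns
    ``{variant name: {allele key: [peaks, tallest first]}}``.
    """
    tol = panel.tolerance if size_tolerance is None else size_tolerance
    matched: dict[str, dict[str, list[Peak]]] = {
        v.name: {k: [] for k in v.allele_keys()} for v in panel.variants
    }
    products = panel.products
    for p in sized_peaks:
        if p.size is None:
            raise CallerError("peak not sized; run size_call first")
        if "off_size" in p.flags:
            continue
        best = None
        best_d = tol
        for prod in products:
            if prod.dye != p.dye:
                continue
            d = abs(p.size - prod.expected_size)
            if d <= best_d:
                best, best_d = prod, d
        if best is not None:
            matched[best.variant_name][best.allele].append(p)
    for per_allele in matched.values():
        for peaks in per_allele.values():
            peaks.sort(key=lambda q: -q.height)
    return matched


# ---------------------------------------------------------------------------
# Zygosity calling


def call_locus(
    variant: Variant,
    matched_alleles: dict[str, list[Peak]],
    thresholds: CallThresholds | None = None,
) -> GenotypeCall:
    """Call zygosity at one locus from its matched allele peaks.

    Peak heights below ``min_height`` are treated as absent signal.  With
    no signal at all the locus is a no-call (``low_signal``).  Nuclear
    loci: single-allele signal calls the corresponding homozygote; dual
    signal calls het inside the het band, the majority homozygote beyond
    the override bounds, and no-call (``ambiguous``) in the dead zones.
    Mitochondrial loci are called on the homoplasmy fraction.
    """
    th = thresholds or CallThresholds()
    flags: list[str] = []

    def signal(key: str) -> float:
        peaks = matched_alleles.get(key, [])
        if len(peaks) > 1:
            flags.append("ambiguous")
        if peaks and peaks[0].height >= th.min_height:
            return peaks[0].height
        return 0.0

    ref_h = signal("ref")
    alt_keys = [k for k in variant.allele_keys() if k != "ref"]
    alt_heights = {k: signal(k) for k in alt_keys}
    alt_key = max(alt_keys, key=lambda k: alt_heights[k])
    alt_h = alt_heights[alt_key]

    if ref_h == 0.0 and alt_h == 0.0:
        return GenotypeCall(
            variant.name, "no_call", flags=tuple(flags + ["low_signal"])
        )
    ratio = alt_h / (ref_h + alt_h)

    if variant.is_mitochondrial:
        if ratio >= th.mt_homoplasmy_min:
            call = "hom_alt"  # homoplasmic alternate
        elif ratio <= 1.0 - th.mt_homoplasmy_min:
            call = "hom_ref"
        else:
            call = "het"  # heteroplasmic, fraction reported
        return GenotypeCall(
            variant.name, call, ref_h, alt_h, ratio,
            mt_fraction=ratio, alt_key=alt_key, flags=tuple(flags),
        )

    lo_hom, hi_hom = th.hom_override
    lo_het, hi_het = th.het_band
    if alt_h == 0.0:
        call = "hom_ref"
    elif ref_h == 0.0:
        call = "hom_alt"
    elif lo_het <= ratio <= hi_het:
        call = "het"
    elif ratio < lo_hom:
        call = "hom_ref"
    elif ratio > hi_hom:
        call = "hom_alt"
    else:
        call = "no_call"
        flags.append("ambiguous")
    return GenotypeCall(
        variant.name, call, ref_h, alt_h, ratio,
        alt_key=alt_key, flags=tuple(flags),
    )


def call_sample(
    panel: Panel,
    peak_table: PeakTable,
    thresholds: CallThresholds | None = None,
) -> list[GenotypeCall]:
    """Size, match and call every panel locus for one sample."""
    th = thresholds or CallThresholds()
    peaks = peak_table.peaks
    if peaks and any(p.size is None for p in peaks):
        peaks = size_call(peaks, peak_table.ladder)
    matched = match_products(panel, peaks, th.size_tolerance)
    return [
        call_locus(v, matched[v.name], th) for v in panel.variants
    ]


def call_batch(
    panel: Panel,
    peak_tables: list[PeakTable],
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Call a batch of samples; returns a sample-by-variant GT matrix."""
    rows = {}
    for tbl in peak_tables:
        calls = call_sample(panel, tbl, thresholds)
        rows[tbl.sample_id] = {c.variant_name: c.gt for c in calls}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=panel.variant_names)


# ---------------------------------------------------------------------------
# Concordance


def concordance(truth: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Sensitivity/specificity of a call matrix against truth.

    Both matrices are sample-by-variant GT grids.  Over (sample, locus)
    pairs with a non-reference truth genotype, sensitivity is the fraction
    called with exactly the true zygosity (a het/hom mixup is discordant);
    specificity is the fraction of truth-reference pairs called reference.
    """
    if not truth.index.equals(calls.index) or not truth.columns.equals(calls.columns):
        calls = calls.reindex(index=truth.index, columns=truth.columns)
        if calls.isna().any().any():
            raise CallerError("truth and call matrices have mismatched axes")
    t = truth.to_numpy()
    c = calls.to_numpy()
    pos = t != "0/0"
    tp = int(((t == c) & pos).sum())
    tn = int(((c == "0/0") & ~pos).sum())
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    discordant = [
        (truth.index[i], truth.columns[j], t[i, j], c[i, j])
        for i, j in zip(*np.nonzero(t != c))
    ]
    per_variant = pd.DataFrame(
        {
            "positives": pd.Series(pos.sum(axis=0), index=truth.columns),
            "discordant": pd.Series(
                (t != c).sum(axis=0), index=truth.columns
            ),
        }
    )
    return {
        "sensitivity": 100.0 * tp / n_pos if n_pos else float("nan"),
        "specificity": 100.0 * tn / n_neg if n_neg else float("nan"),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "discordant": discordant,
        "per_variant": per_variant,
    }
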