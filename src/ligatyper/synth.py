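"""Synthetic genotype cohorts and capillary peak-table simulation.

Two layers: (1) fixture generators that expand published per-variant
zygosity counts into per-sample genotype truth sets (the validation set of
49 positive cases, the 50 healthy controls, and the 171-patient cohort
with its compound-heterozygous pairs); (2) a peak-level electropherogram
simulator that renders any truth set into dye/size/height peak tables with
a configurable noise model, ready for the caller.

The simulator emits peak-level data only (no per-scanpoint traces): one
peak per present allele at the product's expected size plus Gaussian
sizing jitter, lognormal peak heights, heterozygous allele-ratio jitter,
and a Poisson background of low spurious peaks.  Mitochondrial loci emit
ref/alt peaks weighted by the homoplasmy fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _tables
from .caller import Peak, PeakTable
from .panel import DYES, Panel

__all__ = [
    "SampleTruth",
    "NoiseModel",
    "FixtureError",
    "cohort_from_counts",
    "validation_samples_from_table1",
    "control_samples_from_table4",
    "simulate_sample",
    "simulate_cohort",
    "truth_to_matrix",
    "DEFAULT_LADDER_SIZES",
    "instrument_response",
]


class FixtureError(ValueError):
    """Raised when requested cohort counts are infeasible."""


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth genotypes for one sample.

    ``genotypes`` is sparse: it lists only non-reference loci.  Nuclear
    values are zygosity strings (``het``, ``hom_alt``; ``het2`` /
    ``hom_alt2`` address the second alternate of a tri-allelic locus);
    mitochondrial values are homoplasmy fractions in [0, 1].
    """

    sample_id: str
    genotypes: dict[str, str | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, g in self.genotypes.items():
            if isinstance(g, float) and not (0.0 <= g <= 1.0):
                raise FixtureError(
                    f"{self.sample_id}/{name}: homoplasmy fraction {g} not in [0,1]"
                )

    def gt(self, variant_name: str, mitochondrial: bool) -> str:
        """VCF-style genotype string for one locus."""
        g = self.genotypes.get(variant_name)
        if g is None:
            return "0/0"
        if mitochondrial or isinstance(g, float):
            f = float(g)
            return "1/1" if f >= 0.95 else "0/0" if f <= 0.05 else "0/1"
        return {
            "hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
            "het2": "0/2", "hom_alt2": "2/2",
        }[g]


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise parameters for the peak simulator.

    size_sd: sizing jitter SD in nt.  Peak heights are lognormal with the
    given log-scale mean/SD (RFU).  het_imbalance_sd jitters the alt share
    of heterozygous loci around 0.5 (clipped to [0.3, 0.7]).
    baseline_rate is the Poisson mean of spurious low peaks (20-80 RFU,
    uniform size and dye) per sample.  dropout_prob drops individual
    allele peaks.
    """

    size_sd: float = 0.15
    height_mean_log: float = math.log(1000.0)
    height_sd_log: float = 0.25
    het_imbalance_sd: float = 0.05
    baseline_rate: float = 2.0
    dropout_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.size_sd < 0:
            raise FixtureError("size_sd must be >= 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise FixtureError("dropout_prob must be in [0, 1)")

    @classmethod
    def zero(cls, rng_seed: int = 0) -> "NoiseModel":
        """Noise-free instrument: exact sizes, fixed heights, no baseline."""
        return cls(
            size_sd=0.0, height_sd_log=0.0, het_imbalance_sd=0.0,
            baseline_rate=0.0, dropout_prob=0.0, rng_seed=rng_seed,
        )


# ---------------------------------------------------------------------------
# Fixture generators


def _finish(samples: list[dict], prefix: str, seed: int) -> list[SampleTruth]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    width = max(3, len(str(len(samples))))
    return [
        SampleTruth(f"{prefix}{i + 1:0{width}d}", dict(samples[j]))
        for i, j in enumerate(order)
    ]


def _hom_value(panel: Panel, name: str) -> str | float:
    return 1.0 if panel.variant(name).is_mitochondrial else "hom_alt"


def _het_value(panel: Panel, name: str) -> str | float:
    return 0.5 if panel.variant(name).is_mitochondrial else "het"


def cohort_from_counts(
    panel: Panel,
    per_variant_counts: dict[str, tuple[int, int]],
    compound_pairs: list[tuple[str, str, int]],
    n_total: int,
    seed: int = 0,
    strict: bool = True,
) -> list[SampleTruth]:
    """Expand per-variant (hom, het) counts into a cohort of truth sets.

    Compound pairs (variantA, variantB, k) are realised first as k samples
    heterozygous for both, drawing those het occurrences from the
    per-variant het counts; remaining het and all hom counts become
    single-finding samples; the rest of the cohort is variant-free, so the
    per-variant marginals equal the inputs exactly.  In strict mode a pair
    demand exceeding a variant's remaining het supply is an error; in
    reconciliation mode (``strict=False``) it is capped with a warning.
    """
    rem_het = {v: het for v, (hom, het) in per_variant_counts.items()}
    rem_hom = {v: hom for v, (hom, het) in per_variant_counts.items()}
    for name in per_variant_counts:
        panel.variant(name)  # KeyError on unknown variant

    samples: list[dict] = []
    for a, b, k in compound_pairs:
        avail = min(rem_het.get(a, 0), rem_het.get(b, 0))
        if k > avail:
            short = a if rem_het.get(a, 0) < rem_het.get(b, 0) else b
            if strict:
                raise FixtureError(
                    f"compound pair {a}/{b} demands {k} dual-het samples but "
                    f"{short} has only {rem_het.get(short, 0)} het left"
                )
            warnings.warn(
                f"compound pair {a}/{b}: demand {k} capped at {avail} "
                f"({short} het supply exhausted)",
                stacklevel=2,
            )
            k = avail
        for _ in range(k):
            samples.append({a: _het_value(panel, a), b: _het_value(panel, b)})
        rem_het[a] -= k
        rem_het[b] -= k

    for name in per_variant_counts:
        for _ in range(rem_het[name]):
            samples.append({name: _het_value(panel, name)})
        for _ in range(rem_hom[name]):
            samples.append({name: _hom_value(panel, name)})

    if len(samples) > n_total:
        raise FixtureError(
            f"counts require {len(samples)} carrier samples, cohort size is {n_total}"
        )
    samples.extend({} for _ in range(n_total - len(samples)))
    return _finish(samples, "S", seed)


def validation_samples_from_table1(panel: Panel, seed: int = 0) -> list[SampleTruth]:
    """The 49 Sanger-positive validation samples.

    Each printed (variant, zygosity) count becomes that many samples
    carrying the variant as their primary finding (29 het + 20 hom = 49);
    the compound findings then layer a second variant onto samples already
    carrying the listed first variant.  Mitochondrial carriers are
    homoplasmic (fraction 1.0); cross-gene pairs are dual-gene findings,
    not compound heterozygotes.
    """
    samples: list[dict] = []
    primary_het: dict[str, list[dict]] = {}
    for name, (het, hom) in _tables.VALIDATION_COUNTS.items():
        for _ in range(het):
            s = {name: _het_value(panel, name)}
            samples.append(s)
            primary_het.setdefault(name, []).append(s)
        for _ in range(hom):
            samples.append({name: _hom_value(panel, name)})
    for first, second, k in _tables.VALIDATION_PAIRS:
        hosts = [
            s for s in primary_het.get(first, [])
            if second not in s and len(s) == 1
        ]
        if len(hosts) < k:
            raise FixtureError(
                f"validation pair {first}/{second}: only {len(hosts)} "
                f"free het {first} carriers for {k} pairs"
            )
        for s in hosts[:k]:
            s[second] = (
                1.0 if panel.variant(second).is_mitochondrial
                else _het_value(panel, second)
            )
    return _finish(samples, "V", seed)


def control_samples_from_table4(panel: Panel, seed: int = 0) -> list[SampleTruth]:
    """The 50 healthy controls: 5 distinct single-het carriers
    (one each of three GJB2 deletions, two of the SLC26A4 splice variant),
    45 variant-free."""
    samples: list[dict] = [
        {name: _het_value(panel, name)}
        for name, k in _tables.CONTROL_COUNTS.items()
        for _ in range(k)
    ]
    samples.extend({} for _ in range(_tables.CONTROL_N - len(samples)))
    return _finish(samples, "C", seed)


# ---------------------------------------------------------------------------
# Peak simulation

#: co-electrophoresed size-standard fragments (nt)
DEFAULT_LADDER_SIZES = (
    60.0, 80.0, 100.0, 120.0, 140.0, 160.0, 180.0,
    200.0, 220.0, 240.0, 260.0, 280.0, 300.0,
)


def instrument_response(size_nt: float) -> float:
    """Map fragment size to raw migration units.

    Reciprocal-mobility response m = m0 + c / (L0 - L): fragment mobility
    inversely related to length, the relationship the local Southern
    sizing method models.  Strictly increasing over the working range
    (L < 400 nt); the ladder is rendered through the same curve so that
    size calling must genuinely invert it.
    """
    return 500.0 + 340000.0 / (400.0 - size_nt)


def _allele_weights(
    panel: Panel, name: str, g: str | float, rng: np.random.Generator,
    noise: NoiseModel,
) -> dict[str, float]:
    """Relative signal share per allele key for one locus genotype."""
    v = panel.variant(name)
    if v.is_mitochondrial or isinstance(g, float):
        f = float(g)
        return {"ref": 1.0 - f, "alt": f}
    if g == "hom_ref":
        return {"ref": 1.0}
    alt_key = "alt2" if g in ("het2", "hom_alt2") else "alt"
    if g in ("hom_alt", "hom_alt2"):
        return {alt_key: 1.0}
    share = 0.5 + noise.het_imbalance_sd * rng.standard_normal()
    share = float(np.clip(share, 0.3, 0.7))
    return {"ref": 1.0 - share, alt_key: share}


def simulate_sample(
    panel: Panel,
    truth: SampleTruth,
    noise: NoiseModel | None = None,
) -> PeakTable:
    """Render one sample's electropherogram peak table.

    One peak per present allele at the product's expected size plus
    N(0, size_sd) jitter on that product's dye, with lognormal locus
    signal split between alleles by the genotype weights; spurious
    baseline peaks at Poisson(baseline_rate); the size ladder appended.
    Deterministic given the noise model's seed.
    """
    noise = noise or NoiseModel()
    unknown = set(truth.genotypes) - set(panel.variant_names)
    if unknown:
        raise FixtureError(f"{truth.sample_id}: unknown variants {sorted(unknown)}")
    rng = np.random.default_rng(noise.rng_seed)
    lo, hi = panel.size_range

    peaks: list[Peak] = []
    for v in panel.variants:
        g = truth.genotypes.get(v.name, 0.0 if v.is_mitochondrial else "hom_ref")
        weights = _allele_weights(panel, v.name, g, rng, noise)
        signal = math.exp(
            noise.height_mean_log + noise.height_sd_log * rng.standard_normal()
        )
        for key, w in weights.items():
            if w <= 0.0:
                continue
            if noise.dropout_prob and rng.random() < noise.dropout_prob:
                continue
            dye, expected = panel.layout[v.name][key]
            size = expected + noise.size_sd * rng.standard_normal()
            peaks.append(
                Peak(
                    dye=dye,
                    height=signal * w,
                    raw_units=instrument_response(size),
                )
            )
    n_spurious = rng.poisson(noise.baseline_rate) if noise.baseline_rate > 0 else 0
    for _ in range(int(n_spurious)):
        size = rng.uniform(lo, hi)
        peaks.append(
            Peak(
                dye=DYES[rng.integers(len(DYES))],
                height=rng.uniform(20.0, 80.0),
                raw_units=instrument_response(size),
            )
        )
    ladder = [(instrument_response(s), s) for s in DEFAULT_LADDER_SIZES]
    return PeakTable(sample_id=truth.sample_id, peaks=peaks, ladder=ladder)


def simulate_cohort(
    panel: Panel,
    truths: list[SampleTruth],
    noise: NoiseModel | None = None,
) -> list[PeakTable]:
    """Simulate every sample with a per-sample seed derived from the
    noise model's seed; order-stable and reproducible."""
    noise = noise or NoiseModel()
    out = []
    for i, truth in enumerate(truths):
        child = int(
            np.random.SeedSequence([noise.rng_seed, i]).generate_state(1)[0]
        ) % (2**31)
        out.append(simulate_sample(panel, truth, replace(noise, rng_seed=child)))
    return out


def truth_to_matrix(panel: Panel, truths: list[SampleTruth]) -> pd.DataFrame:
    """Sample-by-variant GT matrix of a truth set (VCF genotype strings)."""
    rows = {
        t.sample_id: {
            v.name: t.gt(v.name, v.is_mitochondrial) for v in panel.variants
        }
        for t in truths
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=panel.variant_names)
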