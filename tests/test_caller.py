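"""Size calling, product matching, zygosity calling, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligatyper import (
    CallThresholds,
    NoiseModel,
    Peak,
    PeakTable,
    SampleTruth,
    call_batch,
    call_locus,
    call_sample,
    concordance,
    match_products,
    simulate_cohort,
    simulate_sample,
    size_call,
)
from ligatyper.caller import CallerError
from ligatyper.panel import Variant

LINEAR_LADDER = [(1000.0 + 10.0 * s, s) for s in (60, 100, 140, 180, 220, 260)]


def _raw_peaks(raws, dye="B", height=500.0):
    return [Peak(dye=dye, height=height, raw_units=m) for m in raws]


class TestSizeCall:
    def test_ladder_point_maps_to_known_size(self):
        sized = size_call(_raw_peaks([1000.0 + 10.0 * 140]), LINEAR_LADDER)
        assert sized[0].size == pytest.approx(140.0, abs=1e-9)

    def test_linear_ladder_midpoint(self):
        mid = (2000.0 + 2400.0) / 2  # between the 100 and 140 points
        sized = size_call(_raw_peaks([mid]), LINEAR_LADDER)
        assert sized[0].size == pytest.approx(120.0, abs=1e-9)

    def test_local_southern_matches_closed_form(self):
        """On a ladder drawn from a reciprocal-mobility curve
        m = m0 + c/(L0 - L), the 3-point fit must recover the curve's
        inverse exactly."""
        m0, L0, c = 700.0, 450.0, 250000.0
        curve = lambda L: m0 + c / (L0 - L)
        inverse = lambda m: L0 - c / (m - m0)
        ladder = [(curve(L), float(L)) for L in range(60, 320, 20)]
        for size in (95.3, 121.7, 180.0, 240.0, 279.9):
            sized = size_call(_raw_peaks([curve(size)]), ladder)
            assert sized[0].size == pytest.approx(inverse(curve(size)), abs=1e-9)
            assert sized[0].size == pytest.approx(size, abs=1e-9)

    def test_outside_span_flagged_off_size(self):
        sized = size_call(_raw_peaks([100.0]), LINEAR_LADDER)
        assert "off_size" in sized[0].flags

    def test_degenerate_ladders_rejected(self):
        with pytest.raises(CallerError, match=">= 4"):
            size_call(_raw_peaks([1500.0]), LINEAR_LADDER[:3])
        bad = list(LINEAR_LADDER)
        bad[2] = (bad[3][0] + 1, bad[2][1])
        with pytest.raises(CallerError, match="increasing"):
            size_call(_raw_peaks([1500.0]), bad)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(1610.0, 3590.0), min_size=2, max_size=12, unique=True))
    def test_strictly_monotone_in_raw_units(self, raws):
        raws = sorted(raws)
        sized = size_call(_raw_peaks(raws), LINEAR_LADDER)
        sizes = [p.size for p in sized]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_monotone_on_curved_ladder(self):
        curve = lambda L: 500.0 + 340000.0 / (400.0 - L)
        ladder = [(curve(L), float(L)) for L in range(60, 320, 20)]
        raws = np.linspace(ladder[0][0] + 1, ladder[-1][0] - 1, 500)
        sizes = [p.size for p in size_call(_raw_peaks(list(raws)), ladder)]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))


class TestMatchProducts:
    def test_zero_noise_hom_ref_matches_every_ref(self, hl32):
        tbl = simulate_sample(hl32, SampleTruth("s", {}), NoiseModel.zero())
        sized = size_call(tbl.peaks, tbl.ladder)
        matched = match_products(hl32, sized)
        for v in hl32.variants:
            assert len(matched[v.name]["ref"]) == 1
            for key in v.allele_keys()[1:]:
                assert matched[v.name][key] == []

    def test_far_spurious_peak_unassigned(self, hl32):
        # mid-gap between two size slots: beyond tolerance of every product
        dye, size = hl32.layout["c.235delC"]["ref"]
        stray = Peak(dye=dye, height=300.0, size=size + 2.0)
        matched = match_products(hl32, [stray])
        assert all(
            not peaks
            for per_allele in matched.values()
            for peaks in per_allele.values()
        )

    def test_duplicate_peaks_keep_tallest_and_flag(self, hl32):
        v = hl32.variant("c.235delC")
        dye, size = hl32.layout["c.235delC"]["ref"]
        peaks = [
            Peak(dye=dye, height=400.0, size=size + 0.3),
            Peak(dye=dye, height=900.0, size=size - 0.2),
        ]
        matched = match_products(hl32, peaks)
        assert [p.height for p in matched["c.235delC"]["ref"]] == [900.0, 400.0]
        call = call_locus(v, matched["c.235delC"])
        assert "ambiguous" in call.flags
        assert call.call == "hom_ref"
        assert call.ref_height == 900.0


def _mk(ref_h=None, alt_h=None, mito=False):
    v = (
        Variant("MT-RNR1", "mtDNA", "m.1A>G", "A", ("G",), inheritance="MT")
        if mito
        else Variant("G1", "1", "c.1A>G", "A", ("G",))
    )
    matched = {"ref": [], "alt": []}
    if ref_h:
        matched["ref"] = [Peak(dye="B", height=ref_h, size=100.0)]
    if alt_h:
        matched["alt"] = [Peak(dye="G", height=alt_h, size=100.0)]
    return v, matched


class TestCallLocus:
    def test_ref_only_hom_ref(self):
        call = call_locus(*_mk(ref_h=1200.0))
        assert call.call == "hom_ref"
        assert call.allele_ratio == 0.0

    def test_balanced_het(self):
        call = call_locus(*_mk(ref_h=1000.0, alt_h=950.0))
        assert call.call == "het"
        assert call.allele_ratio == pytest.approx(950 / 1950, abs=1e-9)

    def test_mitochondrial_alt_only_homoplasmic(self):
        call = call_locus(*_mk(alt_h=1100.0, mito=True))
        assert call.call == "hom_alt"
        assert call.mt_fraction == 1.0
        assert call.gt == "1/1"

    def test_mitochondrial_heteroplasmic_fraction(self):
        call = call_locus(*_mk(ref_h=400.0, alt_h=600.0, mito=True))
        assert call.call == "het"
        assert call.mt_fraction == pytest.approx(0.6)

    def test_no_signal_no_call(self):
        call = call_locus(*_mk(ref_h=50.0))  # below min_height
        assert call.call == "no_call"
        assert "low_signal" in call.flags
        assert call.gt == "./."

    def test_extreme_ratio_reverts_to_majority_homozygote(self):
        call = call_locus(*_mk(ref_h=1900.0, alt_h=105.0))  # ratio 0.052
        assert call.call == "hom_ref"
        call = call_locus(*_mk(ref_h=105.0, alt_h=1900.0))
        assert call.call == "hom_alt"

    def test_dead_zone_is_ambiguous_no_call(self):
        call = call_locus(*_mk(ref_h=1000.0, alt_h=200.0))  # ratio 0.167
        assert call.call == "no_call"
        assert "ambiguous" in call.flags


class TestCallSampleAndBatch:
    def test_single_het_zero_noise(self, hl32):
        truth = SampleTruth("s", {"c.299_300delAT": "het"})
        tbl = simulate_sample(hl32, truth, NoiseModel.zero())
        calls = {c.variant_name: c for c in call_sample(hl32, tbl)}
        assert calls["c.299_300delAT"].call == "het"
        others = [c for n, c in calls.items() if n != "c.299_300delAT"]
        assert all(c.call == "hom_ref" for c in others)

    def test_batch_shape(self, hl32):
        truths = [SampleTruth(f"s{i}", {}) for i in range(5)]
        tables = simulate_cohort(hl32, truths, NoiseModel(rng_seed=4))
        calls = call_batch(hl32, tables)
        assert calls.shape == (5, 32)
        assert list(calls.columns) == hl32.variant_names

    def test_no_call_rate_monotone_in_min_height(self, hl32):
        truths = [SampleTruth(f"s{i}", {"c.235delC": "het"}) for i in range(20)]
        tables = simulate_cohort(hl32, truths, NoiseModel(rng_seed=6))
        rates = []
        for h in (100.0, 400.0, 700.0, 1200.0, 5000.0):
            calls = call_batch(hl32, tables, CallThresholds(min_height=h))
            rates.append(int((calls == "./.").to_numpy().sum()))
        assert rates == sorted(rates)


class TestConcordance:
    def test_identity_is_perfect(self):
        m = pd.DataFrame(
            {"v1": ["0/1", "0/0"], "v2": ["1/1", "0/0"]}, index=["a", "b"]
        )
        r = concordance(m, m.copy())
        assert (r["sensitivity"], r["specificity"]) == (100.0, 100.0)

    def test_one_false_negative_among_100_positives(self):
        truth = pd.DataFrame({"v": ["0/1"] * 100}, index=[f"s{i}" for i in range(100)])
        calls = truth.copy()
        calls.iloc[0, 0] = "0/0"
        r = concordance(truth, calls)
        assert r["sensitivity"] == pytest.approx(99.0)

    def test_zygosity_mixup_is_discordant(self):
        truth = pd.DataFrame({"v": ["0/1", "0/1"]}, index=["a", "b"])
        calls = pd.DataFrame({"v": ["1/1", "0/1"]}, index=["a", "b"])
        r = concordance(truth, calls)
        assert r["sensitivity"] == pytest.approx(50.0)
        assert ("a", "v", "0/1", "1/1") in r["discordant"]

    def test_axis_mismatch_rejected(self):
        a = pd.DataFrame({"v": ["0/0"]}, index=["a"])
        b = pd.DataFrame({"w": ["0/0"]}, index=["a"])
        with pytest.raises(CallerError, match="axes"):
            concordance(a, b)
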