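"""Fixture generators (count expansion) and the peak simulator."""

from __future__ import annotations

import numpy as np
import pytest

from ligatyper import (
    NoiseModel,
    SampleTruth,
    cohort_from_counts,
    control_samples_from_table4,
    simulate_cohort,
    simulate_sample,
    truth_to_matrix,
    validation_samples_from_table1,
)
from ligatyper import _tables
from ligatyper.caller import size_call
from ligatyper.synth import FixtureError


def _zygosity_counts(truths, name):
    het = sum(1 for t in truths if t.genotypes.get(name) == "het")
    hom = sum(
        1 for t in truths
        if t.genotypes.get(name) == "hom_alt" or t.genotypes.get(name) == 1.0
    )
    return het, hom


class TestCohortFromCounts:
    def test_strict_marginals_exact(self, hl32):
        counts = {"c.235delC": (2, 3), "c.299_300delAT": (1, 2), "IVS7-2A>G": (0, 1)}
        pairs = [("c.235delC", "c.299_300delAT", 1)]
        truths = cohort_from_counts(hl32, counts, pairs, 20, seed=3, strict=True)
        assert len(truths) == 20
        for name, (hom, het) in counts.items():
            got_het, got_hom = _zygosity_counts(truths, name)
            assert (got_hom, got_het) == (hom, het), name
        dual = [
            t for t in truths
            if t.genotypes.get("c.235delC") == "het"
            and t.genotypes.get("c.299_300delAT") == "het"
        ]
        assert len(dual) == 1

    def test_infeasible_pair_demand_strict_errors(self, hl32):
        counts = {"c.235delC": (0, 1), "c.299_300delAT": (0, 5)}
        with pytest.raises(FixtureError, match="c.235delC"):
            cohort_from_counts(
                hl32, counts, [("c.235delC", "c.299_300delAT", 3)], 10, strict=True
            )

    def test_reconcile_mode_caps_with_warning(self, hl32):
        with pytest.warns(UserWarning, match="capped"):
            truths = cohort_from_counts(
                hl32, _tables.COHORT_COUNTS, _tables.COHORT_PAIRS,
                _tables.COHORT_N, seed=0, strict=False,
            )
        assert len(truths) == _tables.COHORT_N
        # marginals still exact after capping
        for name, (hom, het) in _tables.COHORT_COUNTS.items():
            got_het, got_hom = _zygosity_counts(truths, name)
            assert (got_hom, got_het) == (hom, het), name

    def test_all_zero_counts(self, hl32):
        truths = cohort_from_counts(hl32, {}, [], 10, seed=1)
        assert len(truths) == 10
        assert all(not t.genotypes for t in truths)

    def test_too_many_carriers_rejected(self, hl32):
        with pytest.raises(FixtureError, match="cohort size"):
            cohort_from_counts(hl32, {"c.235delC": (5, 5)}, [], 4)


class TestValidationFixture:
    def test_49_samples(self, hl32):
        assert len(validation_samples_from_table1(hl32, 0)) == 49

    def test_primary_zygosity_counts(self, hl32):
        truths = validation_samples_from_table1(hl32, 0)
        het, hom = _zygosity_counts(truths, "c.235delC")
        assert (het, hom) == (10, 6)
        het, hom = _zygosity_counts(truths, "IVS7-2A>G")
        assert (het, hom) == (3 + 1, 3)  # 3 primary + 1 compound finding

    def test_compound_pair_present(self, hl32):
        truths = validation_samples_from_table1(hl32, 0)
        dual = [
            t for t in truths
            if t.genotypes.get("IVS7-2A>G") == "het"
            and t.genotypes.get("c.2168A>G") == "het"
        ]
        assert len(dual) >= 1

    def test_mitochondrial_carriers_homoplasmic(self, hl32):
        truths = validation_samples_from_table1(hl32, 0)
        fracs = [
            t.genotypes["c.1555A>G"] for t in truths if "c.1555A>G" in t.genotypes
        ]
        assert len(fracs) == 11 + 2  # 11 primary + 2 dual-gene findings
        assert all(f == 1.0 for f in fracs)

    def test_deterministic_given_seed(self, hl32):
        a = validation_samples_from_table1(hl32, 5)
        b = validation_samples_from_table1(hl32, 5)
        assert a == b


class TestControlFixture:
    def test_composition(self, hl32):
        truths = control_samples_from_table4(hl32, 0)
        assert len(truths) == 50
        het, hom = _zygosity_counts(truths, "IVS7-2A>G")
        assert (het, hom) == (2, 0)
        clean = [t for t in truths if not t.genotypes]
        assert len(clean) == 45
        # controls carry single het findings only
        assert all(
            g == "het" for t in truths for g in t.genotypes.values()
        )


class TestSimulateSample:
    def test_zero_noise_hom_ref(self, hl32):
        tbl = simulate_sample(hl32, SampleTruth("s", {}), NoiseModel.zero())
        assert len(tbl.peaks) == len(hl32.variants)  # one ref peak per locus
        sized = size_call(tbl.peaks, tbl.ladder)
        for peak, v in zip(sized, hl32.variants):
            dye, size = hl32.layout[v.name]["ref"]
            assert peak.dye == dye
            assert peak.size == pytest.approx(size, abs=1e-9)

    def test_zero_noise_hom_alt_swaps_product(self, hl32):
        truth = SampleTruth("s", {"c.235delC": "hom_alt"})
        tbl = simulate_sample(hl32, truth, NoiseModel.zero())
        sized = size_call(tbl.peaks, tbl.ladder)
        ref_dye, ref_size = hl32.layout["c.235delC"]["ref"]
        alt_dye, alt_size = hl32.layout["c.235delC"]["alt"]
        hits = lambda dye, size: [
            p for p in sized if p.dye == dye and abs(p.size - size) < 0.5
        ]
        assert len(hits(alt_dye, alt_size)) == 1
        assert len(hits(ref_dye, ref_size)) == 0

    def test_het_emits_both_alleles(self, hl32):
        truth = SampleTruth("s", {"c.235delC": "het"})
        tbl = simulate_sample(hl32, truth, NoiseModel.zero())
        assert len(tbl.peaks) == len(hl32.variants) + 1

    def test_sizing_jitter_within_half_nt(self, hl32):
        """Monte-Carlo: with size_sd 0.15 (about 3.3 sigma to 0.5 nt),
        at least 99% of allele peaks size within +/-0.5 nt."""
        truths = [SampleTruth(f"s{i}", {}) for i in range(1000)]
        tables = simulate_cohort(hl32, truths, NoiseModel(rng_seed=11, baseline_rate=0.0))
        errs = []
        for tbl in tables:
            sized = size_call(tbl.peaks, tbl.ladder)
            for peak, v in zip(sized, hl32.variants):
                errs.append(abs(peak.size - hl32.layout[v.name]["ref"][1]))
        errs = np.asarray(errs)
        assert (errs <= 0.5).mean() >= 0.99

    def test_unknown_variant_rejected(self, hl32):
        with pytest.raises(FixtureError, match="unknown"):
            simulate_sample(hl32, SampleTruth("s", {"nope": "het"}), NoiseModel.zero())


class TestSimulateCohort:
    def test_order_and_length(self, hl32):
        truths = control_samples_from_table4(hl32, 2)
        tables = simulate_cohort(hl32, truths, NoiseModel(rng_seed=2))
        assert [t.sample_id for t in tables] == [t.sample_id for t in truths]

    def test_deterministic_given_seed(self, hl32):
        truths = control_samples_from_table4(hl32, 2)
        a = simulate_cohort(hl32, truths, NoiseModel(rng_seed=9))
        b = simulate_cohort(hl32, truths, NoiseModel(rng_seed=9))
        assert a == b

    def test_empty(self, hl32):
        assert simulate_cohort(hl32, [], NoiseModel()) == []


class TestTruthMatrix:
    def test_gt_strings(self, hl32):
        truths = [
            SampleTruth("a", {"c.235delC": "het", "c.1555A>G": 1.0}),
            SampleTruth("b", {}),
        ]
        m = truth_to_matrix(hl32, truths)
        assert m.loc["a", "c.235delC"] == "0/1"
        assert m.loc["a", "c.1555A>G"] == "1/1"
        assert m.loc["b", "c.235delC"] == "0/0"
        assert m.shape == (2, 32)
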