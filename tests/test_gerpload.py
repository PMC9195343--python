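"""Outgroup fragmentation, polarization, derived counts, load, percentiles."""

import math

import numpy as np
import pytest

from erodekit.formats import ReferenceSequence, SampleCall, VariantRecord
from erodekit.gerpload import (
    AncestralCall,
    count_derived,
    fragment_outgroups,
    gerp_percentile,
    infer_ancestral,
    relative_load,
)
from erodekit.simulate import simulate_gerp_sites
from .conftest import make_variant


class TestFragmentation:
    @pytest.mark.parametrize("length, n_frags", [(70, 2), (100, 2), (35, 1), (34, 0)])
    def test_fragment_counts_tail_dropped(self, length, n_frags):
        seq = ReferenceSequence("og1", "A" * length)
        if n_frags == 0:
            with pytest.warns(UserWarning):
                frags = fragment_outgroups([seq])
        else:
            frags = fragment_outgroups([seq])
        assert len(frags) == n_frags
        assert all(f.length == 35 for f in frags)

    def test_fragments_are_consecutive_nonoverlapping(self):
        seq = ReferenceSequence("og1", "".join("ACGT"[i % 4] for i in range(120)))
        frags = fragment_outgroups([seq])
        assert "".join(f.bases for f in frags) == seq.bases[:105]
        assert frags[1].name == "og1:35-70"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fragment_outgroups([])


class TestAncestralInference:
    def test_strict_majority(self):
        v = make_variant(pos=10, ref="A", alts=("G",))
        og = {("c1", 10): ["A", "A", "G"]}
        call = infer_ancestral([v], og)[0]
        assert call.ancestral_base == "A"
        assert (call.n_outgroups_covering, call.n_agreeing) == (3, 2)

    def test_tie_is_unknown(self):
        v = make_variant(pos=10, ref="A", alts=("G",))
        assert infer_ancestral([v], {("c1", 10): ["A", "G"]})[0].ancestral_base == "unknown"

    def test_zero_coverage_is_unknown(self):
        v = make_variant(pos=10)
        assert infer_ancestral([v], {})[0].ancestral_base == "unknown"

    def test_majority_base_not_an_allele_is_unknown(self):
        v = make_variant(pos=10, ref="A", alts=("C",))
        assert infer_ancestral([v], {("c1", 10): ["T", "T"]})[0].ancestral_base == "unknown"

    def test_min_coverage(self):
        v = make_variant(pos=10, ref="A", alts=("G",))
        og = {("c1", 10): ["A"]}
        assert infer_ancestral([v], og, min_coverage=2)[0].ancestral_base == "unknown"
        assert infer_ancestral([v], og, min_coverage=1)[0].ancestral_base == "A"


class TestDerivedCounts:
    def _anc(self, base):
        return AncestralCall("c1", 100, base, 3, 3)

    @pytest.mark.parametrize(
        "gt, ancestral, expected",
        [
            ((0, 1), "A", 1),  # het, ancestral = REF
            ((1, 1), "A", 2),  # hom ALT, ancestral = REF
            ((0, 0), "G", 2),  # hom REF, ancestral = ALT: REF itself derived
            ((0, 0), "A", 0),
            ((1, 1), "G", 0),
        ],
    )
    def test_counting(self, gt, ancestral, expected):
        v = make_variant(ref="A", alts=("G",), gt=gt, ad=(10, 10))
        assert count_derived(v, "s1", self._anc(ancestral)) == expected

    def test_unknown_ancestral_skips_site(self):
        v = make_variant(ref="A", alts=("G",))
        assert count_derived(v, "s1", self._anc("unknown")) is None

    def test_missing_genotype_skips(self):
        v = make_variant(ref="A", alts=("G",), gt=None, ad=None)
        assert count_derived(v, "s1", self._anc("A")) is None


class TestRelativeLoad:
    def test_worked_example(self):
        # het at RS 2.0 plus hom-derived at RS 3.0: (2*1 + 3*2) / 3 = 8/3
        est = relative_load([(2.0, 1), (3.0, 2)], 0.0, 10.0)
        assert est.relative_load == pytest.approx(8 / 3, rel=1e-12)
        assert est.n_derived_alleles == 3

    def test_normalization_identity(self, rng):
        for _ in range(100):
            g = float(rng.uniform(0.0, 5.0))
            sites = [(g, int(d)) for d in rng.integers(1, 3, size=20)]
            assert relative_load(sites, 0.0, 10.0).relative_load == pytest.approx(g)

    def test_window_boundaries_inclusive(self):
        est = relative_load([(1.0, 1), (2.0, 1), (3.0, 1)], 1.0, 3.0)
        assert est.n_sites_used == 3

    def test_out_of_window_and_zero_derived_ignored(self):
        est = relative_load([(5.0, 1), (2.0, 0), (1.0, 2)], 0.0, 4.0)
        assert est.n_sites_used == 1 and est.n_derived_alleles == 2

    def test_undefined_sentinel_not_zero(self):
        est = relative_load([(5.0, 0)], 0.0, 10.0)
        assert not est.defined and math.isnan(est.relative_load)

    def test_load_bounded_by_window(self, rng):
        for _ in range(20):
            sites = [(float(rng.uniform(0, 6)), int(d))
                     for d in rng.integers(0, 3, size=50)]
            est = relative_load(sites, 1.0, 4.0)
            if est.defined:
                assert 1.0 <= est.relative_load <= 4.0

    def test_scale_equivariance(self, rng):
        sites = [(float(rng.uniform(0, 4)), int(d))
                 for d in rng.integers(0, 3, size=50)]
        base = relative_load(sites, 0.0, 10.0)
        scaled = relative_load([(3 * rs, d) for rs, d in sites], 0.0, 30.0)
        if base.defined:
            assert scaled.relative_load == pytest.approx(3 * base.relative_load)

    def test_duplication_invariance(self, rng):
        sites = [(float(rng.uniform(0, 4)), int(d))
                 for d in rng.integers(0, 3, size=30)]
        once = relative_load(sites, 0.0, 10.0)
        twice = relative_load(sites + sites, 0.0, 10.0)
        if once.defined:
            assert twice.relative_load == pytest.approx(once.relative_load)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            relative_load([], 2.0, 1.0)


class TestSimulatedLoads:
    def test_truth_loads_reproduced_exactly(self):
        bundle = simulate_gerp_sites(
            2000, {"h": (0.05, 0.02), "m": (0.08, 0.04)}, seed=7
        )
        for s, sites in bundle.objects["sites"].items():
            est = relative_load(sites, 0.0, float("inf"))
            assert est.relative_load == pytest.approx(
                bundle.truth["loads"][s], rel=1e-12
            )

    def test_planted_load_contrast_recovered(self):
        # modern samples carry their derived alleles preferentially at
        # high-RS (conserved) sites; their load must come out higher
        wins = 0
        for seed in range(100):
            bundle = simulate_gerp_sites(
                400,
                {"hist": (0.05, 0.02, 0.0), "mod": (0.05, 0.02, 2.0)},
                seed=seed,
            )
            sites = bundle.objects["sites"]
            hist = relative_load(sites["hist"], 0.0, float("inf"))
            mod = relative_load(sites["mod"], 0.0, float("inf"))
            if mod.relative_load > hist.relative_load:
                wins += 1
        assert wins >= 95


class TestPercentile:
    BINS = [(0.0, 1.0, 900), (1.0, 2.0, 90), (2.0, 3.0, 10)]

    @pytest.mark.parametrize(
        "p, expected", [(99.0, 2.0), (99.5, 2.5), (50.0, 500 / 900)]
    )
    def test_interpolation(self, p, expected):
        assert gerp_percentile(self.BINS, p) == pytest.approx(expected)

    def test_single_bin_midpoint(self):
        assert gerp_percentile([(0.0, 1.0, 100)], 50) == pytest.approx(0.5)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gerp_percentile([(0.0, 1.0, 0)], 50)

    def test_noncontiguous_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            gerp_percentile([(0.0, 1.0, 5), (1.5, 2.0, 5)], 50)

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            gerp_percentile(self.BINS, 100)
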