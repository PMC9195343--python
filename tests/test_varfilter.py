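"""Filter-cascade boundaries, the golden hand-labeled VCF, and the merge."""

import pytest

from erodekit.depthqc import DepthThresholds, depth_thresholds
from erodekit.formats import GenomeIntervalSet, SampleCall, VariantRecord
from erodekit.varfilter import (
    FilterConfig,
    FilterTrace,
    exclude_intervals,
    filter_allelic_imbalance,
    filter_depth,
    filter_near_indels,
    filter_sample_vcf,
    filter_site_quality,
    merge_and_filter,
    passing_sites_bed,
    split_by_era,
)
from .conftest import make_variant

CFG = FilterConfig()
THR = depth_thresholds(9.0)  # (3, 90)


class TestSiteQuality:
    @pytest.mark.parametrize(
        "qual, mq, keep",
        [(30.0, 30.0, True), (29.9, 60.0, False), (60.0, 29.0, False)],
    )
    def test_at_least_30_inclusive(self, qual, mq, keep):
        assert filter_site_quality(make_variant(qual=qual, mq=mq), CFG) is keep

    def test_absent_mq_dropped(self):
        assert not filter_site_quality(make_variant(mq=None), CFG)


class TestDepthWindow:
    @pytest.mark.parametrize("dp, keep", [(3, True), (90, True), (91, False), (2, False)])
    def test_boundaries(self, dp, keep):
        v = make_variant(dp=dp)
        assert filter_depth(v, THR, "s1") is keep

    def test_absolute_minimum_of_three(self):
        # even generous thresholds cannot admit DP 2
        thr = DepthThresholds(3.0, 1000.0)
        assert not thr.passes(2)

    def test_missing_dp_dropped(self):
        assert not filter_depth(make_variant(dp=None), THR, "s1")


class TestAllelicImbalance:
    @pytest.mark.parametrize(
        "ad, keep",
        [((2, 8), True), ((8, 2), True), ((1, 9), False), ((9, 1), False), ((5, 5), True)],
    )
    def test_20_80_strict_boundaries(self, ad, keep):
        v = make_variant(gt=(0, 1), ad=ad)
        assert filter_allelic_imbalance(v, CFG, "s1") is keep

    def test_homozygous_passes_untouched(self):
        v = make_variant(gt=(1, 1), ad=(0, 10))
        assert filter_allelic_imbalance(v, CFG, "s1")

    def test_het_missing_ad_dropped(self):
        v = make_variant(gt=(0, 1), ad=None)
        assert not filter_allelic_imbalance(v, CFG, "s1")


class TestIndelProximity:
    def _indel(self, pos):
        return make_variant(pos=pos, ref="AT", alts=("A",), ad=(10, 10))

    def test_distance_five_dropped_six_kept(self):
        # indel span [100, 101]; exclusion zone [95, 106]
        variants = [self._indel(100), make_variant(pos=106), make_variant(pos=107)]
        kept = filter_near_indels(variants, gap=5)
        assert [v.pos for v in kept] == [107]

    def test_indels_removed_afterwards(self):
        kept = filter_near_indels([self._indel(100)], gap=5)
        assert kept == []

    def test_no_indels_all_snvs_kept(self):
        variants = [make_variant(pos=p) for p in (10, 20, 30)]
        assert filter_near_indels(variants) == variants

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_near_indels([make_variant(pos=20), make_variant(pos=10)])


class TestExcludeIntervals:
    def test_coordinate_convention(self):
        # 1-based pos 5 is 0-based 4, inside [4, 5)
        exclude = GenomeIntervalSet([("c1", 4, 5)])
        assert exclude_intervals([make_variant(pos=5)], exclude) == []
        assert len(exclude_intervals([make_variant(pos=6)], exclude)) == 1

    def test_empty_exclude_identity(self):
        vs = [make_variant(pos=p) for p in (1, 5, 9)]
        assert exclude_intervals(vs, GenomeIntervalSet()) == vs

    def test_whole_chrom_excluded(self):
        vs = [make_variant(pos=p) for p in (1, 5, 9)]
        assert exclude_intervals(vs, GenomeIntervalSet([("c1", 0, 100)])) == []


def _multi(pos, per_sample_calls, ref="A", alts=("G",), qual=60.0, mq=60.0):
    """One VariantRecord per sample, as per-sample VCFs would hold them."""
    out = {}
    for sample, call in per_sample_calls.items():
        out[sample] = VariantRecord(
            chrom="c1", pos=pos, ref_allele=ref, alt_alleles=tuple(alts),
            site_qual=qual, map_qual=mq, calls={sample: call},
        )
    return out


HET = SampleCall(genotype=(0, 1), dp=20, ad=(10, 10))


class TestMerge:
    def test_exactly_ten_percent_missing_kept(self):
        samples = {f"s{i}": [] for i in range(10)}
        for i in range(10):
            if i == 0:
                continue  # s0 missing at the site
            samples[f"s{i}"] = [
                VariantRecord(
                    chrom="c1", pos=50, ref_allele="A", alt_alleles=("G",),
                    site_qual=60.0, map_qual=60.0, calls={f"s{i}": HET},
                )
            ]
        merged = merge_and_filter(samples)
        assert len(merged) == 1

    def test_one_third_missing_dropped(self):
        samples = {
            "s1": [make_variant(sample="s1", pos=50)],
            "s2": [make_variant(sample="s2", pos=50)],
            "s3": [],
        }
        assert merge_and_filter(samples) == []

    def test_jointly_triallelic_dropped(self):
        samples = {
            "s1": [make_variant(sample="s1", pos=50, alts=("C",))],
            "s2": [make_variant(sample="s2", pos=50, alts=("T",))],
        }
        assert merge_and_filter(samples) == []

    def test_sample_order_permutation_invariant(self):
        a = {
            "s1": [make_variant(sample="s1", pos=50)],
            "s2": [make_variant(sample="s2", pos=50)],
        }
        b = dict(reversed(list(a.items())))
        sites_a = [(v.chrom, v.pos) for v in merge_and_filter(a)]
        sites_b = [(v.chrom, v.pos) for v in merge_and_filter(b)]
        assert sites_a == sites_b

    def test_genotype_indices_remapped_to_merged_alleles(self):
        samples = {
            "s1": [make_variant(sample="s1", pos=50, alts=("G",), gt=(1, 1), ad=(0, 20))],
            "s2": [make_variant(sample="s2", pos=50, alts=("G",), gt=(0, 0), ad=(20, 0))],
        }
        merged = merge_and_filter(samples)
        assert merged[0].calls["s1"].genotype == (1, 1)
        assert merged[0].calls["s2"].genotype == (0, 0)


class TestSplitAndBed:
    def test_split_partitions_columns_same_sites(self):
        samples = {f"s{i}": [make_variant(sample=f"s{i}", pos=p) for p in (10, 20)]
                   for i in range(4)}
        merged = merge_and_filter(samples)
        era = {"s0": "historical", "s1": "historical", "s2": "modern", "s3": "modern"}
        hist, mod = split_by_era(merged, era)
        assert len(hist) == len(mod) == len(merged)
        assert set(hist[0].calls) == {"s0", "s1"}
        assert set(mod[0].calls) == {"s2", "s3"}

    def test_unassigned_sample_rejected(self):
        merged = merge_and_filter({"s1": [make_variant(sample="s1")]})
        with pytest.raises(ValueError, match="s1"):
            split_by_era(merged, {})

    def test_single_era_warns_with_empty_other(self):
        merged = merge_and_filter({"s1": [make_variant(sample="s1")]})
        with pytest.warns(UserWarning):
            hist, mod = split_by_era(merged, {"s1": "historical"})
        assert len(mod) == len(merged) and mod[0].calls == {}

    def test_passing_bed_merges_adjacent_sites(self):
        vs = [make_variant(pos=10), make_variant(pos=11)]
        assert list(passing_sites_bed(vs)) == [("c1", 9, 11)]

    def test_passing_bed_empty_and_scattered(self):
        assert list(passing_sites_bed([])) == []
        vs = [make_variant(pos=p) for p in (10, 50, 90)]
        bed = passing_sites_bed(vs)
        assert len(bed) == 3 and bed.total_bases == 3


class TestGoldenCascade:
    """A synthetic VCF with one site per failure mode; survivors hand-labeled."""

    SAMPLES = ("s1", "s2", "s3")

    def _per_sample(self):
        clean = SampleCall(genotype=(0, 1), dp=10, ad=(5, 5))
        sites = []
        # (pos, kwargs per failure mode); identical across samples
        sites.append(dict(pos=100, qual=29.9))              # QUAL below 30
        sites.append(dict(pos=200, mq=29.0))                # MQ below 30
        sites.append(dict(pos=300, ref="AT", alts=("A",), ad=(5, 5)))  # indel
        sites.append(dict(pos=306))                          # 5 bp from indel span
        sites.append(dict(pos=307))                          # 6 bp away: survives
        sites.append(dict(pos=400, dp=2, ad=(1, 1)))         # below min depth
        sites.append(dict(pos=500, dp=91, ad=(45, 46)))      # above max depth
        sites.append(dict(pos=600, ad=(1, 9)))               # imbalance 10%
        sites.append(dict(pos=700, ad=(2, 8)))               # exactly 20%: survives
        sites.append(dict(pos=800))                          # in repeat BED
        sites.append(dict(pos=900))                          # in CpG mask
        sites.append(dict(pos=1200))                         # clean pass
        per_sample = {}
        for s in self.SAMPLES:
            variants = []
            for spec in sites:
                kw = dict(spec)
                pos = kw.pop("pos")
                variants.append(
                    make_variant(
                        chrom="c1", pos=pos, sample=s,
                        ref=kw.pop("ref", "A"), alts=kw.pop("alts", ("G",)),
                        qual=kw.pop("qual", 60.0), mq=kw.pop("mq", 60.0),
                        dp=kw.pop("dp", 10), ad=kw.pop("ad", (5, 5)),
                        gt=kw.pop("gt", (0, 1)),
                    )
                )
            per_sample[s] = variants
        # triallelic-on-merge: ALT C in s1/s2, ALT T in s3
        for s in self.SAMPLES:
            alt = ("C",) if s != "s3" else ("T",)
            per_sample[s].append(
                make_variant(chrom="c1", pos=1000, sample=s, alts=alt,
                             gt=(0, 1), dp=10, ad=(5, 5))
            )
        # >10% missing: site only called in s1 and s2 (1/3 missing)
        for s in ("s1", "s2"):
            per_sample[s].append(
                make_variant(chrom="c1", pos=1100, sample=s, gt=(0, 1),
                             dp=10, ad=(5, 5))
            )
        for s in per_sample:
            per_sample[s].sort(key=lambda v: v.pos)
        return per_sample

    def test_exactly_the_labeled_survivors(self):
        per_sample = self._per_sample()
        repeats = GenomeIntervalSet([("c1", 799, 800)])  # 1-based pos 800
        cpg = GenomeIntervalSet([("c1", 899, 901)])      # covers pos 900
        trace = FilterTrace()
        filtered = {
            s: filter_sample_vcf(
                per_sample[s], s, CFG, THR, cpg_mask=cpg, repeats=repeats,
                trace=trace,
            )
            for s in self.SAMPLES
        }
        merged = merge_and_filter(filtered, CFG, trace=trace)
        assert [v.pos for v in merged] == [307, 700, 1200]

    def test_trace_conserves_counts_at_every_stage(self):
        per_sample = self._per_sample()
        repeats = GenomeIntervalSet([("c1", 799, 800)])
        cpg = GenomeIntervalSet([("c1", 899, 901)])
        trace = FilterTrace()
        filtered = {
            s: filter_sample_vcf(
                per_sample[s], s, CFG, THR, cpg_mask=cpg, repeats=repeats,
                trace=trace,
            )
            for s in self.SAMPLES
        }
        merge_and_filter(filtered, CFG, trace=trace)
        trace.check()
        assert all(n_in == n_rm + n_out for _, n_in, n_rm, n_out in trace.stages)
        stage_names = [s for s, *_ in trace.stages]
        assert stage_names[-2:] == ["biallelic", "missingness"]


class TestConfigValidation:
    def test_inverted_imbalance_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(imbalance_low=0.9, imbalance_high=0.8)

    def test_missing_frac_bounds(self):
        with pytest.raises(ValueError):
            FilterConfig(max_missing_frac=1.5)
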