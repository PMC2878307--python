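"""Tag pair handling, p.p.b. signals, metaprofiles and multi-hit rescue."""

import numpy as np
import pysam
import pytest

from alunuc.io_annotation import AluElement, GenomeSequence, RepeatFeature
from alunuc.nucleosome import (
    PPB,
    IntervalIndex,
    TagPair,
    align_profile,
    background_signal,
    categorize_tags,
    load_tag_pairs,
    multihit_augment,
    nucleosome_signal,
    tag_midpoint,
    write_tag_pairs,
)


def _alu(chrom, start, end, strand="+", cls="dimer", name="AluSx"):
    return AluElement(RepeatFeature(chrom, start, end, strand, name), cls)


class TestLoadTagPairs:
    def test_insert_bounds_inclusive(self, tmp_path):
        text = (
            "c1\t100\t246\t1\n"  # insert 147 -> accepted
            "c1\t100\t220\t1\n"  # insert 121 -> rejected
            "c1\t100\t221\t1\n"  # insert 122 -> accepted
            "c1\t100\t271\t1\n"  # insert 172 -> accepted
            "c1\t100\t272\t1\n"  # insert 173 -> rejected
        )
        p = tmp_path / "t.tsv"
        p.write_text(text)
        pairs, n_rej = load_tag_pairs(p)
        assert [q.insert for q in pairs] == [147, 122, 172]
        assert n_rej == 2

    def test_hit_list_round_trip(self, tmp_path):
        pair = TagPair("c1", 100, 246, 3, (("c1", 100), ("c1", 900), ("c2", 50)))
        write_tag_pairs([pair], tmp_path / "t.tsv")
        back, _ = load_tag_pairs(tmp_path / "t.tsv")
        assert back == [pair]

    def test_sam_equals_tsv(self, tmp_path):
        sam = tmp_path / "t.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 10000}]}
        with pysam.AlignmentFile(str(sam), "wh", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r1"
            a.query_sequence = "A" * 36
            a.flag = 0x1 | 0x2 | 0x20  # paired, proper, mate reverse
            a.reference_id = 0
            a.reference_start = 100
            a.cigar = [(0, 36)]
            a.next_reference_id = 0
            a.next_reference_start = 211
            a.template_length = 147
            a.mapping_quality = 30
            fh.write(a)
        tsv = tmp_path / "t.tsv"
        tsv.write_text("c1\t100\t246\t1\n")
        from_sam, _ = load_tag_pairs(sam, format="sam")
        from_tsv, _ = load_tag_pairs(tsv)
        assert from_sam == from_tsv

    def test_unknown_chrom_dropped(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("weird\t100\t246\t1\n")
        pairs, _ = load_tag_pairs(p, known_chroms={"c1"})
        assert pairs == []


class TestTagMidpoint:
    @pytest.mark.parametrize(
        "fwd,rev,mid", [(100, 246, 173), (0, 146, 73), (100, 247, 173)]
    )
    def test_floor_midpoint(self, fwd, rev, mid):
        assert tag_midpoint(TagPair("c1", fwd, rev)) == mid


class TestCategorizeTags:
    ALUS = [_alu("c1", 1000, 1300)]

    def test_unique_split_by_midpoint(self):
        inside = TagPair("c1", 1050, 1196)  # midpoint 1123 in Alu
        outside = TagPair("c1", 100, 246)
        counts = categorize_tags([inside, outside], self.ALUS)
        assert counts.unique_alu == 1 and counts.unique_other == 1

    def test_multi_hit_fractions(self):
        all_in = TagPair("c1", 1010, 1156, 3, (("c1", 1010), ("c1", 1050), ("c1", 1100)))
        none_in = TagPair("c1", 10, 156, 2, (("c1", 10), ("c1", 400)))
        some_in = TagPair("c1", 1010, 1156, 2, (("c1", 1010), ("c1", 10)))
        counts = categorize_tags([all_in, none_in, some_in], self.ALUS)
        assert (counts.multi_complete, counts.multi_partial, counts.multi_none) == (1, 1, 1)

    def test_components_sum_to_total(self, profile_sim):
        counts = categorize_tags(profile_sim.nuc_tags, profile_sim.truth.elements)
        assert counts.total == len(profile_sim.nuc_tags)
        assert counts.multi_complete + counts.multi_partial + counts.multi_none > 0


class TestNucleosomeSignal:
    def test_single_midpoint_uniform_plateau(self):
        sig = nucleosome_signal([("c1", 50)], {"c1": 200}, window_w=21)
        arr = sig.get("c1")
        nz = np.nonzero(arr)[0]
        assert len(nz) == 21 and nz[0] == 40 and nz[-1] == 60
        assert np.allclose(arr[nz], PPB / 21)

    def test_two_distant_midpoints_split_mass(self):
        sig = nucleosome_signal([("c1", 50), ("c1", 150)], {"c1": 300}, 21)
        arr = sig.get("c1")
        assert np.isclose(arr[40:61].sum(), PPB / 2)
        assert np.isclose(arr[140:161].sum(), PPB / 2)

    def test_w1_is_scaled_histogram(self):
        sig = nucleosome_signal([("c1", 5), ("c1", 5), ("c1", 9)], {"c1": 20}, 1)
        arr = sig.get("c1")
        assert np.isclose(arr[5], 2 / 3 * PPB) and np.isclose(arr[9], PPB / 3)

    def test_ppb_conservation(self, profile_sim):
        mids = [(t.chrom, tag_midpoint(t)) for t in profile_sim.nuc_tags]
        sig = nucleosome_signal(mids, profile_sim.genome.lengths(), 21)
        assert abs(sig.total() - PPB) < 1e-3

    def test_no_midpoints_rejected(self):
        with pytest.raises(ValueError):
            nucleosome_signal([], {"c1": 100}, 21)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            nucleosome_signal([("c1", 5)], {"c1": 100}, 20)


class TestBackgroundSignal:
    def test_flat_within_poisson_noise(self):
        L = 20_000
        n = 200_000
        sig = background_signal({"c1": L}, n, rng_seed=1, window_w=21)
        arr = sig.get("c1")[300:-300]  # away from edge effects
        expect = PPB / (L - 146)  # fragments start in [0, L-147]
        per_bp = n / (L - 146) * 21  # counts contributing per position
        sd = expect / np.sqrt(per_bp)
        assert np.all(np.abs(arr - expect) < 4.5 * sd)

    def test_seed_reproducibility(self):
        a = background_signal({"c1": 5000}, 100, rng_seed=3)
        b = background_signal({"c1": 5000}, 100, rng_seed=3)
        assert np.array_equal(a.get("c1"), b.get("c1"))

    def test_single_fragment_single_plateau(self):
        sig = background_signal({"c1": 1000}, 1, rng_seed=0, window_w=21)
        assert np.isclose(sig.get("c1").sum(), PPB)
        assert (sig.get("c1") > 0).sum() == 21


class TestAlignProfile:
    def _delta_signal(self, pos, L=4000):
        arr = {"c1": np.zeros(L)}
        arr["c1"][pos] = 1.0
        from alunuc.nucleosome import NucleosomeSignal

        return NucleosomeSignal(arr, 1, 1)

    def test_spike_at_center_maps_to_offset_zero(self):
        el = _alu("c1", 1000, 1300)
        prof = align_profile(self._delta_signal(el.center), [el], flank=500)
        assert prof.mean_signal[np.where(prof.offsets == 0)[0][0]] == 1.0

    def test_averaging_linearity(self):
        el = _alu("c1", 1000, 1300)
        sig = self._delta_signal(el.center)
        one = align_profile(sig, [el], flank=500)
        many = align_profile(sig, [el] * 4, flank=500)
        assert np.allclose(one.mean_signal, many.mean_signal)

    def test_minus_strand_flip(self):
        el = _alu("c1", 1000, 1300, strand="-")
        prof = align_profile(self._delta_signal(el.center + 10), [el], flank=500)
        i = np.where(prof.offsets == -10)[0][0]
        assert prof.mean_signal[i] == 1.0
        unflipped = align_profile(
            self._delta_signal(el.center + 10), [el], flank=500, strand_aware=False
        )
        assert unflipped.mean_signal[np.where(unflipped.offsets == 10)[0][0]] == 1.0

    def test_out_of_bounds_element_excluded(self):
        el_edge = _alu("c1", 10, 310)
        el_ok = _alu("c1", 1000, 1300)
        sig = self._delta_signal(1150)
        prof = align_profile(sig, [el_edge, el_ok], flank=500)
        assert prof.n_elements == 1 and prof.n_excluded == 1


class TestMultihitAugment:
    ALUS = [_alu("c1", 1000, 1300), _alu("c1", 5000, 5300), _alu("c1", 9000, 9300)]

    def _tag(self, offsets, insert=147):
        # hits at the same Alu-relative offset in several copies
        hits = tuple(("c1", a.start + off - (insert - 1) // 2) for a, off in zip(self.ALUS, offsets))
        return TagPair("c1", hits[0][1], hits[0][1] + insert - 1, len(hits), hits)

    def test_identical_relative_offsets_give_zero_sd(self):
        _, mean_sd = multihit_augment([self._tag([50, 50, 50])], self.ALUS, "complete_only", 0)
        assert mean_sd == 0.0

    def test_population_sd_of_offsets(self):
        # hit midpoints sit at center-relative distances {10, 12, 14}
        c = [a.center for a in self.ALUS]
        insert = 147
        half = (insert - 1) // 2
        hits = tuple(("c1", c[i] + d - half) for i, d in enumerate((10, 12, 14)))
        tag = TagPair("c1", hits[0][1], hits[0][1] + insert - 1, 3, hits)
        _, mean_sd = multihit_augment([tag], self.ALUS, "complete_only", 0)
        assert np.isclose(mean_sd, 2.0)

    def test_ge85_excludes_four_of_five(self):
        insert = 147
        half = (insert - 1) // 2
        in_hits = [("c1", self.ALUS[i % 3].start + 50 - half) for i in range(4)]
        out_hit = [("c1", 50)]
        tag = TagPair("c1", in_hits[0][1], in_hits[0][1] + insert - 1, 5, tuple(in_hits + out_hit))
        mids, _ = multihit_augment([tag], self.ALUS, "ge85", 0)
        assert mids == []  # 4/5 = 80% <= 85%
        mids_complete = multihit_augment([tag], self.ALUS, "complete_only", 0)[0]
        assert mids_complete == []

    def test_chosen_hits_come_from_hit_list(self):
        tag = self._tag([40, 40, 40])
        mids, _ = multihit_augment([tag], self.ALUS, "complete_only", 1)
        assert len(mids) == 1
        assert mids[0][1] in {a.start + 40 for a in self.ALUS}


def test_interval_index_merges_overlaps():
    idx = IntervalIndex([_alu("c1", 100, 400), _alu("c1", 300, 600)])
    assert idx.contains("c1", 500) and not idx.contains("c1", 600)
    assert idx.nearest_center("c1", 0) == 250
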