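"""Tests for VCF ingestion, variant windows and haplotype enumeration."""

import random

import pytest

from varmin import (
    Contig,
    IndexParams,
    apply_haplotype,
    build_windows,
    enumerate_haplotypes,
    load_variants,
)
from varmin.variants import (
    SKIP_EDGE,
    SKIP_INDEL_OVER_SNV,
    SKIP_TOO_MANY,
    WINDOW_OK,
    Variant,
    VariantWindow,
)

from conftest import random_seq
from vcf_utils import write_vcf


@pytest.fixture
def reference(rng):
    return [Contig("chr1", random_seq(rng, 2000))]


def _contig_rows(seq):
    return [("chr1", len(seq))]


class TestLoadVariants:
    def test_af_threshold_is_strict(self, reference, tmp_path):
        seq = reference[0].sequence
        rows = [
            {"contig": "chr1", "pos0": 100, "ref": seq[100], "alts": ["A" if seq[100] != "A" else "C"], "af": (0.04,)},
            {"contig": "chr1", "pos0": 200, "ref": seq[200], "alts": ["A" if seq[200] != "A" else "C"], "af": (0.05,)},
            {"contig": "chr1", "pos0": 300, "ref": seq[300], "alts": ["A" if seq[300] != "A" else "C"], "af": (0.06,)},
        ]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, rejected = load_variants(path, reference, af_min=0.05)
        assert [v.pos0 for v in accepted] == [300]
        assert sorted(r.reason for r in rejected) == ["low_af", "low_af"]

    def test_indel_length_filter(self, reference, tmp_path):
        seq = reference[0].sequence
        k = 21
        rows = [
            # deletion of net length k: rejected ("shorter than k" rule)
            {"contig": "chr1", "pos0": 100, "ref": seq[100 : 100 + k + 1], "alts": [seq[100]], "af": (0.5,)},
            # deletion of net length k-1: kept
            {"contig": "chr1", "pos0": 200, "ref": seq[200 : 200 + k], "alts": [seq[200]], "af": (0.5,)},
        ]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, rejected = load_variants(path, reference, af_min=0.05, k=k)
        assert [v.pos0 for v in accepted] == [200]
        assert [r.reason for r in rejected] == ["indel_too_long"]

    def test_multiallelic_split(self, reference, tmp_path):
        seq = reference[0].sequence
        base = seq[150]
        alts = [b for b in "ACGT" if b != base][:2]
        rows = [{"contig": "chr1", "pos0": 150, "ref": base, "alts": alts, "af": (0.3, 0.2)}]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, _ = load_variants(path, reference, af_min=0.05)
        assert len(accepted) == 2
        assert {v.alt_allele for v in accepted} == set(alts)
        assert {v.pos0 for v in accepted} == {150}
        assert [v.af for v in accepted] == [0.3, 0.2]

    def test_ref_mismatch_rejected_not_fatal(self, reference, tmp_path):
        seq = reference[0].sequence
        wrong = "A" if seq[100] != "A" else "C"
        rows = [
            {"contig": "chr1", "pos0": 100, "ref": wrong, "alts": ["G" if wrong != "G" else "T"], "af": (0.5,)},
            {"contig": "chr1", "pos0": 200, "ref": seq[200], "alts": ["A" if seq[200] != "A" else "C"], "af": (0.5,)},
        ]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, rejected = load_variants(path, reference, af_min=0.05)
        assert len(accepted) == 1 and rejected[0].reason == "ref_mismatch"

    def test_af_from_genotypes_when_info_missing(self, reference, tmp_path):
        seq = reference[0].sequence
        alt = "A" if seq[100] != "A" else "C"
        rows = [
            {
                "contig": "chr1",
                "pos0": 100,
                "ref": seq[100],
                "alts": [alt],
                "gts": [((0, 1), False), ((1, 1), False)],
            }
        ]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows, samples=("S1", "S2"))
        accepted, _ = load_variants(path, reference, af_min=0.05)
        assert accepted[0].af == pytest.approx(0.75)

    def test_no_af_kept_only_without_threshold(self, reference, tmp_path):
        seq = reference[0].sequence
        alt = "A" if seq[100] != "A" else "C"
        rows = [{"contig": "chr1", "pos0": 100, "ref": seq[100], "alts": [alt]}]
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, rejected = load_variants(path, reference, af_min=0.05)
        assert not accepted and rejected[0].reason == "no_af"
        accepted, rejected = load_variants(path, reference, af_min=None)
        assert len(accepted) == 1 and not rejected

    def test_conservation_of_records(self, reference, tmp_path, rng):
        """Every input allele is either accepted or logged-rejected."""
        seq = reference[0].sequence
        rows = []
        for pos in range(100, 1900, 37):
            base = seq[pos]
            alts = [b for b in "ACGT" if b != base][: rng.randint(1, 2)]
            rows.append(
                {
                    "contig": "chr1",
                    "pos0": pos,
                    "ref": base,
                    "alts": alts,
                    "af": tuple(round(rng.random(), 3) for _ in alts),
                }
            )
        n_alleles = sum(len(r["alts"]) for r in rows)
        path = write_vcf(tmp_path / "v.vcf", _contig_rows(seq), rows)
        accepted, rejected = load_variants(path, reference, af_min=0.05)
        assert len(accepted) + len(rejected) == n_alleles


def _snv(pos, ref="A", alt="C", **kw):
    return Variant("chr1", pos, ref, alt, "SNV", af=0.5, **kw)


class TestBuildWindows:
    def test_window_geometry(self):
        """Window length 2*(k+w)-1 with the focal REF start at offset k+w-1."""
        params = IndexParams(k=21, w=11)
        v = _snv(1000)
        (win,) = build_windows([v], params, {"chr1": 5000})
        assert win.win_end - win.win_start == 63
        assert v.pos0 - win.win_start == 31
        assert win.status == WINDOW_OK

    def test_edge_clipping(self):
        params = IndexParams(k=21, w=11)
        (win,) = build_windows([_snv(10)], params, {"chr1": 5000})
        assert (win.win_start, win.win_end) == (0, 42)
        assert win.status == WINDOW_OK

    def test_too_many_combinable_neighbours_skipped(self):
        """More than ten unphased variants around a focal one: skipped."""
        params = IndexParams(k=21, w=11)
        variants = [_snv(1000 + 2 * i) for i in range(12)]  # 11 neighbours each
        wins = build_windows(variants, params, {"chr1": 5000})
        assert all(w.status == SKIP_TOO_MANY for w in wins)
        # ten neighbours are still fine
        wins10 = build_windows(variants[:11], params, {"chr1": 5000})
        assert all(w.status == WINDOW_OK for w in wins10)

    def test_phased_windows_not_capped(self):
        """Fully phased windows are bounded by sample count, not the 10-cap."""
        gts = (((1, 0), True),)
        variants = [_snv(1000 + 3 * i, genotypes=gts) for i in range(11)]
        wins = build_windows(variants, IndexParams(k=21, w=11), {"chr1": 5000})
        assert all(w.status == WINDOW_OK for w in wins)

    def test_indel_overlapping_snv_skipped(self):
        params = IndexParams(k=21, w=11)
        deletion = Variant("chr1", 1000, "AGTC", "A", "DEL", af=0.5)
        snv = _snv(1002)
        wins = build_windows([deletion, snv], params, {"chr1": 5000})
        assert all(w.status == SKIP_INDEL_OVER_SNV for w in wins)

    def test_degenerate_edge_window(self):
        params = IndexParams(k=21, w=11)
        (win,) = build_windows([_snv(5)], params, {"chr1": 15})
        assert win.status == SKIP_EDGE


class TestApplyHaplotype:
    def test_snv_identity_coordinates(self):
        ref_win = "ACGTACGTAC"
        hap = apply_haplotype(ref_win, 100, [_snv(105, ref_win[5], "A")])
        assert len(hap.alt_seq) == len(ref_win)
        assert hap.coord_map == tuple(range(100, 110))
        assert hap.alt_seq[5] == "A"

    def test_deletion_shifts_downstream_positions(self):
        """Deleting 'GT' after offset 5: alt offset 6 maps to reference 8."""
        ref_win = "ACGTACGTACGT"
        v = Variant("chr1", 105, ref_win[5:8], ref_win[5], "DEL", af=0.5)
        hap = apply_haplotype(ref_win, 100, [v])
        assert len(hap.alt_seq) == len(ref_win) - 2
        assert hap.coord_map[5] == 105  # anchor
        assert hap.coord_map[6] == 108  # first base after the deleted span
        assert hap.alt_seq == ref_win[:6] + ref_win[8:]

    def test_insertion_left_anchored(self):
        """Inserted bases map to the base on their left; next base resumes."""
        ref_win = "ACGTACGTAC"
        v = Variant("chr1", 105, ref_win[5], ref_win[5] + "TT", "INS", af=0.5)
        hap = apply_haplotype(ref_win, 100, [v])
        assert hap.coord_map[6] == 105 and hap.coord_map[7] == 105
        assert hap.coord_map[8] == 106
        assert hap.alt_seq == ref_win[:6] + "TT" + ref_win[6:]

    def test_overlapping_edits_rejected(self):
        ref_win = "ACGTACGTAC"
        d = Variant("chr1", 104, ref_win[4:7], ref_win[4], "DEL", af=0.5)
        s = _snv(105, ref_win[5], "A")
        with pytest.raises(ValueError, match="overlap"):
            apply_haplotype(ref_win, 100, [d, s])

    def test_coord_map_round_trip(self, rng):
        """Reverting the applied edits reproduces the reference window."""
        for _ in range(50):
            seq = random_seq(rng, 80)
            pos = rng.randrange(10, 60)
            kind = rng.choice(["SNV", "DEL", "INS"])
            if kind == "SNV":
                v = Variant("chr1", pos, seq[pos], rng.choice([b for b in "ACGT" if b != seq[pos]]), "SNV", af=0.5)
            elif kind == "DEL":
                ln = rng.randint(1, 5)
                v = Variant("chr1", pos, seq[pos : pos + 1 + ln], seq[pos], "DEL", af=0.5)
            else:
                v = Variant("chr1", pos, seq[pos], seq[pos] + random_seq(rng, rng.randint(1, 5)), "INS", af=0.5)
            hap = apply_haplotype(seq, 0, [v])
            # invert: splice REF back over the alt span
            a, b, _ = hap.applied_spans[0]
            restored = hap.alt_seq[:a] + v.ref_allele + hap.alt_seq[b:]
            assert restored == seq
            assert all(x <= y for x, y in zip(hap.coord_map, hap.coord_map[1:]))


class TestEnumerateHaplotypes:
    def _window(self, variants, focal_idx=0, k=21, w=11, clen=5000):
        wins = build_windows(variants, IndexParams(k=k, w=w), {"chr1": clen})
        return wins[focal_idx]

    def test_lone_focal_yields_one_haplotype(self, rng):
        seq = random_seq(rng, 5000)
        v = _snv(1000, seq[1000], "A" if seq[1000] != "A" else "C")
        haps = enumerate_haplotypes(self._window([v]), seq)
        assert len(haps) == 1
        diffs = [
            i for i, (a, b) in enumerate(zip(haps[0].alt_seq, seq[969:1032])) if a != b
        ]
        assert diffs == [31]

    def test_unphased_neighbors_expand_combinatorially(self, rng):
        seq = random_seq(rng, 5000)
        vs = [
            _snv(p, seq[p], "A" if seq[p] != "A" else "C") for p in (1000, 1010, 1020)
        ]
        haps = enumerate_haplotypes(self._window(vs, focal_idx=0), seq)
        assert len(haps) == 4  # focal fixed ALT x 2^2 neighbour subsets
        assert all(any(v.pos0 == 1000 for v in h.applied) for h in haps)

    def test_phased_cooccurring_pattern_only(self, rng):
        """Two variants phased 1|0 in one sample travel together."""
        seq = random_seq(rng, 5000)
        gts = (((1, 0), True),)
        vs = [
            _snv(1000, seq[1000], "A" if seq[1000] != "A" else "C", genotypes=gts),
            _snv(1010, seq[1010], "A" if seq[1010] != "A" else "C", genotypes=gts),
        ]
        haps = enumerate_haplotypes(self._window(vs, focal_idx=0), seq)
        assert len(haps) == 1
        assert {v.pos0 for v in haps[0].applied} == {1000, 1010}

    def test_phased_opposite_haplotypes_never_combined(self, rng):
        seq = random_seq(rng, 5000)
        vs = [
            _snv(1000, seq[1000], "A" if seq[1000] != "A" else "C", genotypes=(((1, 0), True),)),
            _snv(1010, seq[1010], "A" if seq[1010] != "A" else "C", genotypes=(((0, 1), True),)),
        ]
        haps = enumerate_haplotypes(self._window(vs, focal_idx=0), seq)
        assert len(haps) == 1
        assert {v.pos0 for v in haps[0].applied} == {1000}

    def test_skipped_window_rejected(self, rng):
        seq = random_seq(rng, 5000)
        vs = [_snv(1000 + 2 * i, seq[1000 + 2 * i], "A" if seq[1000 + 2 * i] != "A" else "C") for i in range(12)]
        win = self._window(vs)
        with pytest.raises(ValueError, match="status"):
            enumerate_haplotypes(win, seq)
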