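"""Promoter extraction, core-element scan, IR detection, motif machinery."""

import numpy as np
import pytest

from acascan.genomic_context import Operon
from acascan.promoter_analysis import (
    InvertedRepeat,
    Motif,
    PromoterRegion,
    classify_ir,
    classify_promoter_irs,
    compare_motifs,
    discover_motif,
    extract_promoter,
    find_inverted_repeats,
    scan_core_promoter,
    scan_motif,
    calibrate_core_threshold,
)
from acascan.records import CdsFeature, GenomeRecord, revcomp
from acascan.synthetic_data import random_dna


def cds(cid, start, end, strand="+", contig="c1"):
    return CdsFeature(cid, contig, start, end, strand, translation="M")


def brute_force_irs(seq, arm_range=(4, 10), spacer_range=(0, 12), max_mismatch=1):
    """Exhaustive (position, arm, spacer) enumeration with explicit maximality."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(seq)

    def mism(l, arm, sp):
        r = l + arm + sp
        return sum(
            1 for i in range(arm) if seq[l + i] != comp.get(seq[r + arm - 1 - i], "?")
        )

    def ok(l, arm, sp):
        return (
            arm_range[0] <= arm <= arm_range[1]
            and spacer_range[0] <= sp <= spacer_range[1]
            and l >= 0
            and l + 2 * arm + sp <= L
            and mism(l, arm, sp) <= max_mismatch
        )

    found = []
    for arm in range(arm_range[0], arm_range[1] + 1):
        for sp in range(spacer_range[0], spacer_range[1] + 1):
            for l in range(0, L - 2 * arm - sp + 1):
                if not ok(l, arm, sp):
                    continue
                if ok(l - 1, arm + 1, sp) or ok(l, arm + 1, sp - 2):
                    continue
                found.append((l, arm, sp, mism(l, arm, sp)))
    return sorted(found)


def as_tuples(irs):
    return sorted((ir.left[0], ir.arm_length, ir.spacer, ir.mismatches) for ir in irs)


class TestExtractPromoter:
    def test_plus_strand_window_immediately_upstream(self):
        seq = random_dna(2000, 0.5, np.random.default_rng(0))
        g = GenomeRecord("c1", seq, [cds("a", 400, 700)])
        op = Operon("op1", "+", g.features)
        region = extract_promoter(g, op, length=400)
        assert (region.start, region.end) == (0, 400)
        assert region.sequence == seq[0:400]
        assert region.sequence[-1] == seq[399]  # position -1 touches the start codon
        assert not region.clipped

    def test_minus_strand_window_reverse_complemented(self):
        seq = random_dna(1000, 0.5, np.random.default_rng(1))
        g = GenomeRecord("c1", seq, [cds("a", 300, 600, "-")])
        op = Operon("op1", "-", g.features)
        region = extract_promoter(g, op, length=400)
        assert (region.start, region.end) == (600, 1000)
        assert region.sequence == revcomp(seq[600:1000])

    def test_leader_near_contig_start_clipped(self):
        seq = random_dna(500, 0.5, np.random.default_rng(2))
        g = GenomeRecord("c1", seq, [cds("a", 99, 300)])
        op = Operon("op1", "+", g.features)
        region = extract_promoter(g, op, length=400)
        assert len(region.sequence) == 99
        assert region.clipped

    def test_leader_flush_with_edge_gives_empty_flagged_region(self):
        g = GenomeRecord("c1", "ATGAAATAA" * 10, [cds("a", 0, 9)])
        region = extract_promoter(g, Operon("op1", "+", g.features))
        assert region.sequence == "" and region.clipped


class TestScanCorePromoter:
    def _planted(self, spacer=17, seed=3):
        rng = np.random.default_rng(seed)
        seq = list(random_dna(200, 0.5, rng))
        m10 = 200 - 30
        m35 = m10 - spacer - 6
        seq[m35 : m35 + 6] = "TTGACA"
        seq[m10 : m10 + 6] = "TATAAT"
        return "".join(seq), m35, m10

    def test_exact_consensus_recovered_at_planted_positions(self):
        seq, m35, m10 = self._planted()
        call = scan_core_promoter(PromoterRegion("o", "c", 0, 200, "+", seq))
        assert call.minus35.position == m35
        assert call.minus10.position == m10
        assert call.spacer == 17
        assert call.minus35.hexamer == "TTGACA" and call.minus10.hexamer == "TATAAT"

    def test_tie_broken_toward_three_prime_most_minus10(self):
        rng = np.random.default_rng(9)
        seq = list("G" * 160)
        for m10 in (60, 120):
            m35 = m10 - 17 - 6
            seq[m35 : m35 + 6] = "TTGACA"
            seq[m10 : m10 + 6] = "TATAAT"
        call = scan_core_promoter(PromoterRegion("o", "c", 0, 160, "+", "".join(seq)))
        assert call.minus10.position == 120

    def test_background_significance_rate_matches_calibration(self):
        rng = np.random.default_rng(11)
        null = [random_dna(150, 0.5, rng) for _ in range(400)]
        thr = calibrate_core_threshold(null, quantile=0.99)
        fresh = [random_dna(150, 0.5, rng) for _ in range(400)]
        n_sig = sum(
            scan_core_promoter(
                PromoterRegion("o", "c", 0, 150, "+", s), threshold=thr
            ).significant
            for s in fresh
        )
        assert n_sig / len(fresh) <= 0.04  # ~1% nominal, allow sampling noise

    def test_too_short_region_returns_none(self):
        assert scan_core_promoter(PromoterRegion("o", "c", 0, 10, "+", "ACGTACGTAC")) is None


class TestFindInvertedRepeats:
    def test_constructed_palindrome_found_exactly(self):
        seq = "TTGACA" + "GGGTC" + "TGTCAA"
        irs = find_inverted_repeats(seq, arm_range=(4, 6), spacer_range=(0, 8), max_mismatch=0)
        best = irs[0]
        assert best.arm_length == 6 and best.spacer == 5 and best.mismatches == 0
        assert seq[best.left[0] : best.left[1]] == "TTGACA"
        assert seq[best.right[0] : best.right[1]] == "TGTCAA"

    def test_homopolymer_has_no_inverted_repeat(self):
        assert find_inverted_repeats("A" * 60, max_mismatch=0) == []

    @pytest.mark.parametrize(
        "params",
        [
            dict(arm_range=(4, 10), spacer_range=(0, 12), max_mismatch=1),
            dict(arm_range=(4, 8), spacer_range=(0, 6), max_mismatch=0),
            dict(arm_range=(5, 12), spacer_range=(2, 10), max_mismatch=2),
        ],
    )
    def test_matches_bruteforce_oracle(self, params, rng):
        for _ in range(25):
            seq = random_dna(150, 0.5, rng)
            assert as_tuples(find_inverted_repeats(seq, **params)) == brute_force_irs(
                seq, **params
            ), seq

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            seq = random_dna(120, 0.5, rng)
            fwd = find_inverted_repeats(seq)
            rev = find_inverted_repeats(revcomp(seq))
            L = len(seq)
            mirrored = sorted(
                (L - ir.right[1], ir.arm_length, ir.spacer, ir.mismatches) for ir in fwd
            )
            assert mirrored == as_tuples(rev)

    def test_degenerate_arm_bound_rejected(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT", arm_range=(1, 3))


class TestClassifyIr:
    def _core(self, m35=40, spacer=17):
        from acascan.promoter_analysis import CorePromoterCall, ElementCall

        m10 = m35 + 6 + spacer
        return CorePromoterCall(
            minus35=ElementCall(m35, "TTGACA", 0.0),
            minus10=ElementCall(m10, "TATAAT", 0.0),
            spacer=spacer,
            total_score=10.0,
            significant=True,
        )

    def test_ir_spanning_minus10_is_ir1(self):
        core = self._core(m35=40)
        ir = InvertedRepeat(left=(60, 66), right=(70, 76), arm_length=6, spacer=4, mismatches=0)
        assert classify_ir(ir, core) == "IR1"

    def test_ir_fully_upstream_of_minus35_is_ir2(self):
        core = self._core(m35=40)
        ir = InvertedRepeat(left=(5, 11), right=(15, 21), arm_length=6, spacer=4, mismatches=0)
        assert classify_ir(ir, core) == "IR2"

    def test_missing_core_leaves_unclassified(self):
        ir = InvertedRepeat(left=(5, 11), right=(15, 21), arm_length=6, spacer=4, mismatches=0)
        assert classify_ir(ir, None) == "unclassified"


class TestDiscoverMotif:
    def test_zero_noise_recovers_planted_word_and_sites(self):
        rng = np.random.default_rng(17)
        word = random_dna(18, 0.5, rng)
        seqs, offsets = [], []
        for i in range(20):
            bg = list(random_dna(150, 0.5, rng))
            off = int(rng.integers(150 - 18 + 1))
            bg[off : off + 18] = word
            seqs.append("".join(bg))
            offsets.append(off)
        motif = discover_motif(seqs, width=18, mode="oops", n_restarts=3, iterations=120, seed=5)
        cons = motif.consensus
        assert cons == word or revcomp(cons) == word
        # a site covers the same window whichever strand the motif settled on
        recovered = {s[0]: s[1] for s in motif.sites}
        assert [recovered[f"seq{i}"] for i in range(20)] == offsets

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(23)
        seqs = [random_dna(120, 0.5, rng) for _ in range(8)]
        a = discover_motif(seqs, width=12, n_restarts=2, iterations=60, seed=77)
        b = discover_motif(seqs, width=12, n_restarts=2, iterations=60, seed=77)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.sites == b.sites

    def test_width_longer_than_shortest_promoter_rejected(self):
        with pytest.raises(ValueError):
            discover_motif(["ACGTACGT", "ACGT"], width=6)

    def test_information_content_definition(self):
        m = Motif(np.array([[4, 0, 0, 0], [1, 1, 1, 1]]), np.full(4, 0.25))
        # col1: point mass -> 2 bits; col2: uniform -> 0 bits
        assert m.information_content == pytest.approx(2.0, abs=1e-9)


class TestScanMotif:
    def _motif_from(self, word):
        counts = np.zeros((len(word), 4))
        for j, b in enumerate(word):
            counts[j, "ACGT".index(b)] = 10
        return Motif(counts, np.full(4, 0.25))

    def test_embedded_consensus_found_at_maximal_score(self):
        rng = np.random.default_rng(3)
        word = "TTGACATGCAGT"
        seq = list(random_dna(100, 0.5, rng))
        seq[40 : 40 + len(word)] = word
        m = self._motif_from(word)
        hits = scan_motif(m, "".join(seq), score_threshold=m.log_odds.max(axis=1).sum() - 1e-9)
        assert any(h[0] == 40 and h[1] == "+" for h in hits)

    def test_threshold_above_maximum_gives_no_hits(self):
        m = self._motif_from("ACGTACGT")
        assert scan_motif(m, "ACGTACGTACGT", m.log_odds.max(axis=1).sum() + 1.0) == []

    def test_matches_exhaustive_window_oracle(self, rng):
        m = self._motif_from("TTGACATG")
        lo = m.log_odds
        for _ in range(10):
            seq = random_dna(80, 0.5, rng)
            got = scan_motif(m, seq, score_threshold=0.0)
            exp = []
            for off in range(len(seq) - m.width + 1):
                for strand, window in (
                    ("+", seq[off : off + m.width]),
                    ("-", revcomp(seq[off : off + m.width])),
                ):
                    s = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(window))
                    if s >= 0.0:
                        exp.append((off, strand, pytest.approx(s)))
            exp.sort(key=lambda h: (h[0], h[1]))
            assert got == exp


class TestCompareMotifs:
    def _random_motif(self, rng, width):
        return Motif(rng.integers(0, 9, size=(width, 4)).astype(float), np.full(4, 0.25))

    def test_self_comparison_perfect_forward(self, rng):
        m = self._random_motif(rng, 10)
        offset, orientation, corr = compare_motifs(m, m, min_overlap=5)
        assert (offset, orientation) == (0, "forward")
        assert corr == pytest.approx(1.0)

    def test_reverse_complement_perfect_reverse(self, rng):
        m = self._random_motif(rng, 10)
        rc = Motif(m.counts[::-1, ::-1].copy(), m.background)
        offset, orientation, corr = compare_motifs(m, rc, min_overlap=5)
        assert orientation == "reverse"
        assert corr == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        def oracle(a, b, min_overlap):
            fa, fb = a.frequencies, b.frequencies
            best = None
            for ori, mat in (("forward", fb), ("reverse", fb[::-1, ::-1])):
                wa, wb = len(fa), len(mat)
                for off in range(-wb + min_overlap, wa - min_overlap + 1):
                    cols = [
                        (fa[j], mat[j - off])
                        for j in range(max(0, off), min(wa, off + wb))
                    ]
                    if len(cols) < min_overlap:
                        continue
                    cs = []
                    for u, v in cols:
                        su, sv = u.std(), v.std()
                        if su == 0 and sv == 0:
                            cs.append(1.0 if np.allclose(u, v) else 0.0)
                        elif su == 0 or sv == 0:
                            cs.append(0.0)
                        else:
                            cs.append(float(np.corrcoef(u, v)[0, 1]))
                    cand = (float(np.mean(cs)), ori == "forward", -abs(off), off, ori)
                    if best is None or cand > best:
                        best = cand
            return best[3], best[4], best[0]

        for _ in range(10):
            a = self._random_motif(rng, int(rng.integers(6, 12)))
            b = self._random_motif(rng, int(rng.integers(6, 12)))
            got = compare_motifs(a, b, min_overlap=5)
            exp = oracle(a, b, 5)
            assert got[:2] == exp[:2]
            assert got[2] == pytest.approx(exp[2])


def test_planted_promoter_ir_detected_and_classified_ir1():
    """Planted IR overlapping the core element comes out labelled IR1."""
    from acascan.synthetic_data import PlantedPromoterSpec, plant_promoter

    spec = PlantedPromoterSpec(ir_mismatches=0)
    seq, els = plant_promoter(spec, 400, seed=31)
    window = seq[-150:]
    off0 = len(seq) - len(window)
    core = scan_core_promoter(PromoterRegion("o", "c", 0, 400, "+", seq))
    irs = [
        InvertedRepeat(
            (ir.left[0] + off0, ir.left[1] + off0),
            (ir.right[0] + off0, ir.right[1] + off0),
            ir.arm_length,
            ir.spacer,
            ir.mismatches,
        )
        for ir in find_inverted_repeats(window)
    ]
    irs = classify_promoter_irs(irs, core)
    planted = els["irs"][0]
    matched = [
        ir
        for ir in irs
        if ir.left[0] < planted["left"][1]
        and ir.left[1] > planted["left"][0]
        and ir.right[0] < planted["right"][1]
        and ir.right[1] > planted["right"][0]
    ]
    assert matched and any(ir.classification == "IR1" for ir in matched)
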