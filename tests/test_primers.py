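import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from panelseq.primers import (
    MaskedSequenceError,
    NoPair,
    PenaltyWeights,
    PrimerConstraints,
    PrimerPair,
    TmParams,
    gc_content,
    mask_polymorphic,
    melting_temperature,
    pick_primer_pair,
    reverse_complement,
)


def random_window(rng, n=301, gc=0.55):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=n))


class TestMasking:
    COORDS = ("chr1", 1001, 1030)

    def test_no_variants_unchanged(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        assert mask_polymorphic(seq, self.COORDS, []) == seq

    def test_single_variant_masked(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        out = mask_polymorphic(seq, self.COORDS, [("chr1", 1011)])
        assert out[10] == "N"
        assert out[:10] == seq[:10] and out[11:] == seq[11:]

    def test_target_marker_never_masked(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        out = mask_polymorphic(
            seq, self.COORDS, [("chr1", 1011), ("chr1", 1016)], target_pos=1016
        )
        assert out[10] == "N" and out[15] == seq[15]

    def test_outside_and_other_chrom_ignored(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        out = mask_polymorphic(
            seq, self.COORDS, [("chr1", 1000), ("chr1", 1031), ("chr2", 1011)]
        )
        assert out == seq

    def test_idempotent_and_matches_union_oracle(self, rng):
        seq = random_window(rng, 120)
        coords = ("chr3", 501, 620)
        variants = [("chr3", int(p)) for p in rng.integers(400, 700, size=60)]
        out = mask_polymorphic(seq, coords, variants)
        expected = list(seq)
        for _, p in variants:
            if 501 <= p <= 620:
                expected[p - 501] = "N"
        assert out == "".join(expected)
        assert mask_polymorphic(out, coords, variants) == out

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            mask_polymorphic("ACGT", ("chr1", 1, 10), [])


class TestTmAndGc:
    def test_gc_arithmetic(self):
        assert gc_content("ACGT") == 50.0
        assert gc_content("AAAA") == 0.0
        assert gc_content("GGCC") == 100.0

    def test_tm_matches_independent_nearest_neighbor_reference(self, rng):
        """30 random 25-mers within 1.5 degC of Biopython's NN model
        under identical salt/concentration conditions."""
        params = TmParams()
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=25))
            ours = melting_temperature(seq, params)
            ref = mt.Tm_NN(
                seq,
                nn_table=mt.DNA_NN3,
                Na=params.monovalent_mM,
                dnac1=params.primer_nM,
                dnac2=params.template_nM,
                saltcorr=5,
            )
            assert abs(ours - ref) < 1.5

    def test_masked_sequence_rejected(self):
        with pytest.raises(MaskedSequenceError):
            melting_temperature("ACGTNACGTACG")

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestPickPrimerPair:
    def test_window_too_short_names_product_size(self):
        out = pick_primer_pair("ACGT" * 30, 60, marker_id="m1")  # 120 bp
        assert out == NoPair("m1", "product_size")

    def test_returned_pair_satisfies_all_constraints(self, rng):
        c = PrimerConstraints()
        found = 0
        for i in range(10):
            window = random_window(rng)
            out = pick_primer_pair(window, 150, marker_id=f"m{i}", window_start=1)
            if isinstance(out, NoPair):
                continue
            found += 1
            for seq, tm, gc in [
                (out.left_seq, out.left_tm, out.left_gc),
                (out.right_seq, out.right_tm, out.right_gc),
            ]:
                assert c.len_min <= len(seq) <= c.len_max
                assert c.tm_min <= tm <= c.tm_max
                assert c.gc_min <= gc <= c.gc_max
            assert c.product_min <= out.product_size <= c.product_max
            # marker strictly inside the product, outside both primers
            left_end = out.left_start + len(out.left_seq) - 1
            right_start = out.right_end - len(out.right_seq) + 1
            assert left_end < 151 < right_start
            assert out.product_size == out.right_end - out.left_start + 1
        assert found >= 5  # GC-rich windows are usually designable

    def test_right_primer_is_reverse_complement_of_window(self, rng):
        window = random_window(rng)
        out = pick_primer_pair(window, 150, window_start=1)
        assert isinstance(out, PrimerPair)
        rstart = out.right_end - len(out.right_seq) + 1
        fwd = window[rstart - 1 : out.right_end]
        assert reverse_complement(out.right_seq) == fwd

    def test_primers_never_cover_masked_bases(self, rng):
        window = random_window(rng)
        masked = mask_polymorphic(
            window,
            ("chr1", 1, len(window)),
            [("chr1", int(p)) for p in rng.integers(1, 302, size=25)],
            target_pos=151,
        )
        out = pick_primer_pair(masked, 150, window_start=1)
        if isinstance(out, PrimerPair):
            assert "N" not in out.left_seq and "N" not in out.right_seq

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        window = random_window(rng, 300)
        c = PrimerConstraints()
        w = PenaltyWeights()
        params = TmParams()
        out = pick_primer_pair(window, 150, c, w, params, window_start=1)

        def primer_ok(sub):
            if "N" in sub:
                return None
            gc = gc_content(sub)
            if not (c.gc_min <= gc <= c.gc_max):
                return None
            tm = melting_temperature(sub, params)
            if not (c.tm_min <= tm <= c.tm_max):
                return None
            return tm

        lefts, rights = [], []
        for length in range(c.len_min, c.len_max + 1):
            for start in range(0, 300 - length + 1):
                sub = window[start : start + length]
                tm = primer_ok(sub)
                if tm is None:
                    continue
                if start + length - 1 < 150:
                    lefts.append((start, length, tm))
                if start > 150:
                    rights.append((start, length, tm))

        best, best_key = None, None
        for ls, ll, ltm in lefts:
            for rs, rl, rtm in rights:
                product = rs + rl - ls
                if not (c.product_min <= product <= c.product_max):
                    continue
                pen = abs(ll - 25) + abs(rl - 25) + abs(ltm - 65) + abs(rtm - 65) + abs(ltm - rtm)
                key = (pen, ls, product, ll)
                if best_key is None or key < best_key:
                    best, best_key = (ls, ll, rs, rl), key
        if best is None:
            assert isinstance(out, NoPair)
        else:
            assert isinstance(out, PrimerPair)
            ls, ll, rs, rl = best
            assert out.left_start == ls + 1
            assert len(out.left_seq) == ll
            assert out.right_end == rs + rl
            assert len(out.right_seq) == rl
            assert out.penalty == pytest.approx(best_key[0])

    def test_all_masked_window_yields_no_pair(self):
        out = pick_primer_pair("N" * 301, 150, marker_id="m")
        assert isinstance(out, NoPair)
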