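import numpy as np
import pytest

from panelseq.discovery import (
    CandidateSNP,
    DiscoveryParams,
    intersect_callers,
    merge_candidates,
    purify_against_self,
    select_biallelic_shared,
    supplement_by_allele_fraction,
)
from panelseq.io_formats import BASES, GenomeSequence, SiteAlleleCounts, VariantRecord

CALLERS = ["cA", "cB", "cC", "cD", "cE"]


def rec(pos, depth=10, mq=30.0, caller="cA", ref="A", alt="G", chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt, depth, mq, caller, "acc1")


def params(**kw):
    kw.setdefault("required_callers", frozenset(CALLERS))
    return DiscoveryParams(**kw)


class TestIntersectCallers:
    def test_unanimous_site_emitted(self):
        per_caller = {c: [rec(100, caller=c)] for c in CALLERS}
        out = intersect_callers(per_caller, params())
        assert [c.site for c in out] == [("chr1", 100, "A", "G")]
        assert out[0].source == "consensus"

    def test_depth_boundary_five_in_four_out(self):
        ok = {c: [rec(100, depth=5, caller=c)] for c in CALLERS}
        assert len(intersect_callers(ok, params())) == 1
        low = dict(ok)
        low["cE"] = [rec(100, depth=4, caller="cE")]
        assert intersect_callers(low, params()) == []

    def test_mq_boundary(self):
        ok = {c: [rec(100, mq=20.0, caller=c)] for c in CALLERS}
        assert len(intersect_callers(ok, params())) == 1
        low = dict(ok)
        low["cA"] = [rec(100, mq=19.9, caller="cA")]
        assert intersect_callers(low, params()) == []

    def test_allele_mismatch_not_intersected(self):
        per_caller = {c: [rec(100, caller=c)] for c in CALLERS}
        per_caller["cB"] = [rec(100, caller="cB", alt="T")]
        assert intersect_callers(per_caller, params()) == []

    def test_empty_required_caller_warns_empty_result(self, caplog):
        per_caller = {c: [rec(100, caller=c)] for c in CALLERS[:-1]}
        per_caller["cE"] = []
        assert intersect_callers(per_caller, params()) == []

    def test_matches_brute_force_oracle(self, rng):
        # 200 sites, independent 20 % per-caller dropout, random depth/MQ
        sites = [
            (f"chr{rng.integers(1, 3)}", int(p), "C", "T")
            for p in sorted(rng.choice(np.arange(1, 10_000), 200, replace=False))
        ]
        per_caller = {c: [] for c in CALLERS}
        table = {}  # (site, caller) -> record or None
        for site in sites:
            for c in CALLERS:
                if rng.random() < 0.2:
                    table[(site, c)] = None
                    continue
                r = VariantRecord(
                    site[0], site[1], site[2], site[3],
                    int(rng.integers(0, 15)), float(rng.integers(0, 45)), c, "acc1",
                )
                per_caller[c].append(r)
                table[(site, c)] = r

        p = params()
        expected = sorted(
            (
                s
                for s in sites
                if all(
                    table[(s, c)] is not None
                    and table[(s, c)].depth >= p.min_depth
                    and table[(s, c)].mapping_quality >= p.min_mq
                    for c in CALLERS
                )
            ),
            key=lambda s: (s[0], s[1], s[3]),
        )
        got = intersect_callers(per_caller, p)
        assert [c.site for c in got] == expected

    def test_output_subset_of_every_filtered_input(self, rng):
        per_caller = {
            c: [
                rec(int(p), depth=int(rng.integers(0, 12)), caller=c)
                for p in rng.choice(np.arange(1, 500), 60, replace=False)
            ]
            for c in CALLERS
        }
        out = intersect_callers(per_caller, params())
        for c in CALLERS:
            filtered = {
                r.site
                for r in per_caller[c]
                if r.depth >= 5 and r.mapping_quality >= 20
            }
            assert {cand.site for cand in out} <= filtered

    def test_raising_threshold_never_grows_output(self, rng):
        per_caller = {
            c: [
                rec(int(p), depth=int(rng.integers(0, 12)),
                    mq=float(rng.integers(0, 45)), caller=c)
                for p in rng.choice(np.arange(1, 500), 80, replace=False)
            ]
            for c in CALLERS
        }
        sizes = [
            len(intersect_callers(per_caller, params(min_depth=d, min_mq=mq)))
            for d, mq in [(0, 0), (5, 20), (8, 30), (12, 45)]
        ]
        assert sizes == sorted(sizes, reverse=True)


def counts(pos, ref_n, alt_n, acc, ref="A", alt="G", chrom="chr1"):
    c = [0, 0, 0, 0]
    c[BASES.index(ref)] = ref_n
    c[BASES.index(alt)] = alt_n
    return SiteAlleleCounts(chrom, pos, acc, tuple(c))


@pytest.fixture
def reference():
    return GenomeSequence(["chr1"], {"chr1": "A" * 10_000})


class TestSupplement:
    ACCS = ["x", "y", "z"]

    def p(self):
        return DiscoveryParams(required_accessions=frozenset(self.ACCS))

    def test_boundary_095_emitted(self, reference):
        tables = {a: [counts(100, 1, 19, a)] for a in self.ACCS}
        out = supplement_by_allele_fraction(tables, reference, self.p())
        assert [(c.chrom, c.pos, c.ref_allele, c.alt_allele, c.source) for c in out] == [
            ("chr1", 100, "A", "G", "allele_fraction")
        ]

    def test_090_in_one_accession_blocks(self, reference):
        tables = {a: [counts(100, 1, 19, a)] for a in self.ACCS}
        tables["z"] = [counts(100, 2, 18, "z")]
        assert supplement_by_allele_fraction(tables, reference, self.p()) == []

    def test_depth_below_min_blocks(self, reference):
        tables = {a: [counts(100, 0, 4, a)] for a in self.ACCS}
        assert supplement_by_allele_fraction(tables, reference, self.p()) == []

    def test_conflicting_majority_alt_blocks(self, reference):
        tables = {a: [counts(100, 0, 20, a)] for a in self.ACCS}
        tables["y"] = [counts(100, 0, 20, "y", alt="T")]
        assert supplement_by_allele_fraction(tables, reference, self.p()) == []

    def test_nonref_tie_disqualifies(self, reference):
        c = [0, 10, 10, 0]  # ref A, C and G tie at 10
        tables = {
            a: [SiteAlleleCounts("chr1", 100, a, tuple(c))] for a in self.ACCS
        }
        assert supplement_by_allele_fraction(tables, reference, self.p()) == []

    def test_position_absent_in_one_accession_ineligible(self, reference):
        tables = {a: [counts(100, 0, 20, a)] for a in self.ACCS}
        tables["x"] = []
        assert supplement_by_allele_fraction(tables, reference, self.p()) == []

    def test_position_off_reference_is_error(self, reference):
        tables = {a: [counts(20_000, 0, 20, a)] for a in self.ACCS}
        with pytest.raises(ValueError):
            supplement_by_allele_fraction(tables, reference, self.p())

    def test_matches_brute_force_scan(self, reference, rng):
        positions = sorted(rng.choice(np.arange(1, 9000), 80, replace=False))
        tables = {a: [] for a in self.ACCS}
        for pos in positions:
            for a in self.ACCS:
                depth = int(rng.integers(2, 30))
                alt_n = int(rng.integers(0, depth + 1))
                tables[a].append(counts(int(pos), depth - alt_n, alt_n, a))
        got = supplement_by_allele_fraction(tables, reference, self.p())

        expected = []
        for i, pos in enumerate(positions):
            rows = [tables[a][i] for a in self.ACCS]
            if all(
                r.depth >= 5 and r.count("G") / r.depth >= 0.95 for r in rows
            ):
                expected.append(("chr1", int(pos), "A", "G"))
        assert [c.site for c in got] == expected


class TestPurify:
    def cand(self, pos):
        return CandidateSNP("chr1", pos, "A", "G", "consensus")

    def p(self):
        return DiscoveryParams()

    def test_clean_site_retained(self):
        out = purify_against_self([self.cand(5)], [counts(5, 20, 0, "self")], self.p())
        assert len(out) == 1

    def test_boundary_strictly_greater_than_5pct(self):
        # 1/20 = 5 % exactly -> retained; 6 % -> removed
        keep = purify_against_self(
            [self.cand(5)], [counts(5, 19, 1, "self")], self.p()
        )
        assert len(keep) == 1
        drop = purify_against_self(
            [self.cand(5)], [counts(5, 47, 3, "self")], self.p()  # 3/50 = 6 %
        )
        assert drop == []

    def test_no_self_coverage_retained(self):
        out = purify_against_self([self.cand(5)], [], self.p())
        assert len(out) == 1

    def test_idempotent_monotone_matches_oracle(self, rng):
        cands = [self.cand(int(p)) for p in range(1, 101)]
        self_rows = []
        fracs = {}
        for c in cands:
            depth = 50
            bad = int(rng.integers(0, 10))
            fracs[c.pos] = bad / depth
            self_rows.append(counts(c.pos, depth - bad, bad, "self"))
        out = purify_against_self(cands, self_rows, self.p())
        expected = [c for c in cands if fracs[c.pos] <= 0.05]
        assert out == expected
        assert purify_against_self(out, self_rows, self.p()) == out
        assert set(c.site for c in out) <= set(c.site for c in cands)


class TestSharedBiallelic:
    def cand(self, pos, alt="T", acc="a"):
        return CandidateSNP("chr1", pos, "A", alt, "consensus")

    def test_shared_alt_emitted(self):
        per_acc = {f"a{i}": [self.cand(500)] for i in range(8)}
        out = select_biallelic_shared(per_acc, list(per_acc))
        assert [c.site for c in out] == [("chr1", 500, "A", "T")]

    def test_conflicting_alternate_excluded(self):
        per_acc = {f"a{i}": [self.cand(500)] for i in range(7)}
        per_acc["a7"] = [self.cand(500, alt="C")]
        assert select_biallelic_shared(per_acc, list(per_acc)) == []

    def test_multiallelic_evidence_excluded(self):
        per_acc = {f"a{i}": [self.cand(500)] for i in range(8)}
        per_acc["a0"] = [self.cand(500), self.cand(500, alt="G")]
        assert select_biallelic_shared(per_acc, list(per_acc)) == []

    def test_empty_accessions_is_error(self):
        with pytest.raises(ValueError):
            select_biallelic_shared({}, [])

    def test_known_mix_matches_hand_enumeration(self):
        accs = ["a", "b", "c"]
        per_acc = {
            # pos 10 shared T; pos 20 conflicting; pos 30 missing in c;
            # pos 40 shared C
            "a": [self.cand(10), self.cand(20, "T"), self.cand(30), self.cand(40, "C")],
            "b": [self.cand(10), self.cand(20, "C"), self.cand(30), self.cand(40, "C")],
            "c": [self.cand(10), self.cand(20, "T"), self.cand(40, "C")],
        }
        out = select_biallelic_shared(per_acc, accs)
        assert [c.site for c in out] == [
            ("chr1", 10, "A", "T"),
            ("chr1", 40, "A", "C"),
        ]


class TestMerge:
    def test_union_has_no_duplicate_positions(self):
        cons = [CandidateSNP("chr1", 10, "A", "G", "consensus")]
        supp = [
            CandidateSNP("chr1", 10, "A", "G", "allele_fraction"),
            CandidateSNP("chr1", 20, "C", "T", "allele_fraction"),
        ]
        merged = merge_candidates(cons, supp)
        assert [(c.pos, c.source) for c in merged] == [
            (10, "consensus"),
            (20, "allele_fraction"),
        ]
        keys = [(c.chrom, c.pos) for c in merged]
        assert len(keys) == len(set(keys))


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"min_alt_fraction": 0.0},
            {"min_alt_fraction": 1.2},
            {"max_self_discordance": 1.0},
            {"min_depth": -1},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            DiscoveryParams(**kw)
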