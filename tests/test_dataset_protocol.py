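"""Set-construction protocol: filters, identity backends, ECOD homology."""

import datetime

import pytest

from sscnn.dataset_protocol import (
    AlignmentIdentityBackend,
    ChainMetadataRecord,
    ECODTable,
    MatrixIdentityBackend,
    builtin_identity,
    cross_set_identity_filter,
    date_split,
    dedup_identical,
    ecod_homology_filter,
    ecod_lookup,
    intra_set_identity_reduce,
    quality_filter,
    quality_sort_key,
    read_metadata_tsv,
    train_valid_split,
    write_metadata_tsv,
)
from sscnn.synthetic_data import GeneratorConfig, simulate_metadata

CUTOFF = datetime.date(2018, 1, 1)


def rec(pdb, chain="A", seq="ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY",
        date=datetime.date(2017, 6, 1), res=2.0, rfree=0.20, rwork=None,
        ca_only=False, n_coords=None):
    return ChainMetadataRecord(
        pdb_id=pdb, chain_id=chain, sequence=seq, release_date=date,
        resolution=res, r_free=rfree, r_work=rwork, ca_only=ca_only,
        n_coords=n_coords if n_coords is not None else len(seq))


class TestDateSplit:
    def test_boundary(self):
        before = rec("b001", date=datetime.date(2017, 12, 31))
        on = rec("a001", date=datetime.date(2018, 1, 1))
        b, a = date_split([before, on], CUTOFF)
        assert b == [before] and a == [on]

    def test_empty(self):
        assert date_split([], CUTOFF) == ([], [])

    def test_missing_date(self):
        r = ChainMetadataRecord(pdb_id="x", chain_id="A", sequence="MKVL")
        with pytest.raises(ValueError, match="date"):
            date_split([r], CUTOFF)


class TestDedup:
    def test_resolution_wins(self):
        lo = rec("x001", res=1.5)
        hi = rec("x002", res=2.0)
        survivors, links = dedup_identical([hi, lo])
        assert survivors == [lo]
        assert set(r.key for r in links[lo.key]) == {"x001:A", "x002:A"}

    def test_rfree_breaks_resolution_tie(self):
        a = rec("x001", res=1.5, rfree=0.24)
        b = rec("x002", res=1.5, rfree=0.20)
        survivors, _ = dedup_identical([a, b])
        assert survivors == [b]

    def test_distinct_sequences_unchanged(self):
        a = rec("x001", seq="MKVLAENT" * 6)
        b = rec("x002", seq="GPHYWRDS" * 6)
        survivors, _ = dedup_identical([a, b])
        assert survivors == [a, b]


class TestQualityFilter:
    def test_boundary_values_pass(self):
        r = rec("q001", seq="A" * 40, res=2.2, rfree=0.25)
        assert quality_filter([r]) == [r]

    def test_effective_r_from_rwork(self):
        r = rec("q002", rfree=None, rwork=0.21)  # 0.21 + 0.05 = 0.26 > 0.25
        assert quality_filter([r]) == []
        ok = rec("q003", rfree=None, rwork=0.20)  # exactly 0.25: kept
        assert quality_filter([ok]) == [ok]

    def test_short_chain_rejected(self):
        assert quality_filter([rec("q004", seq="A" * 39)]) == []

    def test_ca_only_rejected(self):
        assert quality_filter([rec("q005", ca_only=True)]) == []

    def test_missing_resolution_rejected(self):
        assert quality_filter([rec("q006", res=None)]) == []

    def test_idempotent(self):
        rs = [rec("q007"), rec("q008", res=2.5)]
        once = quality_filter(rs)
        assert quality_filter(once) == once


class TestBuiltinIdentity:
    def test_identical_sequences(self):
        s = "MKVLINGHEWQRDSTAYFPC"
        assert builtin_identity(s, s, "shortest") == 100.0
        assert builtin_identity(s, s, "aligned") == 100.0

    def test_exact_prefix_is_100_by_shortest(self):
        assert builtin_identity("ACDEFG", "ACD", "shortest") == 100.0

    def test_symmetry_of_shortest_definition(self):
        a, b = "MKVLINGHEWQRDSTAYFPC", "MKVLINGAEWQRDST"
        assert (builtin_identity(a, b, "shortest")
                == builtin_identity(b, a, "shortest"))

    def test_unambiguous_alignment_fraction(self):
        # single substitution in otherwise identical sequences: the optimal
        # global alignment is gapless, identity = 19/20 under both rules
        a = "MKVLINGHEWQRDSTAYFPC"
        b = "MKVLINGAEWQRDSTAYFPC"
        assert builtin_identity(a, b, "shortest") == pytest.approx(95.0)
        assert builtin_identity(a, b, "aligned") == pytest.approx(95.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            builtin_identity("", "MKVL")

    def test_backend_diagonal(self):
        backend = AlignmentIdentityBackend("shortest")
        r = rec("x001")
        assert backend.identity(r, r) == 100.0


class TestCrossSetFilter:
    def test_either_backend_exceeding_removes(self):
        cand, ref = rec("c001"), rec("r001", seq="GPHYWRDS" * 6)
        low = MatrixIdentityBackend({frozenset((cand.key, ref.key)): 20.0})
        high = MatrixIdentityBackend({frozenset((cand.key, ref.key)): 26.0})
        assert cross_set_identity_filter([cand], [ref], [low, high]) == []
        assert cross_set_identity_filter([cand], [ref], [low]) == [cand]

    def test_boundary_25_kept(self):
        cand, ref = rec("c001"), rec("r001", seq="GPHYWRDS" * 6)
        at = MatrixIdentityBackend({frozenset((cand.key, ref.key)): 25.0})
        assert cross_set_identity_filter([cand], [ref], [at]) == [cand]

    def test_empty_reference(self):
        cand = rec("c001")
        backend = MatrixIdentityBackend({})
        assert cross_set_identity_filter([cand], [], [backend]) == [cand]

    def test_requires_backend(self):
        with pytest.raises(ValueError):
            cross_set_identity_filter([rec("c001")], [], [])


class TestIntraSetReduce:
    def _trio(self):
        a = rec("t001", seq="AAKVLING" * 8, res=1.6)
        b = rec("t002", seq="CCKVLING" * 8, res=1.9)
        c = rec("t003", seq="DDKVLING" * 8, res=2.1)
        matrix = {frozenset((x.key, y.key)): 40.0
                  for x in (a, b, c) for y in (a, b, c) if x.key < y.key}
        return [a, b, c], MatrixIdentityBackend(matrix)

    def test_best_resolution_survives(self):
        trio, backend = self._trio()
        assert intra_set_identity_reduce(trio, [backend]) == [trio[0]]

    def test_no_conflicts_unchanged(self):
        trio, _ = self._trio()
        none = MatrixIdentityBackend({})
        assert intra_set_identity_reduce(trio, [none]) == sorted(
            trio, key=quality_sort_key)

    def test_permutation_invariant(self):
        trio, backend = self._trio()
        fwd = intra_set_identity_reduce(trio, [backend])
        rev = intra_set_identity_reduce(trio[::-1], [backend])
        assert fwd == rev

    def test_tie_broken_by_key(self):
        a = rec("t001", seq="AAKVLING" * 8)
        b = rec("t002", seq="CCKVLING" * 8)
        backend = MatrixIdentityBackend({frozenset((a.key, b.key)): 40.0})
        assert intra_set_identity_reduce([b, a], [backend]) == [a]

    def test_idempotent(self):
        trio, backend = self._trio()
        once = intra_set_identity_reduce(trio, [backend])
        assert intra_set_identity_reduce(once, [backend]) == once


class TestTrainValidSplit:
    def test_ratio(self):
        records = [rec(f"p{i:03d}", seq="MKVLINGH" * (5 + i % 3))
                   for i in range(100)]
        train, valid = train_valid_split(records, seed=3)
        assert len(train) == 90 and len(valid) == 10
        assert set(r.key for r in train) | set(r.key for r in valid) == set(
            r.key for r in records)

    def test_deterministic(self):
        records = [rec(f"p{i:03d}") for i in range(20)]
        assert train_valid_split(records, seed=1) == train_valid_split(
            records, seed=1)


ECOD_TEXT = """#uid\tecod_domain_id\tmanual_rep\tf_id\tpdb\tchain\tpdb_range\tseqid_range\tunp\tarch\tx\th\tt\tf\tasm\tlig
1\te1\tF\t1.1.1.4\tabcd\tA\tA:1-50\t1-50\tQ1\ta\tx\th\tt\tf\tNA\tNO
2\te2\tF\t1.1.2.9\tabcd\tA\tA:60-120\t60-120\tQ1\ta\tx\th\tt\tf\tNA\tNO
3\te3\tF\t2.4.1.1\twxyz\tB\tB:1-80\t1-80\tQ2\ta\tx\th\tt\tf\tNA\tNO
"""


class TestECOD:
    def test_table_parsing_collects_xh_groups(self):
        table = ECODTable.from_text(ECOD_TEXT)
        assert table.get("abcd", "A") == {"1.1"}
        assert table.get("wxyz", "B") == {"2.4"}
        assert table.get("none", "A") is None

    def test_lookup_cascade(self):
        table = ECODTable.from_text(ECOD_TEXT)
        seq = "MKVLINGH" * 10
        index = {seq: [("abcd", "A"), ("abcd", "C"), ("qrst", "A")]}

        direct = rec("abcd", "A", seq=seq)
        assert ecod_lookup(direct, table, index) == ({"1.1"}, "direct")

        sibling = rec("abcd", "C", seq=seq)
        assert ecod_lookup(sibling, table, index) == ({"1.1"}, "same_pdb")

        other_entry = rec("qrst", "A", seq=seq)
        # same-pdb siblings take priority; drop them to exercise step 3
        index3 = {seq: [("qrst", "A"), ("abcd", "A")]}
        groups, status = ecod_lookup(other_entry, table, index3)
        assert groups == {"1.1"} and status == "other_pdb"

        lost = rec("lost", "A", seq="GPHYWRDS" * 10)
        assert ecod_lookup(lost, table, {}) == (set(), "unresolved")

    def test_homology_filter(self):
        table = ECODTable.from_text(ECOD_TEXT)
        training = [rec("abcd", "A", seq="MKVLINGH" * 10)]
        shares = rec("wxyz", "B", seq="CCHYWRDS" * 10)   # group 2.4, disjoint
        same = rec("abcd", "A", seq="MKVLINGH" * 10)     # shares 1.1
        unresolved = rec("lost", "A", seq="GPHYWRDS" * 10)
        kept = ecod_homology_filter([shares, same, unresolved], training,
                                    table, {})
        assert kept == [shares]

    def test_empty_training_union_keeps_all(self):
        table = ECODTable.from_text(ECOD_TEXT)
        cand = rec("wxyz", "B")
        assert ecod_homology_filter([cand], [], table, {}) == [cand]


class TestMetadataTSV:
    def test_round_trip(self):
        records = [rec("x001"), rec("x002", res=None, rfree=None, rwork=0.19),
                   rec("x003", ca_only=True)]
        assert read_metadata_tsv(write_metadata_tsv(records)) == records


def brute_force_protocol(fixture, threshold=25.0):
    """Exhaustive-pair reference implementation of the candidate pipeline."""
    backend = MatrixIdentityBackend(fixture.identity)

    before = [r for r in fixture.records
              if r.release_date < fixture.cutoff_date]
    after = [r for r in fixture.records
             if r.release_date >= fixture.cutoff_date]

    def best(group):
        return min(group, key=quality_sort_key)

    def dedup(rs):
        seqs = {}
        for r in rs:
            seqs.setdefault(r.sequence, []).append(r)
        return [best(g) for g in seqs.values()]

    before_d, after_d = dedup(before), dedup(after)
    before_seqs = {r.sequence for r in before_d}
    after_d = [r for r in after_d if r.sequence not in before_seqs]

    def quality_ok(r):
        if r.ca_only or r.resolution is None or r.resolution > 2.2:
            return False
        eff = r.r_free if r.r_free is not None else (
            r.r_work + 0.05 if r.r_work is not None else None)
        if eff is None or eff > 0.25:
            return False
        return len(r.sequence) >= 40

    candidates = [r for r in after_d if quality_ok(r)]
    candidates = [
        c for c in candidates
        if all(backend.identity(c, b) <= threshold for b in before_d)
    ]
    kept = []
    for c in sorted(candidates, key=quality_sort_key):
        if all(backend.identity(c, k) <= threshold for k in kept):
            kept.append(c)
    return {r.key for r in kept}


class TestFullPipelineAgainstBruteForce:
    def test_survivors_match_reference(self):
        fixture = simulate_metadata(GeneratorConfig(), seed=424)
        backend = MatrixIdentityBackend(fixture.identity)

        before, after = date_split(fixture.records, fixture.cutoff_date)
        before_d, _ = dedup_identical(before)
        after_d, _ = dedup_identical(after)
        before_seqs = {r.sequence for r in before_d}
        after_d = [r for r in after_d if r.sequence not in before_seqs]
        test = quality_filter(after_d)
        test = cross_set_identity_filter(test, before_d, [backend])
        test = intra_set_identity_reduce(test, [backend])

        assert {r.key for r in test} == brute_force_protocol(fixture)

    def test_no_survivor_close_to_reference(self):
        # post-hoc audit: every surviving candidate is <= 25% identical to
        # every pre-cutoff chain under the injected identities
        fixture = simulate_metadata(GeneratorConfig(), seed=77)
        backend = MatrixIdentityBackend(fixture.identity)
        before, after = date_split(fixture.records, fixture.cutoff_date)
        after_d, _ = dedup_identical(after)
        test = quality_filter(after_d)
        test = cross_set_identity_filter(test, before, [backend])
        for t in test:
            for b in before:
                assert backend.identity(t, b) <= 25.0

    def test_each_filter_rejects_something(self):
        fixture = simulate_metadata(GeneratorConfig(), seed=424)
        before, after = date_split(fixture.records, fixture.cutoff_date)
        assert before and after
        after_d, _ = dedup_identical(after)
        assert len(after_d) < len(after)
        q = quality_filter(after_d)
        assert len(q) < len(after_d)
        backend = MatrixIdentityBackend(fixture.identity)
        x = cross_set_identity_filter(q, before, [backend])
        assert len(x) < len(q)
        i = intra_set_identity_reduce(x, [backend])
        assert len(i) < len(x)

    def test_ecod_fixture_exercises_cascade(self):
        fixture = simulate_metadata(GeneratorConfig(), seed=424)
        table = ECODTable.from_text(fixture.ecod_text)
        statuses = set()
        for r in fixture.records:
            if r.pdb_id.startswith("c"):
                _, status = ecod_lookup(r, table, fixture.same_sequence_index)
                statuses.add(status)
        assert statuses >= {"direct", "same_pdb", "other_pdb", "unresolved"}
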