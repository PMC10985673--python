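import numpy as np
import pytest

from lshtax.lsh import (
    HashSpec,
    LshIndex,
    LshParams,
    expected_matches,
    rho,
    round_half_up,
    suggest_params,
)
from lshtax.seqcodec import decode_kmer, encode_kmer, EncodedKmer, hamming_distance
from tests.conftest import random_kmer_string


@pytest.fixture
def small_index():
    params = LshParams(h=8)
    return LshIndex(params, HashSpec.generate(params, seed=7), seed=7)


class TestParams:
    def test_dmax_default_round_half_up(self):
        assert LshParams(p=3).d_max == round_half_up(4.5) == 5
        assert LshParams(p=2).d_max == 3

    def test_invalid(self):
        with pytest.raises(ValueError):
            LshParams(h=32)
        with pytest.raises(ValueError):
            LshParams(p=6, d_max=5)

    def test_hash_spec_reproducible(self):
        p = LshParams(h=8)
        assert HashSpec.generate(p, 3) == HashSpec.generate(p, 3)
        assert HashSpec.generate(p, 3) != HashSpec.generate(p, 4)


class TestTableHash:
    def test_all_a_row_zero(self, small_index):
        x = encode_kmer("A" * 32)
        for t in range(small_index.params.l):
            assert small_index.table_hash(x, t) == 0

    def test_off_sample_positions_ignored(self, small_index, rng):
        positions = set(small_index.spec.positions[0])
        s = list(random_kmer_string(rng))
        s2 = list(s)
        for i in range(32):
            if i not in positions:
                s2[i] = "ACGT"[("ACGT".index(s2[i]) + 1) % 4]
        assert small_index.table_hash(encode_kmer("".join(s)), 0) == small_index.table_hash(
            encode_kmer("".join(s2)), 0
        )

    def test_string_extraction_oracle_200(self, small_index, rng):
        for _ in range(200):
            s = random_kmer_string(rng)
            x = encode_kmer(s)
            for t in range(small_index.params.l):
                pos = small_index.spec.positions[t]
                extracted = "".join(s[p] for p in pos)
                oracle = encode_kmer(extracted, len(pos)).value
                assert small_index.table_hash(x, t) == oracle


class TestRho:
    def test_identical_always_collide(self):
        assert rho(0, LshParams()) == 1.0

    def test_max_distance_never(self):
        assert rho(32, LshParams()) == 0.0

    def test_paper_defaults_150bp(self):
        assert round(expected_matches(150, 0.25, LshParams()), 1) == 3.2

    def test_single_table(self):
        assert round(expected_matches(150, 0.25, LshParams(l=1)), 1) == 1.6

    def test_degenerate_read(self):
        assert expected_matches(32, 0.0, LshParams()) == 1.0

    def test_monotone_decreasing(self):
        p = LshParams()
        vals = [rho(d, p) for d in range(33)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestInsert:
    def test_insert_then_lookup(self, small_index, rng):
        x = encode_kmer(random_kmer_string(rng))
        assert small_index.insert(x)
        m = small_index.lookup(x)
        assert m is not None and m.distance == 0

    def test_duplicate_not_appended(self, small_index, rng):
        x = encode_kmer(random_kmer_string(rng))
        assert small_index.insert(x)
        assert not small_index.insert(x)
        assert len(small_index) == 1

    def test_reservoir_retention_frequency(self, rng):
        # 10b k-mers into one row of a single-table index: each should
        # survive with probability b/(10b) = 0.1
        params = LshParams(h=8, l=1, b=7)
        spec = HashSpec.generate(params, seed=5)
        positions = set(spec.positions[0])
        base = random_kmer_string(np.random.default_rng(0))
        values = []
        free = [i for i in range(32) if i not in positions]
        for j in range(10 * params.b):
            s = list(base)
            for bit, i in enumerate(free):  # vary only off-sample positions
                s[i] = "ACGT"[(j >> (2 * bit)) & 3] if bit < 16 else s[i]
            values.append(encode_kmer("".join(s)))
        assert len({v.value for v in values}) == 70
        trials, hits = 1000, 0
        for t in range(trials):
            idx = LshIndex(params, spec, seed=t)
            for v in values:
                idx.insert(v)
            row = idx.table_hash(values[0], 0)
            hits += 0 in idx.tables[0][row]
        p_hat = hits / trials
        se = (0.1 * 0.9 / trials) ** 0.5
        assert abs(p_hat - 0.1) <= 3 * se

    def test_bulk_insert_equivalent_content(self, rng):
        params = LshParams(h=8)
        vals = np.unique(rng.integers(0, 2**63, size=500, dtype=np.uint64))
        idx = LshIndex(params, HashSpec.generate(params, 1), seed=1)
        idx.bulk_insert(vals)
        assert len(idx) == vals.size
        assert np.array_equal(np.sort(idx.kmer_values), vals)
        # with no row overflow every value must be findable at distance 0
        d, _, _ = idx.lookup_batch(vals)
        assert (d == 0).all()

    def test_bulk_insert_requires_empty(self, small_index, rng):
        small_index.insert(encode_kmer(random_kmer_string(rng)))
        with pytest.raises(ValueError):
            small_index.bulk_insert(np.array([1], dtype=np.uint64))


class TestLookup:
    def test_no_shared_row_no_match(self, small_index):
        small_index.insert(encode_kmer("A" * 32))
        assert small_index.lookup(encode_kmer("T" * 32)) is None

    def test_no_false_positive_distance(self, rng):
        params = LshParams(h=8)
        idx = LshIndex(params, HashSpec.generate(params, 3), seed=3)
        stored = [random_kmer_string(rng) for _ in range(256)]
        idx.bulk_insert(np.array([encode_kmer(s).value for s in stored], dtype=np.uint64))
        kv = idx.kmer_values
        for _ in range(300):
            q = random_kmer_string(rng)
            m = idx.lookup(encode_kmer(q))
            if m is not None:
                oracle = sum(
                    a != b for a, b in zip(q, decode_kmer(EncodedKmer(int(kv[m.ref_index]))))
                )
                assert m.distance == oracle <= params.d_max

    def test_tie_break_smallest_ref_index(self, rng):
        # two stored k-mers at equal distance 1 from the query
        params = LshParams(h=6, b=16)
        idx = LshIndex(params, HashSpec.generate(params, 11), seed=11)
        q = random_kmer_string(rng)
        a, b = list(q), list(q)
        a[0] = "ACGT"[("ACGT".index(a[0]) + 1) % 4]
        b[31] = "ACGT"[("ACGT".index(b[31]) + 1) % 4]
        idx.insert(encode_kmer("".join(a)))
        idx.insert(encode_kmer("".join(b)))
        m = idx.lookup(encode_kmer(q))
        assert m is not None and m.distance == 1 and m.ref_index == 0

    def test_recall_tracks_rho(self, rng):
        # reduced version of the acceptance check: neighbors planted with
        # i.i.d. per-base mismatch probability d/k (the analytic model
        # behind rho) are recovered at rate rho(d) within Monte-Carlo
        # error. Disjoint table position sets make the formula exact.
        params = LshParams(h=10, b=16, p=3, d_max=32)
        perm = rng.permutation(32)
        spec = HashSpec(
            (tuple(int(x) for x in perm[:10]), tuple(int(x) for x in perm[10:20])), 0
        )
        idx = LshIndex(params, spec, seed=2)
        idx.bulk_insert(rng.integers(0, 2**63, size=2**10, dtype=np.uint64))
        kv = idx.kmer_values
        for d in (2, 5):
            trials = 800
            picked = rng.integers(len(idx), size=trials)
            queries = kv[picked].copy()
            hit = rng.random((trials, 32)) < d / 32
            for pos in range(32):
                m = hit[:, pos]
                shift = np.uint64(2 * pos)
                sym = (queries >> shift) & np.uint64(3)
                delta = rng.integers(1, 4, size=trials).astype(np.uint64)
                new = (sym + delta) % np.uint64(4)
                queries = np.where(
                    m, (queries & ~(np.uint64(3) << shift)) | (new << shift), queries
                )
            _, ref, _ = idx.lookup_batch(queries)
            found = ref == picked
            expect = rho(d, params)
            se = (expect * (1 - expect) / trials) ** 0.5
            assert abs(found.mean() - expect) <= 3 * se + 1e-9


class TestSuggestParams:
    def test_standard_library_size(self):
        assert suggest_params(2**33).h == 15

    def test_floor(self):
        assert suggest_params(1).h == 8

    def test_tight_budget_errors(self):
        with pytest.raises(ValueError):
            suggest_params(2**20, memory_budget=1000)

    def test_budget_caps_h(self):
        free = suggest_params(2**33)  # h=15, ~146 GB total
        capped = suggest_params(2**33, memory_budget=120 * 10**9)
        assert capped.h < free.h


class TestSerialization:
    def test_round_trip_bit_identical_lookups(self, rng, tmp_path):
        params = LshParams(h=8)
        idx = LshIndex(params, HashSpec.generate(params, 9), seed=9)
        idx.bulk_insert(rng.integers(0, 2**63, size=1000, dtype=np.uint64))
        idx.labels[: len(idx)] = rng.integers(0, 50, size=len(idx), dtype=np.uint16)
        idx.save(tmp_path / "lib")
        idx2 = LshIndex.load(tmp_path / "lib")
        queries = rng.integers(0, 2**63, size=2000, dtype=np.uint64)
        for tie in ("ref", "label"):
            a = idx.lookup_batch(queries, tie=tie)
            b = idx2.lookup_batch(queries, tie=tie)
            for x, y in zip(a, b):
                assert np.array_equal(x, y)

    def test_deterministic_construction(self, rng):
        params = LshParams(h=8)
        vals = rng.integers(0, 2**63, size=3000, dtype=np.uint64)
        idx1 = LshIndex(params, HashSpec.generate(params, 4), seed=4)
        idx2 = LshIndex(params, HashSpec.generate(params, 4), seed=4)
        idx1.bulk_insert(vals)
        idx2.bulk_insert(vals)
        assert np.array_equal(idx1.kmer_values, idx2.kmer_values)
        for t1, t2 in zip(idx1.tables, idx2.tables):
            assert np.array_equal(t1, t2)
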