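"""Dot-bracket parsing, stretch extraction, sensor sites, fold ensembles."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lariatfold.lariat_mapper import revcomp
from lariatfold.structure_stats import (
    DEFAULT_SENSOR_PANEL,
    DsRNAStretch,
    MaxPairFolder,
    ViennaFolder,
    can_pair,
    count_sensor_sites_for_regions,
    ensemble_deviation,
    extract_stretches,
    normalized_mfe,
    parse_dotbracket,
    sensor_sites,
)
from lariatfold.synthetic_data import random_sequence


def random_dotbracket(rng: random.Random, max_len: int = 60) -> str:
    """Random balanced nested structure (grammar S -> (S)S | .S | empty)."""

    def gen(budget: int) -> str:
        if budget <= 0 or rng.random() < 0.2:
            return ""
        if budget >= 2 and rng.random() < 0.45:
            inner = gen(budget - 2)
            rest = gen(budget - 2 - len(inner))
            return "(" + inner + ")" + rest
        return "." + gen(budget - 1)

    return gen(max_len)


def stretch_oracle(db: str) -> list[int]:
    """Stack-based independent stretch extraction working on the string."""
    stack, partner = [], {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            partner[j], partner[i] = i, j
    lengths = []
    run = 0
    for i in range(len(db)):
        if db[i] == "(" :
            if run and partner.get(i - 1) == partner[i] + 1:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


class TestParseDotbracket:
    def test_pairs_by_stack_matching(self):
        s = parse_dotbracket("((..))", "GGAACC")
        assert s.pairs == frozenset({(0, 5), (1, 4)})

    def test_unpaired(self):
        assert parse_dotbracket("......", "AAAAAA").pairs == frozenset()

    @pytest.mark.parametrize("db,seq", [("((.)", "ACGU"), ("())", "ACG"), ("(.)", "ACGU"), ("(x)", "ACG")])
    def test_malformed_rejected(self, db, seq):
        with pytest.raises(ValueError):
            parse_dotbracket(db, seq)

    def test_roundtrip(self):
        db = "((..((....)).))"
        s = parse_dotbracket(db, "A" * len(db))
        from lariatfold.structure_stats import to_dotbracket

        assert to_dotbracket(s.pairs, len(db)) == db


class TestExtractStretches:
    def test_perfect_stem(self):
        s = parse_dotbracket("((((....))))", "GGGGAAAACCCC")
        st_ = extract_stretches(s)
        assert [x.length_bp for x in st_] == [4]
        assert (st_[0].five_prime_start, st_[0].three_prime_end) == (0, 11)

    def test_bulge_breaks_run(self):
        db = "((..((....))))"
        s = parse_dotbracket(db, "A" * len(db))
        assert s.pairs == frozenset({(0, 13), (1, 12), (4, 11), (5, 10)})
        assert [x.length_bp for x in extract_stretches(s)] == [2, 2]

    def test_unpaired_structure(self):
        assert extract_stretches(parse_dotbracket("....", "ACGU")) == []

    def test_pair_conservation_random_structures(self):
        rng = random.Random(99)
        for _ in range(300):
            db = random_dotbracket(rng)
            if not db:
                continue
            s = parse_dotbracket(db, "A" * len(db))
            st_ = extract_stretches(s)
            assert sum(2 * x.length_bp for x in st_) == db.count("(") + db.count(")")
            assert sorted(x.length_bp for x in st_) == sorted(stretch_oracle(db))


class TestSensorSites:
    @pytest.mark.parametrize(
        "lengths,sensor,thr,expected",
        [([33], "PKR", 33, 1), ([17, 16], "OAS1", 17, 1), ([70], "OAS1", 17, 4)],
    )
    def test_floor_sum(self, lengths, sensor, thr, expected):
        stretches = [DsRNAStretch(l, 0, 1) for l in lengths]
        assert sensor_sites(stretches, {sensor: thr})[sensor] == expected

    def test_default_panel_thresholds(self):
        stretches = [DsRNAStretch(34, 0, 1)]
        assert sensor_sites(stretches) == {"OAS1": 2, "RIG-I": 1, "PKR": 1}

    @given(st.integers(1, 120), st.integers(1, 120), st.integers(1, 40))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_merging_never_decreases_counts(self, a, b, thr):
        split = sensor_sites([DsRNAStretch(a, 0, 1), DsRNAStretch(b, 0, 1)], {"x": thr})
        merged = sensor_sites([DsRNAStretch(a + b, 0, 1)], {"x": thr})
        assert merged["x"] >= split["x"]

    def test_elongation_monotone(self):
        for L in range(1, 80):
            shorter = sensor_sites([DsRNAStretch(L, 0, 1)])
            longer = sensor_sites([DsRNAStretch(L + 1, 0, 1)])
            assert all(longer[s] >= shorter[s] for s in shorter)


class TestNormalizedMfe:
    @pytest.mark.parametrize("mfe,length,expected", [(-50, 100, -0.5), (0, 10, 0.0), (-3, 3, -1.0)])
    def test_values(self, mfe, length, expected):
        assert normalized_mfe(mfe, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalized_mfe(-1.0, 0)


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive maximum over all nested pairings (oracle for tiny n)."""

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        # j unpaired, or j paired with some k
        result = best(i, j - 1)
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                result = max(result, 1 + best(i, k - 1) + best(k + 1, j - 1))
        return result

    return best(0, len(seq) - 1)


class TestMaxPairFolder:
    def test_agrees_with_exhaustive_enumeration_small(self, folder):
        rng = random.Random(5)
        cases = ["GGGGAAAACCCC", "ACGUACGUACGU", "GCGCGCGC", "AAAAAAA", "GUGUGUGUGUGU"]
        cases += [random_sequence(rng.randint(5, 12), seed=1000 + i) for i in range(30)]
        for seq in cases:
            res = folder(seq)
            assert len(res.structure.pairs) == enumerate_max_pairs(seq.replace("T", "U"))

    def test_energy_is_pair_count(self, folder):
        res = folder("GGGGAAAACCCC")
        assert res.mfe == -4.0
        assert res.normalized_mfe == pytest.approx(-4.0 / 12)

    def test_structure_respects_min_loop_and_pairing(self, folder):
        res = folder(random_sequence(40, seed=8))
        seq = res.structure.sequence
        for i, j in res.structure.pairs:
            assert j - i > 3
            assert can_pair(seq[i], seq[j])

    def test_deterministic(self, folder):
        s = random_sequence(50, seed=2)
        assert folder(s).structure.dotbracket == folder(s).structure.dotbracket


class TestEnsembleDeviation:
    def test_homopolymer_deviation_exactly_zero(self, folder):
        d = ensemble_deviation("A" * 30, folder, n=5, seed=0)
        assert d.deviation == 0.0

    def test_inverted_repeat_folds_below_its_shuffles(self, folder):
        s = random_sequence(18, seed=31)
        construct = s + "AAAA" + revcomp(s).replace("T", "U")
        d = ensemble_deviation(construct, folder, n=10, seed=1)
        assert d.deviation < 0
        assert d.deviation == pytest.approx(d.observed_mfe - d.mean_shuffled_mfe, abs=1e-9)

    def test_invalid_n(self, folder):
        with pytest.raises(ValueError):
            ensemble_deviation("ACGU", folder, n=0)


class TestRegionSensorTable:
    def test_long_regions_skipped_and_reported(self, folder):
        seqs = {"short": "GGGGAAAACCCC", "long": "A" * 5001}
        rows, skipped = count_sensor_sites_for_regions(seqs, folder, max_length=5000)
        assert [r["region_id"] for r in rows] == ["short"]
        assert skipped == [{"region_id": "long", "length": 5001, "reason": "length > 5000"}]

    def test_perfect_hairpin_triggers_pkr(self, folder):
        seqs = {"hp": "G" * 34 + "AAAA" + "C" * 34}
        rows, _ = count_sensor_sites_for_regions(seqs, folder)
        assert rows[0]["PKR"] == 1
        assert rows[0]["n_stretches"] == 1

    def test_unstructured_region_zero_everywhere(self, folder):
        rows, _ = count_sensor_sites_for_regions({"flat": "A" * 60}, folder)
        assert all(rows[0][s] == 0 for s in DEFAULT_SENSOR_PANEL)


class TestViennaFolder:
    def test_production_predictor_wiring(self):
        f = ViennaFolder()
        res = f("GGGGAAAACCCC")
        assert res.structure.dotbracket == "((((....))))"
        assert res.mfe < 0
        assert res.normalized_mfe == pytest.approx(res.mfe / 12)
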