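import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugcombo.enrichment import EnrichmentProfile
from drugcombo.features import (
    BASE_FEATURE_NAMES,
    build_matrix,
    build_pair_vector,
    chemical_feature,
    cross_group_features,
    feature_names,
    pathway_features,
    read_matrix,
    split_matrix,
    within_group_features,
    write_matrix,
)
from drugcombo.interactions import CombinationLabelSet, DrugRecord, ScoreTable

from .conftest import make_table


# ---------------------------------------------------------------------------
# Independent brute-force enumerator (the oracle). Deliberately naive.


def brute_cross(t1, t2, ppi):
    scores = []
    for a in t1:
        for b in t2:
            if a != b:
                scores.append(ppi.score(a, b))
    if not scores:
        return 0.0, 0.0
    return max(scores), sum(scores) / len(scores)


def brute_within_one(t, ppi):
    scores = [ppi.score(a, b) for a, b in itertools.combinations(sorted(t), 2)]
    if not scores:
        return 0.0, 0.0
    return max(scores), sum(scores) / len(scores)


def brute_vector(d1, d2, drugs, chem, ppi, profiles):
    t1, t2 = drugs[d1].targets, drugs[d2].targets
    cmax, cmean = brute_cross(t1, t2, ppi)
    v1_max, v1_mean = brute_within_one(t1, ppi)
    v2_max, v2_mean = brute_within_one(t2, ppi)
    e1, e2 = profiles[d1].scores, profiles[d2].scores
    return np.array(
        [
            chem.score(d1, d2),
            cmax,
            cmean,
            v1_max + v2_max,
            v1_mean + v2_mean,
            abs(v1_max - v2_max),
            abs(v1_mean - v2_mean),
            *(e1 + e2),
            *np.abs(e1 - e2),
        ]
    )


def random_instance(rng, n_pathways=6):
    """Random tiny two-drug instance: <=5 targets each, <=6 pathways."""
    proteins = [f"P{i}" for i in range(10)]
    t1 = frozenset(rng.choice(proteins, size=rng.integers(1, 6), replace=False))
    t2 = frozenset(rng.choice(proteins, size=rng.integers(1, 6), replace=False))
    drugs = {"d1": DrugRecord("d1", t1), "d2": DrugRecord("d2", t2)}
    ppi = ScoreTable("protein")
    for a, b in itertools.combinations(proteins, 2):
        if rng.random() < 0.4:
            ppi.add(a, b, int(rng.integers(1, 1000)))
    chem = ScoreTable("chemical")
    if rng.random() < 0.7:
        chem.add("d1", "d2", int(rng.integers(1, 1000)))
    pids = tuple(f"pw{j}" for j in range(n_pathways))
    profiles = {
        d: EnrichmentProfile(d, pids, rng.random(n_pathways) * 5) for d in drugs
    }
    return drugs, chem, ppi, profiles


# ---------------------------------------------------------------------------


class TestChemicalFeature:
    def test_direct_lookup(self):
        chem = make_table("chemical", {("d1", "d2"): 800})
        assert chemical_feature("d1", "d2", chem) == 800

    def test_absent_pair_zero(self):
        assert chemical_feature("d1", "d3", ScoreTable("chemical")) == 0

    def test_symmetry(self):
        chem = make_table("chemical", {("d1", "d2"): 800})
        assert chemical_feature("d2", "d1", chem) == chemical_feature("d1", "d2", chem)


class TestCrossGroup:
    def test_single_pair(self):
        ppi = make_table("protein", {("A", "B"): 900})
        assert cross_group_features(frozenset("A"), frozenset("B"), ppi) == (900, 900)

    def test_mean_over_all_cross_pairs(self):
        ppi = make_table("protein", {("A", "B"): 600})
        got = cross_group_features(frozenset({"A"}), frozenset({"B", "C"}), ppi)
        assert got == brute_cross({"A"}, {"B", "C"}, ppi) == (600, 300)

    def test_no_interactions(self):
        got = cross_group_features(
            frozenset({"A"}), frozenset({"B"}), ScoreTable("protein")
        )
        assert got == (0, 0)

    def test_shared_target_excluded_from_divisor(self):
        # pairs (A,B) and (B,B): the identical-protein pair is skipped
        ppi = make_table("protein", {("A", "B"): 400})
        got = cross_group_features(frozenset({"A", "B"}), frozenset({"B"}), ppi)
        assert got == (400, 400)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cross_group_features(frozenset(), frozenset({"A"}), ScoreTable("protein"))


class TestWithinGroup:
    def test_singleton_convention(self):
        ppi = make_table("protein", {("A", "B"): 400})
        got = within_group_features(frozenset({"A", "B"}), frozenset({"C"}), ppi)
        assert got == (400, 400, 400, 400)

    def test_both_singletons(self):
        got = within_group_features(
            frozenset({"A"}), frozenset({"B"}), ScoreTable("protein")
        )
        assert got == (0, 0, 0, 0)

    def test_swap_invariance(self):
        ppi = make_table("protein", {("A", "B"): 400, ("C", "D"): 100})
        t1, t2 = frozenset({"A", "B"}), frozenset({"C", "D", "E"})
        assert within_group_features(t1, t2, ppi) == within_group_features(t2, t1, ppi)


class TestPathwayFeatures:
    def p(self, drug, values):
        pids = tuple(f"pw{i}" for i in range(len(values)))
        return EnrichmentProfile(drug, pids, np.array(values, dtype=float))

    def test_direct_arithmetic(self):
        got = pathway_features(self.p("d1", [1, 2]), self.p("d2", [3, 0]))
        np.testing.assert_array_equal(got, [4, 2, 2, 2])

    def test_identical_profiles_zero_diffs(self):
        e = self.p("d1", [1.5, 2.5, 0.0])
        got = pathway_features(e, self.p("d2", [1.5, 2.5, 0.0]))
        np.testing.assert_array_equal(got[3:], [0, 0, 0])

    def test_length_458_for_229_pathways(self):
        rng = np.random.default_rng(0)
        e1 = self.p("d1", rng.random(229))
        e2 = self.p("d2", rng.random(229))
        assert len(pathway_features(e1, e2)) == 458

    def test_mismatched_order_rejected(self):
        e1 = EnrichmentProfile("d1", ("pwA", "pwB"), np.zeros(2))
        e2 = EnrichmentProfile("d2", ("pwB", "pwA"), np.zeros(2))
        with pytest.raises(ValueError, match="mismatched pathway order"):
            pathway_features(e1, e2)


class TestPairVector:
    def test_dimension_7_plus_2p(self):
        rng = np.random.default_rng(1)
        drugs, chem, ppi, profiles = random_instance(rng, n_pathways=6)
        vec = build_pair_vector("d1", "d2", drugs, chem, ppi, profiles)
        assert len(vec.values) == 7 + 2 * 6
        assert vec.names[:7] == BASE_FEATURE_NAMES

    def test_oracle_equivalence_200_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            drugs, chem, ppi, profiles = random_instance(rng)
            vec = build_pair_vector("d1", "d2", drugs, chem, ppi, profiles)
            expected = brute_vector("d1", "d2", drugs, chem, ppi, profiles)
            np.testing.assert_allclose(vec.values, expected, rtol=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        drugs, chem, ppi, profiles = random_instance(rng)
        a = build_pair_vector("d1", "d2", drugs, chem, ppi, profiles)
        b = build_pair_vector("d2", "d1", drugs, chem, ppi, profiles)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.pair == b.pair

    def test_non_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            drugs, chem, ppi, profiles = random_instance(rng)
            vec = build_pair_vector("d1", "d2", drugs, chem, ppi, profiles)
            assert np.all(vec.values >= 0)
            assert np.all(np.isfinite(vec.values))


class TestBuildMatrix:
    def make_inputs(self):
        rng = np.random.default_rng(5)
        proteins = [f"P{i}" for i in range(8)]
        drugs = {}
        for i in range(4):
            t = frozenset(rng.choice(proteins, size=2, replace=False))
            drugs[f"d{i}"] = DrugRecord(f"d{i}", t)
        ppi = make_table("protein", {("P0", "P1"): 500, ("P2", "P3"): 700})
        chem = make_table("chemical", {("d0", "d1"): 650})
        pids = ("pwA", "pwB")
        profiles = {
            d: EnrichmentProfile(d, pids, rng.random(2)) for d in drugs
        }
        labels = CombinationLabelSet(
            frozenset({("d0", "d1")}), frozenset({("d0", "d2"), ("d1", "d3")})
        )
        return labels, drugs, chem, ppi, profiles

    def test_row_order_and_labels(self):
        labels, drugs, chem, ppi, profiles = self.make_inputs()
        df = build_matrix(labels, drugs, chem, ppi, profiles)
        assert list(df["label"]) == [1, 0, 0]
        assert list(zip(df["drug1"], df["drug2"])) == [
            ("d0", "d1"), ("d0", "d2"), ("d1", "d3")
        ]
        assert df.shape[1] == 3 + 7 + 2 * 2

    def test_unresolvable_drug_names_pair(self):
        labels, drugs, chem, ppi, profiles = self.make_inputs()
        del drugs["d2"]
        with pytest.raises(KeyError, match="d2"):
            build_matrix(labels, drugs, chem, ppi, profiles)

    def test_matrix_roundtrip(self, tmp_path):
        labels, drugs, chem, ppi, profiles = self.make_inputs()
        df = build_matrix(labels, drugs, chem, ppi, profiles)
        path = tmp_path / "matrix.tsv"
        write_matrix(df, path)
        X1, y1, names1 = split_matrix(df)
        X2, y2, names2 = split_matrix(read_matrix(path))
        assert names1 == names2
        np.testing.assert_allclose(X1, X2, rtol=1e-9)
        np.testing.assert_array_equal(y1, y2)

    def test_feature_names_465_at_study_scale(self):
        names = feature_names([f"pw{i:03d}" for i in range(229)])
        assert len(names) == 465
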