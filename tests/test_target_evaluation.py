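import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pipetarget.target_evaluation import (
    LPAResult,
    _running_es,
    benchmark_auc,
    define_poc_targets,
    disease_tree,
    load_drug_table,
    lpa,
    pict,
    simulate_negatives,
)


def drug_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "drug", "phase", "indication"]) \
        .assign(approved=lambda d: d["phase"] == 4)


class TestPocTargets:
    def test_phase_one_only_excluded(self):
        rec = drug_frame([("g1", "d1", 1, "dz")])
        assert define_poc_targets(rec, "dz") == set()

    def test_indication_must_match(self):
        rec = drug_frame([("g1", "d1", 3, "dzA")])
        assert define_poc_targets(rec, "dzB") == set()

    def test_distinct_gene_count(self):
        rec = drug_frame([("g1", "d1", 2, "dz"), ("g1", "d2", 3, "dz"),
                          ("g2", "d3", 4, "dz"), ("g3", "d4", 2, "dz"),
                          ("g3", "d5", 2, "dz")])
        assert define_poc_targets(rec, "dz") == {"g1", "g2", "g3"}


class TestSimulateNegatives:
    def _records(self):
        return drug_frame([("t1", "d", 3, "dz"), ("t2", "d", 1, "dz"),
                           ("n1", "d", 2, "other"), ("n2", "d", 1, "other"),
                           ("n3", "d", 4, "other")])

    def test_neighbors_of_disease_genes_excluded(self):
        g = nx.Graph([("t1", "n1")])
        neg = simulate_negatives(self._records(), "dz", [g])
        assert "n1" not in neg and neg == {"n2", "n3"}

    def test_genes_without_any_record_never_negative(self):
        g = nx.Graph([("x", "y")])
        neg = simulate_negatives(self._records(), "dz", [g])
        assert "x" not in neg and "y" not in neg

    def test_disjointness_identity(self):
        g = nx.Graph([("t1", "n1"), ("t2", "n2")])
        rec = self._records()
        neg = simulate_negatives(rec, "dz", [g])
        disease = {"t1", "t2"}
        neighbors = {"n1", "n2"}
        assert neg & (disease | neighbors) == set()

    def test_any_phase_excludes_from_negatives(self):
        # t2 has only a phase-1 record for the disease, still excluded
        neg = simulate_negatives(self._records(), "dz", [nx.Graph()])
        assert "t2" not in neg

    def test_seeded_subsample(self):
        rec = self._records()
        a = simulate_negatives(rec, "dz", [nx.Graph()], seed=4, n=2)
        b = simulate_negatives(rec, "dz", [nx.Graph()], seed=4, n=2)
        assert a == b and len(a) == 2

    def test_empty_pool_is_error(self):
        rec = drug_frame([("t1", "d", 3, "dz")])
        with pytest.raises(ValueError, match="empty"):
            simulate_negatives(rec, "dz", [nx.Graph()])


class TestBenchmarkAuc:
    def test_perfect_separation(self):
        cred = pd.Series({"p1": 5.0, "p2": 4.0, "n1": 1.0, "n2": 0.5})
        assert benchmark_auc(cred, {"p1", "p2"}, {"n1", "n2"}) == 1.0

    def test_all_tied_gives_half(self):
        cred = pd.Series({g: 1.0 for g in "abcd"})
        assert benchmark_auc(cred, {"a", "b"}, {"c", "d"}) == 0.5

    def test_three_of_four_concordant_pairs(self):
        cred = pd.Series({"p1": 3.0, "p2": 1.0, "n1": 2.0, "n2": 0.0})
        assert benchmark_auc(cred, {"p1", "p2"}, {"n1", "n2"}) == 0.75

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            genes = [f"g{i}" for i in range(16)]
            cred = pd.Series(rng.integers(0, 5, 16).astype(float), index=genes)
            pos, neg = set(genes[:6]), set(genes[6:])
            conc = sum((cred[p] > cred[n]) + 0.5 * (cred[p] == cred[n])
                       for p, n in itertools.product(pos, neg))
            assert benchmark_auc(cred, pos, neg) == pytest.approx(conc / (6 * 10))

    def test_overlap_rejected(self):
        cred = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="overlap"):
            benchmark_auc(cred, {"a"}, {"a", "b"})


class TestLpa:
    def test_top_m_set_has_full_coverage_and_peak_at_m(self):
        cred = pd.Series(np.linspace(10, 0, 50), index=[f"g{i:02d}" for i in range(50)])
        target = {f"g{i:02d}" for i in range(5)}
        r = lpa(cred, target, n_perm=500, seed=0)
        assert r.coverage == 1.0
        assert r.peak_index == 5
        assert r.leading_edge == target
        assert r.es > 0.9

    def test_two_gene_set_against_exhaustive_null(self):
        # 10 equal-credit genes ranked by id; the target occupies the
        # first two ranks, the unique configuration maximizing ES
        cred = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        target = {"g0", "g1"}
        r = lpa(cred, target, n_perm=4000, weight=1.0, seed=3)
        es_all = []
        for pos in itertools.combinations(range(10), 2):
            pos = np.array(pos)
            es, _ = _running_es(pos, np.ones(2), 10)
            es_all.append(es)
        es_all = np.array(es_all)
        assert r.es == pytest.approx(es_all.max())
        # the sampled p concentrates around (1 + N*f)/(1 + N), where f
        # is the exact null exceedance fraction from full enumeration
        frac = np.mean(es_all >= r.es - 1e-12)
        expected_p = (1 + 4000 * frac) / (1 + 4000)
        assert r.p == pytest.approx(expected_p, abs=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        cred = pd.Series(rng.uniform(0, 10, 60), index=[f"g{i}" for i in range(60)])
        target = set(cred.nlargest(8).index)
        a = lpa(cred, target, n_perm=300, seed=11)
        b = lpa(cred, target, n_perm=300, seed=11)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_members_outside_universe_dropped(self):
        cred = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        r = lpa(cred, {"a", "zzz"}, n_perm=100, seed=0)
        # coverage denominator keeps the full requested set
        assert r.coverage in (0.0, 0.5)


class TestPict:
    def _result(self, p, nes=2.0, coverage=0.5, n_perm=100):
        return LPAResult(es=0.5, nes=nes, p=p, coverage=coverage,
                         leading_edge=set(), peak_index=1, n_perm=n_perm)

    def test_arithmetic(self):
        res = {"dz": self._result(p=0.01, nes=2.0, coverage=0.5)}
        (s,) = pict(res)
        assert s.fdr == 0.01  # single test: BH leaves p unchanged
        assert s.pict == pytest.approx(np.log10(2.0 * 0.5 / 0.01))

    def test_zero_coverage_missing(self):
        (s,) = pict({"dz": self._result(p=0.01, coverage=0.0)})
        assert s.pict is None

    def test_fdr_floor_at_permutation_resolution(self):
        (s,) = pict({"dz": self._result(p=1e-9, n_perm=100)})
        assert s.fdr == pytest.approx(0.01)

    def test_doubling_fdr_lowers_pict_by_log2(self):
        a = pict({"dz": self._result(p=0.01)})[0]
        b = pict({"dz": self._result(p=0.02)})[0]
        assert a.pict - b.pict == pytest.approx(np.log10(2))


class TestDiseaseTree:
    def test_three_diseases_keep_strongest_edges(self):
        members = {
            "A": {"g1", "g2", "g3", "g4"},
            "B": {"g1", "g2", "g3", "g9"},   # shares 3 with A
            "C": {"g1", "g2", "g8", "g7"},   # shares 2 with A, 2 with B
        }
        tree = disease_tree(members)
        assert tree.number_of_edges() == 2
        assert tree.has_edge("A", "B") and tree["A"]["B"]["shared"] == 3
        # C attaches through one of its weight-2 edges
        assert tree.degree("C") == 1

    def test_two_diseases_single_edge_iff_sharing(self):
        assert disease_tree({"A": {"g"}, "B": {"g"}}).number_of_edges() == 1
        assert disease_tree({"A": {"g"}, "B": {"h"}}).number_of_edges() == 0

    def test_tree_property_on_random_cases(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = int(rng.integers(3, 6))
            members = {f"D{i}": set(rng.choice(20, size=6).tolist())
                       for i in range(d)}
            tree = disease_tree(members)
            assert tree.number_of_edges() <= d - 1
            assert nx.is_forest(tree)

    def test_isolated_disease_retained(self):
        tree = disease_tree({"A": {"g1"}, "B": {"g1"}, "C": {"zz"}})
        assert "C" in tree.nodes and tree.degree("C") == 0


def test_load_drug_table_round_trip(tmp_path, bundle):
    df = load_drug_table(bundle["files"]["drugs"])
    assert (df["approved"] == (df["phase"] == 4)).all()

    bad = tmp_path / "bad.tsv"
    df2 = df.copy()
    df2.loc[df2.index[0], "approved"] = not df2.loc[df2.index[0], "approved"]
    df2.to_csv(bad, sep="\t", index=False)
    with pytest.raises(ValueError, match="inconsistent"):
        load_drug_table(bad)
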