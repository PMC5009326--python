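"""Rank-signature classifier: filtering, ES distance, CV, GA, biomarker."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsig.signature import (
    ClassifierParams,
    ExpressionDataset,
    GASettings,
    _es_from_positions,
    _position_scores,
    build_signature,
    classify,
    cross_validate,
    distance_matrix,
    enrichment_score,
    extract_biomarker,
    fit_signatures,
    ga_optimize,
    permutation_test,
    rank_sample,
    signature_distance,
    wilcoxon_filter,
)
from netsig.synthetic import ExprSimConfig, simulate_expression


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_es(hit_set, ranking, weight_exponent=1.0):
    """Literal running-sum enrichment score, position by position."""
    n = len(ranking)
    hits = set(hit_set)
    k = len(hits)
    if k == n:
        return 1.0
    if n == 1:
        w_all = [1.0]
    else:
        w_all = [abs(1 - 2 * i / (n - 1)) ** weight_exponent for i in range(n)]
    hit_w = [w_all[i] if p in hits else 0.0 for i, p in enumerate(ranking)]
    total = sum(hit_w)
    if total == 0:
        hit_w = [1.0 if p in hits else 0.0 for p in ranking]
        total = float(k)
    running = 0.0
    max_pos, min_neg = 0.0, 0.0
    for i, p in enumerate(ranking):
        if p in hits:
            running += hit_w[i] / total
        else:
            running -= 1.0 / (n - k)
        max_pos = max(max_pos, running)
        min_neg = min(min_neg, running)
    # magnitude ties resolve to the positive side
    return max_pos if max_pos >= -min_neg - 1e-12 else min_neg


def exact_ranksum_pvalue(x, y):
    """Two-sided rank-sum p by enumerating all C(n+m, n) assignments."""
    pooled = sorted(x + y)
    ranks = {}
    # midranks for ties
    vals = {}
    for i, v in enumerate(pooled, start=1):
        vals.setdefault(v, []).append(i)
    for v, idx in vals.items():
        ranks[v] = sum(idx) / len(idx)
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats = []
    all_ranks = [ranks[v] for v in pooled]
    for combo in itertools.combinations(range(len(pooled)), n):
        stats.append(sum(all_ranks[i] for i in combo))
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)


# ---------------------------------------------------------------------------
# Wilcoxon filter
# ---------------------------------------------------------------------------

class TestWilcoxonFilter:
    def test_complete_separation_matches_exact_enumeration(self):
        """4v4 fully separated values give the enumerated p = 2/70."""
        x = np.vstack([[1, 2, 3, 4, 5, 6, 7, 8]] * 2).astype(float)
        ds = ExpressionDataset(
            abundance=x,
            probe_ids=["pA", "pB"],
            sample_ids=[f"s{i}" for i in range(8)],
            group_labels=["G1"] * 4 + ["G2"] * 4,
            probe_to_gene={"pA": "gA", "pB": "gB"},
        )
        _, pmap = wilcoxon_filter(ds, alpha_filter=0.05)
        oracle = exact_ranksum_pvalue([1, 2, 3, 4], [5, 6, 7, 8])
        assert oracle == pytest.approx(2 / 70)
        assert pmap["pA"] == pytest.approx(oracle, abs=1e-12)

    def test_identical_groups_give_p_one_nothing_retained(self):
        x = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (3, 1))
        ds = ExpressionDataset(
            abundance=x,
            probe_ids=["p1", "p2", "p3"],
            sample_ids=[f"s{i}" for i in range(6)],
            group_labels=["A"] * 3 + ["B"] * 3,
            probe_to_gene={f"p{i}": "g" for i in (1, 2, 3)},
        )
        retained, pmap = wilcoxon_filter(ds, alpha_filter=0.05)
        assert retained == []
        assert all(p == 1.0 for p in pmap.values())

    def test_alpha_one_retains_everything(self, small_dataset):
        retained, _ = wilcoxon_filter(small_dataset, alpha_filter=1.0)
        assert retained == sorted(small_dataset.probe_ids)

    def test_single_sample_group_rejected(self, small_dataset):
        ds = small_dataset.subset_samples([0, 10, 11, 12])
        with pytest.raises(ValueError, match="at least 2"):
            wilcoxon_filter(ds, 0.05)


# ---------------------------------------------------------------------------
# Ranking and signatures
# ---------------------------------------------------------------------------

class TestRanking:
    def test_strictly_decreasing_values_keep_probe_order(self, tiny_dataset):
        assert rank_sample(tiny_dataset, tiny_dataset.probe_ids, "a") == [
            "p0", "p1", "p2", "p3", "p4",
        ]

    def test_all_equal_sample_falls_back_to_probe_id_order(self):
        ds = ExpressionDataset(
            abundance=np.ones((4, 4)),
            probe_ids=["z", "a", "m", "b"],
            sample_ids=list("wxyz"),
            group_labels=["A", "A", "B", "B"],
            probe_to_gene={p: p for p in "zamb"},
        )
        assert rank_sample(ds, ds.probe_ids, "w") == ["a", "b", "m", "z"]

    def test_input_probe_order_is_irrelevant(self, tiny_dataset):
        rng = np.random.default_rng(0)
        base = rank_sample(tiny_dataset, tiny_dataset.probe_ids, "b")
        for _ in range(20):
            perm = list(rng.permutation(tiny_dataset.probe_ids))
            assert rank_sample(tiny_dataset, perm, "b") == base

    @pytest.mark.parametrize(
        "n1,n2,top,bottom",
        [
            (2, 2, ("a", "b"), ("e", "f")),
            (3, 3, ("a", "b", "c"), ("d", "e", "f")),
            (1, 1, ("a",), ("f",)),
        ],
    )
    def test_signature_takes_first_n1_and_last_n2(self, n1, n2, top, bottom):
        sig = build_signature(list("abcdef"), n1, n2)
        assert sig.top == top and sig.bottom == bottom

    def test_signature_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_signature(["a", "b"], 2, 1)


# ---------------------------------------------------------------------------
# Enrichment score and distance
# ---------------------------------------------------------------------------

class TestEnrichmentScore:
    @given(
        n=st.integers(3, 20),
        k=st.integers(1, 6),
        q=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_running_sum(self, n, k, q, data):
        """Fast path equals the literal running sum on universes <= 20."""
        k = min(k, n - 1)
        ranking = [f"p{i}" for i in range(n)]
        hit_idx = data.draw(
            st.lists(st.integers(0, n - 1), min_size=k, max_size=k, unique=True)
        )
        hits = [ranking[i] for i in hit_idx]
        oracle = brute_force_es(hits, ranking, q)
        assert enrichment_score(hits, ranking, q) == pytest.approx(oracle, abs=1e-12)
        w = np.abs(_position_scores(n)) ** q
        fast = _es_from_positions(np.sort(np.array(hit_idx)), n, w)
        assert fast == pytest.approx(oracle, abs=1e-12)

    def test_set_at_top_scores_plus_one(self):
        ranking = [f"p{i}" for i in range(10)]
        assert enrichment_score(ranking[:3], ranking) == pytest.approx(1.0)

    def test_set_at_bottom_scores_minus_one(self):
        ranking = [f"p{i}" for i in range(10)]
        assert enrichment_score(ranking[-3:], ranking) == pytest.approx(-1.0)


class TestSignatureDistance:
    def _sigs(self, ranking_a, ranking_b, n1=2, n2=2):
        sa = build_signature(ranking_a, n1, n2)
        sb = build_signature(ranking_b, n1, n2)
        return sa, sb

    def test_identical_samples_have_zero_distance(self):
        r = [f"p{i}" for i in range(10)]
        sa, sb = self._sigs(r, r)
        assert signature_distance(sa, sb, r, r) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_anticorrelated_samples_have_distance_one(self):
        r = [f"p{i}" for i in range(10)]
        rev = r[::-1]
        sa, sb = self._sigs(r, rev)
        assert signature_distance(sa, sb, r, rev) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_over_random_pairs(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(12)]
        for _ in range(50):
            ra = list(rng.permutation(probes))
            rb = list(rng.permutation(probes))
            sa, sb = self._sigs(ra, rb, 3, 3)
            d1 = signature_distance(sa, sb, ra, rb)
            d2 = signature_distance(sb, sa, rb, ra)
            assert d1 == pytest.approx(d2, abs=1e-12)
            assert 0.0 <= d1 <= 1.0

    def test_mismatched_universes_rejected(self):
        ra = ["a", "b", "c", "d"]
        rb = ["a", "b", "c", "e"]
        sa, sb = self._sigs(ra, rb, 1, 1)
        with pytest.raises(ValueError, match="universe"):
            signature_distance(sa, sb, ra, rb)

    def test_distance_matrix_is_symmetric_zero_diagonal_unit_range(
        self, small_dataset, default_params
    ):
        sigs, _, retained = fit_signatures(small_dataset, default_params)
        from netsig.signature import rank_all_samples

        rankings = rank_all_samples(small_dataset, retained)
        dmat = distance_matrix(rankings, {s.sample_id: s for s in sigs})
        arr = dmat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert arr.min() >= 0.0 and arr.max() <= 1.0


# ---------------------------------------------------------------------------
# Classification, CV, permutation test
# ---------------------------------------------------------------------------

class TestClassify:
    def test_assigns_nearest_group(self):
        dist = {"t1": 0.0, "t2": 0.9, "t3": 0.8}
        labels = {"t1": "X", "t2": "Y", "t3": "Y"}
        label, tie = classify(dist, labels)
        assert label == "X" and not tie

    def test_tie_goes_to_lexicographically_smaller_label_with_flag(self):
        dist = {"t1": 0.5, "t2": 0.5}
        labels = {"t1": "B", "t2": "A"}
        label, tie = classify(dist, labels)
        assert label == "A" and tie

    def test_separable_training_data_self_classifies_perfectly(self):
        """Each training sample is nearest its own group on separable data."""
        from netsig.signature import distance_matrix, rank_all_samples

        for seed in range(5):
            cfg = ExprSimConfig(
                n_probes=300, n_samples_per_group=(8, 8), n_informative=40,
                effect_size=3.0, seed=seed,
            )
            ds = simulate_expression(cfg)
            sigs, _, retained = fit_signatures(
                ds, ClassifierParams(n1=10, n2=10, alpha_filter=0.01)
            )
            rankings = rank_all_samples(ds, retained)
            dmat = distance_matrix(rankings, {s.sample_id: s for s in sigs})
            labels = dict(zip(ds.sample_ids, ds.group_labels))
            for sid in ds.sample_ids:
                dist = {t: float(dmat.loc[sid, t]) for t in ds.sample_ids}
                pred, _ = classify(dist, labels)
                assert pred == labels[sid]


class TestCrossValidate:
    def test_folds_partition_samples_exactly_once(self, small_dataset, default_params):
        report = cross_validate(small_dataset, default_params, n_folds=5, seed=0)
        assert len(report.fold_assignments) == len(small_dataset.sample_ids)
        assert set(report.fold_assignments) == set(range(5))

    def test_separable_data_reaches_high_accuracy(self, small_dataset, default_params):
        report = cross_validate(small_dataset, default_params, n_folds=5, seed=0)
        assert report.accuracy >= 0.9

    def test_label_permutation_gives_chance_accuracy(self, small_dataset):
        """No leakage: with permuted labels accuracy sits at the majority rate."""
        rng = np.random.default_rng(11)
        params = ClassifierParams(n1=5, n2=5, alpha_filter=0.5)
        accs = []
        for _ in range(20):
            perm = list(rng.permutation(small_dataset.group_labels))
            ds = ExpressionDataset(
                small_dataset.abundance, small_dataset.probe_ids,
                small_dataset.sample_ids, perm, small_dataset.probe_to_gene,
            )
            accs.append(cross_validate(ds, params, n_folds=4, seed=1).accuracy)
        majority = 0.5  # balanced 10v10
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - majority) < 3 * max(se, 0.02)

    def test_small_group_reduces_fold_count(self, small_dataset, default_params, caplog):
        report = cross_validate(small_dataset, default_params, n_folds=50, seed=0)
        assert report.n_folds == 10

    def test_monotone_in_effect_size(self):
        """Mean CV accuracy never decreases as the planted effect grows."""
        means = []
        for effect in (0.0, 1.0, 3.0):
            accs = []
            for seed in range(10):
                cfg = ExprSimConfig(
                    n_probes=120, n_samples_per_group=(10, 8), n_informative=20,
                    effect_size=effect, seed=seed,
                )
                ds = simulate_expression(cfg)
                params = ClassifierParams(n1=5, n2=5, alpha_filter=0.1)
                accs.append(cross_validate(ds, params, n_folds=4, seed=seed).accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05 <= means[2] + 0.10
        assert means[2] >= means[0]


class TestPermutationTest:
    def test_p_bounded_and_minimal_when_observed_dominates(self, small_dataset, default_params):
        p, obs, perms = permutation_test(
            small_dataset, default_params, n_perm=19, seed=0
        )
        assert 0 < p <= 1
        if obs > perms.max():
            assert p == pytest.approx(1 / 20)

    def test_probe_label_mode_runs_and_destroys_signal(self, small_dataset, default_params):
        p, obs, perms = permutation_test(
            small_dataset, default_params, n_perm=19, seed=0, unit="probes"
        )
        assert obs > np.mean(perms)

    def test_unknown_unit_rejected(self, small_dataset, default_params):
        with pytest.raises(ValueError, match="unit"):
            permutation_test(small_dataset, default_params, n_perm=5, unit="genes")


# ---------------------------------------------------------------------------
# GA optimization
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ga_dataset():
    cfg = ExprSimConfig(
        n_probes=60, n_samples_per_group=(9, 9), n_informative=12,
        effect_size=2.0, seed=5,
    )
    return simulate_expression(cfg)


class TestGAOptimize:

    def test_single_point_space_returns_that_point(self, ga_dataset):
        params, report, log = ga_optimize(
            ga_dataset, [4], [4], [0.1],
            settings=GASettings(population=4, generations=2),
            n_folds=3, seed=0,
        )
        assert (params.n1, params.n2, params.alpha_filter) == (4, 4, 0.1)

    def test_ga_matches_exhaustive_grid_search(self, ga_dataset):
        """On a 3x3x2 grid the GA finds the grid-search optimum."""
        n1s, n2s, alphas = [3, 5, 8], [3, 5, 8], [0.05, 0.5]
        import itertools as it

        from netsig.signature import ClassifierParams as CP
        from netsig.signature import cross_validate as cv
        from netsig.signature import wilcoxon_filter as wf

        for seed in range(3):
            best_oracle = -np.inf
            for n1, n2, a in it.product(n1s, n2s, alphas):
                retained, _ = wf(ga_dataset, a)
                P = max(len(retained), n1 + n2)
                rep = cv(ga_dataset, CP(n1=n1, n2=n2, alpha_filter=a, seed=seed),
                         n_folds=3, seed=seed)
                best_oracle = max(best_oracle, rep.accuracy - 0.01 * (n1 + n2) / P)
            _, _, log = ga_optimize(
                ga_dataset, n1s, n2s, alphas,
                settings=GASettings(population=10, generations=8, mutation_prob=0.3),
                n_folds=3, seed=seed,
            )
            assert log[-1]["best_fitness"] == pytest.approx(best_oracle, abs=1e-12)

    def test_fixed_seed_reproduces_trajectory(self, ga_dataset):
        out1 = ga_optimize(
            ga_dataset, [3, 5], [3, 5], [0.1],
            settings=GASettings(population=6, generations=3), n_folds=3, seed=9,
        )
        out2 = ga_optimize(
            ga_dataset, [3, 5], [3, 5], [0.1],
            settings=GASettings(population=6, generations=3), n_folds=3, seed=9,
        )
        assert out1[0] == out2[0]
        assert out1[2] == out2[2]

    def test_empty_space_rejected(self, ga_dataset):
        with pytest.raises(ValueError, match="empty"):
            ga_optimize(ga_dataset, [], [3], [0.1])


# ---------------------------------------------------------------------------
# Biomarker extraction
# ---------------------------------------------------------------------------

class TestBiomarker:
    def test_shared_signature_yields_its_probes(self):
        from netsig.signature import SampleSignature

        sigs = [
            SampleSignature(sample_id=s, top=("a", "b"), bottom=("c", "d"))
            for s in ("s1", "s2", "s3")
        ]
        bm = extract_biomarker(sigs, {p: "g1" for p in "abcd"}, {p: 0.01 for p in "abcd"})
        assert bm.probe_ids == {"a", "b", "c", "d"}
        assert bm.gene_symbols == {"g1"}

    def test_disjoint_signatures_union(self):
        from netsig.signature import SampleSignature

        sigs = [
            SampleSignature(sample_id="s1", top=("a", "b"), bottom=("c", "d")),
            SampleSignature(sample_id="s2", top=("e", "f"), bottom=("g", "h")),
        ]
        bm = extract_biomarker(
            sigs, {p: p.upper() for p in "abcdefgh"}, {p: 0.5 for p in "abcdefgh"}
        )
        assert len(bm.probe_ids) == 8
        assert len(bm.gene_symbols) == 8
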