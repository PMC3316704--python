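"""Tests for the nested model series, tie handling and model designation."""

import numpy as np
import pytest

from revs import (
    Dataset,
    SyntheticSpec,
    TieWidthError,
    aic_gaussian,
    build_nested_sequence,
    categorize_support,
    delta_aics,
    fit_subset,
    generate_synthetic,
    level_matrix,
    rank_by_inclusion,
    resolve_tie_alternatives,
    run_revs,
    select_best,
)
from revs.search import InclusionRanking

from conftest import oracle_best_subsets


def _staircase_ranking(p, names=None):
    """Fabricated tie-free ranking: variable j has count p - j."""
    return InclusionRanking(
        counts=np.arange(p, 0, -1),
        order=tuple(range(p)),
        tie_groups=tuple((i,) for i in range(p)),
        predictor_names=names or tuple(f"x{i + 1}" for i in range(p)),
    )


@pytest.fixture
def tied_data():
    """Seeded dataset with a near-duplicate column producing count ties,
    one of them split at the best-model boundary."""
    return generate_synthetic(
        SyntheticSpec(
            n=60, p=6, effects={0: 1.0, 2: 0.8}, rho=0.4, sigma=1.0,
            seed=33, duplicates=((0, 0.3),),
        )
    )


class TestDeltaAics:
    def test_published_four_model_comparison(self):
        # AIC column 156.00 / 157.40 / 160.71 / 184.74 gives exactly these
        # delta values
        deltas = delta_aics([156.00, 157.40, 160.71, 184.74])
        assert deltas == pytest.approx([0.0, 1.40, 4.71, 28.74])

    def test_all_equal_gives_all_zero(self):
        assert delta_aics([3.3, 3.3, 3.3]) == pytest.approx([0, 0, 0])

    def test_permutation_invariance_of_multiset(self):
        vals = [10.0, 12.5, 11.1, 30.0]
        d1 = sorted(delta_aics(vals))
        d2 = sorted(delta_aics(vals[::-1]))
        assert d1 == pytest.approx(d2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            delta_aics([])

    def test_nan_entries_ignored_for_minimum(self):
        deltas = delta_aics([float("nan"), 5.0, 7.0])
        assert np.isnan(deltas[0])
        assert deltas[1:] == pytest.approx([0.0, 2.0])


class TestCategorizeSupport:
    @pytest.mark.parametrize(
        "delta,label",
        [
            (0.0, "very strong"),
            (2.0, "very strong"),  # boundary inclusive
            (2.5, "strong"),
            (4.0, "strong"),
            (4.71, "considerably less"),
            (10.0, "considerably less"),
            (28.74, "essentially none"),  # the full-model delta regime
        ],
    )
    def test_bands(self, delta, label):
        assert categorize_support(delta).label == label

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            categorize_support(-0.1)

    def test_every_nonnegative_delta_has_a_category(self):
        for delta in np.linspace(0, 50, 501):
            categorize_support(float(delta))


class TestBuildNestedSequence:
    def test_single_predictor(self):
        data = generate_synthetic(SyntheticSpec(n=25, p=1, effects={0: 1.0}))
        seq = run_revs(data)
        assert len(seq.models) == 1
        assert seq.delta_aic == (0.0,)

    def test_one_model_per_predictor(self, small_data):
        seq = run_revs(small_data)
        assert len(seq.models) == small_data.p

    def test_models_nest_and_grow_by_one(self, small_data):
        seq = run_revs(small_data)
        for j in range(1, len(seq.models)):
            prev = set(seq.models[j - 1].subset)
            cur = set(seq.models[j].subset)
            assert prev < cur and len(cur) == len(prev) + 1

    def test_composition_with_oracle_ranking(self, medium_data):
        # the j-th model must hold exactly the top-j variables of the
        # ranking derived from oracle-validated level-best subsets
        oracle = oracle_best_subsets(medium_data)
        p = medium_data.p
        counts = np.zeros(p, dtype=int)
        for k in range(1, p + 1):
            for v in oracle[k][0]:
                counts[v] += 1
        expected_order = sorted(range(p), key=lambda v: (-counts[v], v))
        seq = run_revs(medium_data)
        for j in range(p):
            assert set(seq.models[j].subset) == set(expected_order[: j + 1])

    def test_entered_signs_match_coefficients(self, medium_data):
        seq = run_revs(medium_data)
        for j, (fit, var, sign) in enumerate(
            zip(seq.models, seq.entered, seq.entered_signs)
        ):
            pos = fit.subset.index(var)
            assert np.sign(fit.slopes[pos]) == sign

    def test_unfittable_top_levels_flagged_not_fatal(self):
        rng = np.random.default_rng(4)
        data = Dataset(rng.normal(size=8), rng.normal(size=(8, 8)))
        seq = build_nested_sequence(data, _staircase_ranking(8))
        assert seq.models[5] is not None  # k=6, n=8 > 7
        assert seq.models[6] is None and seq.models[7] is None
        assert np.isfinite(seq.delta_aic[:6]).all()
        assert seq.best_by_aic is not None

    def test_delta_floor_and_nonnegativity(self, small_data):
        seq = run_revs(small_data)
        all_deltas = list(seq.delta_aic) + list(seq.alternative_delta_aic)
        assert min(all_deltas) == pytest.approx(0.0)
        assert all(d >= 0 for d in all_deltas)


class TestTieAlternatives:
    def test_no_tie_groups_leaves_sequence_unchanged(self, medium_data):
        matrix = level_matrix(medium_data)
        ranking = rank_by_inclusion(matrix)
        assert all(len(g) == 1 for g in ranking.tie_groups)
        seq = build_nested_sequence(medium_data, ranking)
        resolved = resolve_tie_alternatives(seq, ranking, medium_data)
        assert resolved.alternatives == ()
        assert resolved.best_by_aic == seq.best_by_aic

    def test_two_way_split_fits_the_one_alternative(self, tied_data):
        matrix = level_matrix(tied_data)
        ranking = rank_by_inclusion(matrix)
        seq = resolve_tie_alternatives(
            build_nested_sequence(tied_data, ranking), ranking, tied_data
        )
        assert seq.alternatives  # ties exist and are split somewhere
        # oracle: for every alternative, refit the swapped subset by hand
        # and verify AIC; the winner must be the argmin over all models
        candidates = []
        for j, fit in enumerate(seq.models):
            candidates.append((fit.aic, ("primary", j)))
        for i, alt in enumerate(seq.alternatives):
            refit = fit_subset(tied_data, alt.fit.subset)
            assert refit.aic == pytest.approx(alt.fit.aic)
            assert 0 < len(alt.chosen) < len(alt.tie_group)
            candidates.append((alt.fit.aic, ("alternative", i)))
        best_aic, best_handle = min(candidates)
        assert seq.best_model.aic == pytest.approx(best_aic)

    def test_two_way_boundary_split_yields_single_alternative_there(
        self, tied_data
    ):
        seq = run_revs(tied_data)
        ranking = seq.ranking
        j_best = (
            seq.best_by_aic[1] + 1
            if seq.best_by_aic[0] == "primary"
            else seq.alternatives[seq.best_by_aic[1]].fit.k
        )
        group = ranking.group_of(ranking.order[j_best - 1])
        same_size = [a for a in seq.alternatives if a.fit.k == j_best]
        if len(group) == 2:
            assert len(same_size) == 1

    def test_wide_tie_raises_and_override_enumerates(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 9))
        y = X[:, 0] + X[:, 1] + rng.normal(size=40)
        data = Dataset(y, X)
        # fabricated ranking: a 7-way tie heads the order, so the best
        # model's cutoff necessarily splits it
        ranking = InclusionRanking(
            counts=np.array([5, 5, 5, 5, 5, 5, 5, 2, 1]),
            order=tuple(range(9)),
            tie_groups=(tuple(range(7)), (7,), (8,)),
            predictor_names=data.predictor_names,
        )
        seq = build_nested_sequence(data, ranking)
        assert seq.best_by_aic[0] == "primary" and seq.best_by_aic[1] < 6
        with pytest.raises(TieWidthError, match="tie too wide"):
            resolve_tie_alternatives(seq, ranking, data)
        with pytest.warns(UserWarning, match="enumerating"):
            resolved = resolve_tie_alternatives(
                seq, ranking, data, allow_wide_ties=True
            )
        assert resolved.alternatives


class TestSelectBest:
    def test_single_model_designations_coincide(self):
        data = generate_synthetic(SyntheticSpec(n=30, p=1, effects={0: 1.0}))
        seq = run_revs(data)
        best = select_best(seq)
        assert (
            best["best_by_aic"]
            == best["best_by_adj_r2"]
            == best["best_by_p"]
            == ("primary", 0)
        )

    def test_aic_prefers_no_larger_model_than_adjusted_r2(self, small_data):
        # AIC penalises parameters harder than the adjusted R², so its
        # optimum sits at the same size or earlier in the nested series
        seq = run_revs(small_data)
        best = select_best(seq)
        size = lambda h: seq.model(*h).k
        assert size(best["best_by_aic"]) <= size(best["best_by_adj_r2"])

    def test_aic_best_matches_independent_recomputation(self, small_data):
        seq = run_revs(small_data)
        recomputed = [
            aic_gaussian(m.rss, m.n, m.k) for m in seq.models
        ] + [aic_gaussian(a.fit.rss, a.fit.n, a.fit.k) for a in seq.alternatives]
        assert seq.best_model.aic == pytest.approx(min(recomputed))

    def test_competing_set_is_delta_at_most_two(self, small_data):
        seq = run_revs(small_data)
        deltas = dict(
            [(("primary", i), d) for i, d in enumerate(seq.delta_aic)]
            + [
                (("alternative", i), d)
                for i, d in enumerate(seq.alternative_delta_aic)
            ]
        )
        expected = {h for h, d in deltas.items() if np.isfinite(d) and d <= 2}
        assert set(seq.competing) == expected


class TestOrderInvariance:
    def test_best_model_invariant_under_column_permutation(self):
        data = generate_synthetic(
            SyntheticSpec(
                n=50, p=8, effects={0: 1.0, 3: 0.8}, rho=0.5, sigma=1.0,
                seed=1, duplicates=((0, 0.2), (3, 0.2)),
            )
        )
        ranking = rank_by_inclusion(level_matrix(data))
        assert any(len(g) > 1 for g in ranking.tie_groups)  # ties active
        base = run_revs(data).best_model
        rng = np.random.default_rng(77)
        for _ in range(5):
            perm = list(rng.permutation(data.p))
            best = run_revs(data.permute_columns(perm)).best_model
            assert frozenset(best.names) == frozenset(base.names)
            assert best.aic == pytest.approx(base.aic)

    def test_full_model_always_in_series(self, small_data):
        seq = run_revs(small_data)
        full = fit_subset(small_data, range(small_data.p))
        assert seq.models[-1].aic == pytest.approx(full.aic)
        assert seq.best_model.aic <= full.aic + 1e-9
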