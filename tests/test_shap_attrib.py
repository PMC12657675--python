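"""Shapley attribution: axioms, estimator convergence, image games, ROI."""

import numpy as np
import pytest

from adgrade import shap_attrib as sa


def random_table_game(m, rng, scale=1.0):
    """Random coalitional game backed by a 2^m value table."""
    table = rng.normal(scale=scale, size=2**m)

    def value(mask):
        code = int(np.dot(mask.astype(int), 1 << np.arange(m)))
        return table[code]

    return sa.CoalitionalGame(m=m, value=value)


def ordering_brute_force(game):
    """Independent oracle: mean marginal contribution over all M! orderings."""
    from itertools import permutations

    m = game.m
    phi = np.zeros(m)
    count = 0
    for order in permutations(range(m)):
        mask = np.zeros(m, dtype=bool)
        prev = game(mask)
        for i in order:
            mask[i] = True
            cur = game(mask)
            phi[i] += cur - prev
            prev = cur
        count += 1
    return phi / count


class TestExactShapley:
    def test_additive_game_recovers_weights(self, rng):
        w = rng.normal(size=6)
        game = sa.CoalitionalGame(m=6, value=lambda mask: float(w[mask].sum()))
        assert np.allclose(sa.exact_shapley(game), w)

    def test_symmetric_players_get_equal_shares(self):
        # f({1}) = f({2}), arbitrary f({1,2})
        table = {(False, False): 0.0, (True, False): 0.3, (False, True): 0.3,
                 (True, True): 1.1}
        game = sa.CoalitionalGame(m=2, value=lambda m: table[tuple(m)])
        phi = sa.exact_shapley(game)
        assert phi[0] == pytest.approx(phi[1])

    def test_matches_ordering_enumeration_oracle(self, rng):
        for _ in range(5):
            game = random_table_game(3, rng)
            assert np.allclose(sa.exact_shapley(game), ordering_brute_force(game))

    def test_enumeration_bound_enforced(self):
        game = sa.CoalitionalGame(m=25, value=lambda m: 0.0)
        with pytest.raises(sa.EnumerationBoundError):
            sa.exact_shapley(game)

    def test_efficiency_exact(self, rng):
        game = random_table_game(5, rng)
        phi = sa.exact_shapley(game)
        full = game(np.ones(5, dtype=bool))
        empty = game(np.zeros(5, dtype=bool))
        assert phi.sum() == pytest.approx(full - empty, abs=1e-12)


class TestAxiomSuite:
    def test_axioms_on_random_small_games(self):
        rng = np.random.default_rng(777)
        for trial in range(30):
            m = int(rng.integers(2, 7))
            game = random_table_game(m, rng)
            phi = sa.exact_shapley(game)
            # efficiency
            assert phi.sum() == pytest.approx(
                game(np.ones(m, bool)) - game(np.zeros(m, bool)), abs=1e-10
            )
            # linearity: phi(a + b) = phi(a) + phi(b)
            game_b = random_table_game(m, rng)
            summed = sa.CoalitionalGame(
                m=m, value=lambda mask: game(mask) + game_b(mask)
            )
            assert np.allclose(
                sa.exact_shapley(summed),
                phi + sa.exact_shapley(game_b),
                atol=1e-10,
            )

    def test_null_player_gets_zero(self, rng):
        # value ignores player 0 entirely
        w = rng.normal(size=4)
        game = sa.CoalitionalGame(
            m=5, value=lambda mask: float(w[mask[1:]].sum())
        )
        phi = sa.exact_shapley(game)
        assert phi[0] == pytest.approx(0.0, abs=1e-12)


class TestSampledShapley:
    def test_additive_game_exact_after_one_permutation(self, rng):
        w = rng.normal(size=4)
        game = sa.CoalitionalGame(m=4, value=lambda mask: float(w[mask].sum()))
        phi, _ = sa.sampled_shapley(game, n_permutations=1, seed=0)
        assert np.allclose(phi, w)

    def test_converges_to_exact_on_m5_game(self):
        rng = np.random.default_rng(99)
        game = random_table_game(5, rng)
        exact = sa.exact_shapley(game)
        phi, se = sa.sampled_shapley(game, n_permutations=10_000, seed=1)
        vals = [
            game(np.array([(c >> j) & 1 for j in range(5)], dtype=bool))
            for c in range(32)
        ]
        f_range = max(vals) - min(vals)
        assert np.max(np.abs(phi - exact)) < 0.02 * f_range

    def test_efficiency_holds_at_any_sample_size(self, rng):
        game = random_table_game(6, rng)
        full = game(np.ones(6, bool))
        empty = game(np.zeros(6, bool))
        for n in (1, 7, 50):
            phi, _ = sa.sampled_shapley(game, n_permutations=n, seed=3)
            assert phi.sum() == pytest.approx(full - empty, abs=1e-10)

    def test_standard_errors_shrink_like_root_n(self):
        rng = np.random.default_rng(5)
        game = random_table_game(5, rng)
        ns = np.array([100, 400, 1600, 6400])
        ses = []
        for n in ns:
            _, se = sa.sampled_shapley(game, n_permutations=int(n), seed=11)
            ses.append(se.mean())
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert abs(slope + 0.5) < 0.1


class TestImageAttribution:
    def _background(self, rng, shape=(16, 16), n=8):
        return sa.BackgroundSet(rng.random((n,) + shape))

    def test_constant_model_gives_zero_map(self, rng):
        model = lambda x: np.tile([0.25, 0.25, 0.25, 0.25], (len(x), 1))
        img = rng.random((16, 16))
        attr = sa.image_attribution(
            model, img, self._background(rng), target_class=1, tile=8,
            n_permutations=4, background_draws=2, seed=0,
        )
        assert np.allclose(attr.values, 0.0, atol=1e-12)

    def test_linear_model_matches_closed_form(self, rng):
        # model output = sum_g w_g * mean_g(x): group attribution must equal
        # w_g * (mean_g(x) - mean over background draws of mean_g(b))
        grouping = sa.tile_grouping((16, 16), 8)  # 4 groups
        w = np.array([0.5, -0.3, 0.2, 0.7])

        def model(batch):
            vals = np.stack(
                [batch[:, grouping == g].mean(axis=1) for g in range(4)], axis=1
            )
            score = vals @ w
            out = np.zeros((len(batch), 2))
            out[:, 0] = score
            out[:, 1] = 1 - score
            return out

        img = rng.random((16, 16))
        bg = self._background(rng)
        attr = sa.image_attribution(
            model, img, bg, target_class=0, tile=8,
            n_permutations=30, background_draws=10, seed=2,
        )
        # reproduce the background draws the game used
        inner = np.random.default_rng(2)
        draws = inner.integers(0, len(bg.images), size=10)
        bg_used = bg.images[draws]
        expected = np.array(
            [
                w[g] * (img[grouping == g].mean()
                        - bg_used[:, grouping == g].mean(axis=1).mean())
                for g in range(4)
            ]
        )
        assert np.allclose(attr.group_values, expected, atol=1e-8)

    def test_map_shape_and_efficiency(self, rng):
        model = lambda x: np.stack(
            [x.mean(axis=(1, 2)), 1 - x.mean(axis=(1, 2))], axis=1
        )
        img = rng.random((16, 16))
        bg = self._background(rng)
        attr = sa.image_attribution(
            model, img, bg, target_class=0, tile=4,
            n_permutations=5, background_draws=3, seed=1,
        )
        assert attr.values.shape == img.shape
        full_score = float(model(img[None])[0, 0])
        assert attr.values.sum() + attr.base_value == pytest.approx(
            full_score, abs=1e-8
        )

    def test_bad_grouping_rejected(self, rng):
        model = lambda x: np.tile([1.0, 0.0], (len(x), 1))
        img = rng.random((16, 16))
        with pytest.raises(sa.InvalidGroupingError):
            sa.image_attribution(
                model, img, self._background(rng), target_class=0,
                grouping=np.zeros((8, 8), dtype=int),
            )


class TestRoiFraction:
    def _map(self, values):
        return sa.AttributionMap(
            values=np.asarray(values, dtype=float),
            base_value=0.0,
            predicted_class=0,
            target_class=0,
        )

    def test_whole_image_mask_gives_one(self, rng):
        attr = self._map(rng.normal(size=(8, 8)))
        assert sa.roi_fraction(attr, np.ones((8, 8), bool)) == 1.0

    def test_empty_mask_gives_zero(self, rng):
        attr = self._map(rng.normal(size=(8, 8)))
        assert sa.roi_fraction(attr, np.zeros((8, 8), bool)) == 0.0

    def test_half_mass_inside_mask(self):
        values = np.zeros((4, 4))
        values[0, 0], values[3, 3] = 2.0, -2.0  # equal |phi| inside/outside
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        assert sa.roi_fraction(self._map(values), mask) == pytest.approx(0.5)

    def test_zero_map_gives_zero(self):
        assert sa.roi_fraction(self._map(np.zeros((4, 4))), np.ones((4, 4), bool)) == 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(sa.ShapeError):
            sa.roi_fraction(self._map(np.zeros((4, 4))), np.ones((5, 5), bool))


class TestSummaryRanking:
    def _map_from_groups(self, phi, grouping):
        values = np.zeros(grouping.shape)
        for i, p in enumerate(phi):
            m = grouping == i
            values[m] = p / m.sum()
        return sa.AttributionMap(
            values=values,
            base_value=0.0,
            predicted_class=0,
            target_class=0,
            group_values=np.asarray(phi, dtype=float),
            group_ids=grouping,
        )

    def test_single_map_ranking_sorts_abs_values(self):
        grouping = sa.tile_grouping((8, 8), 4)
        ranked = sa.summary_ranking(
            [self._map_from_groups([0.1, -0.9, 0.5, 0.2], grouping)]
        )
        assert [r["feature"] for r in ranked] == [1, 2, 3, 0]

    def test_duplicated_maps_keep_ranking(self):
        grouping = sa.tile_grouping((8, 8), 4)
        m = self._map_from_groups([0.1, -0.9, 0.5, 0.2], grouping)
        assert [r["feature"] for r in sa.summary_ranking([m, m, m])] == [1, 2, 3, 0]

    def test_planted_dominant_feature_ranks_first(self):
        grouping = sa.tile_grouping((8, 8), 4)
        rng = np.random.default_rng(17)
        for _ in range(20):
            maps = []
            for _ in range(20):
                phi = rng.normal(scale=0.1, size=4)
                phi[2] = 10.0 * np.sign(rng.normal()) * (1 + rng.random())
                maps.append(self._map_from_groups(phi, grouping))
            assert sa.summary_ranking(maps)[0]["feature"] == 2

    def test_inconsistent_groupings_rejected(self):
        g1 = sa.tile_grouping((8, 8), 4)
        g2 = sa.tile_grouping((8, 8), 2)
        m1 = self._map_from_groups([0.1, 0.2, 0.3, 0.4], g1)
        m2 = self._map_from_groups(list(range(16)), g2)
        with pytest.raises(ValueError):
            sa.summary_ranking([m1, m2])
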