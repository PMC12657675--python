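"""Shapley-value attribution for image classifiers.

The Shapley value of player i in a coalitional game (M players, value
function f over subsets) is

    phi_i = sum_{S subseteq N\\{i}} |S|! (M - |S| - 1)! / M! * (f(S u {i}) - f(S)),

the average marginal contribution of i over all player orderings. Two
routes are provided: exact subset enumeration for small M, and a
permutation-sampling estimator whose efficiency property
(sum phi = f(full) - f(empty)) holds exactly for every sampled ordering.

For images, pixels are grouped into superpixel tiles (players); the game
value f(S) is the model's target-class score with out-of-coalition tiles
replaced by background pixels, averaged over background draws. Group
attributions broadcast back to pixels give the attribution map; aggregating
|phi| over a region-of-interest mask gives that region's share of the total
feature importance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np


class InvalidGroupingError(ValueError):
    pass


class ShapeError(ValueError):
    pass


class EnumerationBoundError(ValueError):
    pass


@dataclass
class CoalitionalGame:
    """M players and a value function over boolean coalition masks."""

    m: int
    value: callable  # f(mask: np.ndarray[bool] of length m) -> float

    def __call__(self, mask: np.ndarray) -> float:
        return float(self.value(np.asarray(mask, dtype=bool)))


@dataclass
class AttributionMap:
    """Per-pixel Shapley values (group values broadcast per pixel)."""

    values: np.ndarray  # (H, W)
    base_value: float
    predicted_class: int
    target_class: int
    group_values: np.ndarray | None = None
    group_ids: np.ndarray | None = None  # (H, W) int partition map

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class BackgroundSet:
    """Reference images the model's expectation is taken over."""

    images: np.ndarray  # (B, H, W)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if len(self.images) == 0:
            raise ShapeError("background set must be nonempty")


def exact_shapley(game: CoalitionalGame, bound: int = 20) -> np.ndarray:
    """Exact Shapley values by subset enumeration; M must stay <= bound."""
    m = game.m
    if m > bound:
        raise EnumerationBoundError(
            f"M={m} exceeds the enumeration bound {bound}; use sampled_shapley"
        )
    players = list(range(m))
    # cache all 2^m coalition values, keyed by bitmask
    values = np.empty(2**m)
    for code in range(2**m):
        mask = np.array([(code >> j) & 1 for j in range(m)], dtype=bool)
        values[code] = game(mask)
    phi = np.zeros(m)
    fact = [factorial(j) for j in range(m + 1)]
    for i in players:
        others = [j for j in players if j != i]
        for size in range(m):
            w = fact[size] * fact[m - size - 1] / fact[m]
            for s in combinations(others, size):
                code = sum(1 << j for j in s)
                phi[i] += w * (values[code | (1 << i)] - values[code])
    return phi


def sampled_shapley(
    game: CoalitionalGame, n_permutations: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling estimate of the Shapley values.

    Returns (phi_hat, standard_errors). Efficiency holds exactly: for every
    permutation the marginals telescope to f(full) - f(empty), so the mean
    satisfies sum(phi_hat) = f(full) - f(empty) to machine precision.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    m = game.m
    contribs = np.zeros((n_permutations, m))
    for p in range(n_permutations):
        order = rng.permutation(m)
        mask = np.zeros(m, dtype=bool)
        prev = game(mask)
        for i in order:
            mask[i] = True
            cur = game(mask)
            contribs[p, i] = cur - prev
            prev = cur
    phi = contribs.mean(axis=0)
    if n_permutations > 1:
        se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    else:
        se = np.full(m, np.nan)
    return phi, se


def tile_grouping(shape: tuple[int, int], tile: int = 8) -> np.ndarray:
    """g x g superpixel partition of the pixel grid, as an int id map."""
    h, w = shape
    rows = np.arange(h) // tile
    cols = np.arange(w) // tile
    n_cols = int(cols.max()) + 1
    return (rows[:, None] * n_cols + cols[None, :]).astype(np.int64)


def image_attribution(
    model,
    image: np.ndarray,
    background: BackgroundSet,
    target_class: int,
    grouping: np.ndarray | None = None,
    tile: int = 8,
    n_permutations: int = 20,
    background_draws: int = 10,
    seed: int = 0,
) -> AttributionMap:
    """Shapley attribution map of ``model``'s target-class score for ``image``.

    ``model`` maps a (N, H, W) batch to (N, n_classes) probabilities.
    ``grouping`` is an int id map partitioning the pixels (default: ``tile``
    x ``tile`` superpixels). f(S) averages the target-class score over
    ``background_draws`` background substitutions of out-of-S groups.
    """
    image = np.asarray(image, dtype=np.float64)
    if grouping is None:
        grouping = tile_grouping(image.shape, tile)
    grouping = np.asarray(grouping)
    if grouping.shape != image.shape:
        raise InvalidGroupingError("grouping must have the image's shape")
    ids = np.unique(grouping)
    if not np.array_equal(ids, np.arange(len(ids))):
        raise InvalidGroupingError("group ids must be 0..G-1 with every pixel assigned")
    g = len(ids)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(background.images), size=background_draws)
    bg = background.images[draws]  # (D, H, W)
    group_masks = [grouping == i for i in ids]

    def value(coalition: np.ndarray) -> float:
        keep = np.isin(grouping, ids[coalition])
        comps = np.where(keep[None], image[None], bg)  # (D, H, W)
        probs = model(comps)
        return float(np.mean(probs[:, target_class]))

    game = CoalitionalGame(m=g, value=value)
    phi, _ = sampled_shapley(game, n_permutations, seed=int(rng.integers(2**31)))
    base = game(np.zeros(g, dtype=bool))
    pixel_map = np.zeros_like(image)
    for i, mask in enumerate(group_masks):
        pixel_map[mask] = phi[i] / mask.sum()
    pred = int(np.argmax(model(image[None])[0]))
    return AttributionMap(
        values=pixel_map,
        base_value=base,
        predicted_class=pred,
        target_class=int(target_class),
        group_values=phi,
        group_ids=grouping,
    )


def roi_fraction(attr: AttributionMap, mask: np.ndarray) -> float:
    """Share of total absolute attribution inside a binary region mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != attr.values.shape:
        raise ShapeError(f"mask shape {mask.shape} != map shape {attr.values.shape}")
    total = np.abs(attr.values).sum()
    if total == 0:
        return 0.0
    return float(np.abs(attr.values[mask]).sum() / total)


def summary_ranking(maps: list[AttributionMap]) -> list[dict]:
    """Features (groups) ranked by mean |phi| across maps, with sign profiles."""
    if not maps:
        raise ValueError("need at least one attribution map")
    ref = maps[0]
    if ref.group_values is None:
        raise ValueError("maps must carry group-level values")
    g = len(ref.group_values)
    for m in maps:
        if m.group_values is None or len(m.group_values) != g or not np.array_equal(
            m.group_ids, ref.group_ids
        ):
            raise ValueError("attribution maps use inconsistent groupings")
    mat = np.stack([m.group_values for m in maps])  # (n_maps, G)
    mean_abs = np.abs(mat).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    return [
        {
            "feature": int(i),
            "mean_abs_phi": float(mean_abs[i]),
            "values": mat[:, i].tolist(),
        }
        for i in order
    ]


__all__ = [
    "CoalitionalGame",
    "AttributionMap",
    "BackgroundSet",
    "InvalidGroupingError",
    "ShapeError",
    "EnumerationBoundError",
    "exact_shapley",
    "sampled_shapley",
    "tile_grouping",
    "image_attribution",
    "roi_fraction",
    "summary_ranking",
]
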