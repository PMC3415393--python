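"""Sex-based plate-layout design and diagnostics.

Laying samples out on 8x12 plates with distinct, rotationally asymmetric
sex patterns turns a cheap genotype-derived sex check into a definitive
plate-level diagnostic: using the wrong plate, or the right plate in the
wrong orientation, shows up immediately when inferred sexes are plotted by
well.  Individual switches of neighbouring samples are only detectable when
the two wells hold opposite sexes, so good designs minimise the number of
orthogonally adjacent same-sex pairs while avoiding 180-degree rotational
symmetry (of the pattern, and of its sex-inverse).

An 8x12 plate has 88 horizontal + 84 vertical = 172 orthogonally adjacent
well pairs (diagonals are ignored throughout).
"""

from __future__ import annotations

import numpy as np

from .core import PLATE_N_COLS, PLATE_N_ROWS, PlateLayout

N_NEIGHBOUR_PAIRS = (PLATE_N_ROWS * (PLATE_N_COLS - 1)) + ((PLATE_N_ROWS - 1) * PLATE_N_COLS)

#: row blocks of the 1-2-2-2-1 design; the unequal end blocks break the
#: rotational symmetry a plain 2-2-2-2 pattern would have
ROW_BLOCKS = (1, 2, 2, 2, 1)

PATTERN_KINDS = ("blocked_12221", "permuted_columns", "chequerboard", "random")


def _row_phases() -> np.ndarray:
    """Per-row phase bit: blocks of sizes 1,2,2,2,1 with alternating phase."""
    phases = []
    bit = 0
    for size in ROW_BLOCKS:
        phases.extend([bit] * size)
        bit ^= 1
    return np.array(phases, dtype=int)


def _basic_columns() -> list[np.ndarray]:
    """The four basic 8-well column patterns used by the permuted-columns
    family: the blocked phase vector, its complement, and a cyclic shift of
    each (the phase vector is a palindrome, so plain reversals would
    duplicate the first two)."""
    p = _row_phases()
    q = np.roll(p, 3)
    return [p, 1 - p, q, 1 - q]


def _bits_to_sexes(bits: np.ndarray) -> np.ndarray:
    return np.where(bits.astype(bool), "female", "male").astype(object)


def generate_pattern(
    kind: str,
    seed: int | None = None,
    permutation: tuple[int, ...] | None = None,
    plate_id: str = "design",
) -> PlateLayout:
    """Generate a sex pattern for a full 8x12 plate (48 of each sex).

    Kinds:

    - ``blocked_12221`` — rows form blocks of sizes 1,2,2,2,1 with
      alternating sex phase and adjacent columns complementary (the simplest
      rotationally asymmetric regular design; 36 same-sex pairs, 3 per
      column).
    - ``permuted_columns`` — columns drawn from the four basic column
      patterns in a caller-chosen order (``permutation``: 12 indices into
      the basic set; default cycles 0,1,2,3).
    - ``chequerboard`` — alternation in both directions; 0 same-sex pairs
      but 180-degree rotationally symmetric, so unusable on its own.
    - ``random`` — uniform random balanced layout (requires ``seed``).
    """
    rows = np.arange(PLATE_N_ROWS)[:, None]
    cols = np.arange(PLATE_N_COLS)[None, :]
    if kind == "blocked_12221":
        bits = _row_phases()[:, None] ^ (cols % 2)
    elif kind == "chequerboard":
        bits = (rows + cols) % 2
    elif kind == "permuted_columns":
        if permutation is None:
            permutation = tuple(i % 4 for i in range(PLATE_N_COLS))
        if len(permutation) != PLATE_N_COLS:
            raise ValueError("permutation must list 12 column indices")
        basic = _basic_columns()
        bits = np.stack([basic[i] for i in permutation], axis=1)
    elif kind == "random":
        rng = np.random.default_rng(seed)
        flat = np.repeat([0, 1], PLATE_N_ROWS * PLATE_N_COLS // 2)
        bits = rng.permutation(flat).reshape(PLATE_N_ROWS, PLATE_N_COLS)
    else:
        raise ValueError(f"unknown pattern kind: {kind!r}; choose from {PATTERN_KINDS}")
    return PlateLayout.from_sex_grid(plate_id, _bits_to_sexes(np.asarray(bits)))


def count_same_sex_pairs(layout: PlateLayout) -> int:
    """Number of orthogonally adjacent well pairs holding the same sex."""
    s = layout.sexes
    if s.shape != (PLATE_N_ROWS, PLATE_N_COLS) or (s == None).any():  # noqa: E711
        raise ValueError("full 8x12 sex layout required")
    horiz = int((s[:, :-1] == s[:, 1:]).sum())
    vert = int((s[:-1, :] == s[1:, :]).sum())
    return horiz + vert


def same_sex_pairs_per_column(layout: PlateLayout) -> list[int]:
    """Vertical same-sex pairs per column plus each column's share of
    horizontal pairs is design-specific; this reports the vertical count
    only (the quantity quoted as 'three in each column' for the blocked
    design, whose horizontal pairs are zero)."""
    s = layout.sexes
    return [int((s[:-1, c] == s[1:, c]).sum()) for c in range(PLATE_N_COLS)]


def check_rotational_distinctness(layouts: list[PlateLayout]) -> list[dict]:
    """Flag layouts confusable under a 180-degree rotation.

    Checks each layout against a rotation of itself, of its sex-inverse
    (a design whose inverse equals its own rotation cannot be used together
    with that inverse), and of every other supplied layout.
    """
    flags = []
    rots = [lay.rotate180() for lay in layouts]
    for i, lay in enumerate(layouts):
        if lay.sexes_equal(rots[i]):
            flags.append({"type": "self_rotational", "layouts": [lay.plate_id]})
        if lay.sex_inverse().sexes_equal(rots[i]):
            flags.append({"type": "inverse_rotational", "layouts": [lay.plate_id]})
        for j in range(i + 1, len(layouts)):
            if lay.sexes_equal(rots[j]) or lay.sexes_equal(layouts[j]):
                flags.append(
                    {"type": "pair_confusable", "layouts": [lay.plate_id, layouts[j].plate_id]}
                )
            elif lay.sex_inverse().sexes_equal(rots[j]):
                flags.append(
                    {
                        "type": "pair_inverse_confusable",
                        "layouts": [lay.plate_id, layouts[j].plate_id],
                    }
                )
    return flags


# ---------------------------------------------------------------------------
# random-layout simulations


def _random_balanced_bits(rng: np.random.Generator, n: int) -> np.ndarray:
    """n independent uniform balanced 8x12 0/1 layouts, shape (n, 8, 12)."""
    flat = np.tile(np.repeat([0, 1], PLATE_N_ROWS * PLATE_N_COLS // 2), (n, 1))
    out = rng.permuted(flat, axis=1)
    return out.reshape(n, PLATE_N_ROWS, PLATE_N_COLS)


def _same_sex_counts(bits: np.ndarray) -> np.ndarray:
    horiz = (bits[:, :, :-1] == bits[:, :, 1:]).sum(axis=(1, 2))
    vert = (bits[:, :-1, :] == bits[:, 1:, :]).sum(axis=(1, 2))
    return horiz + vert


def expected_same_sex_pairs_random(n_male: int = 48, n_female: int = 48) -> float:
    """Analytic expectation of same-sex neighbour pairs for a uniform
    balanced layout: 172 x P(two distinct wells share a sex)."""
    n = n_male + n_female
    p_same = (n_male * (n_male - 1) + n_female * (n_female - 1)) / (n * (n - 1))
    return N_NEIGHBOUR_PAIRS * p_same


def simulate_random_layout_stats(
    n_plates: int,
    n_reps: int,
    seed: int,
    n_pair_layouts: int = 10_000,
) -> dict:
    """Monte-Carlo summaries for random balanced plate layouts.

    Per replicate, ``n_plates`` independent balanced layouts are drawn and
    the minimum over all plate pairs of the number of differing wells is
    recorded.  Since both layouts are balanced, a difference of d wells can
    be explained by a minimum of d/2 simple switches.  Same-sex pair counts
    are accumulated over ``n_pair_layouts`` additional independent layouts.
    """
    if n_plates < 2:
        raise ValueError("need at least two plates to compare")
    rng = np.random.default_rng(seed)

    counts = _same_sex_counts(_random_balanced_bits(rng, n_pair_layouts))

    minima = np.empty(n_reps, dtype=int)
    for rep in range(n_reps):
        bits = _random_balanced_bits(rng, n_plates).reshape(n_plates, -1).astype(np.int32)
        # differing wells between plates a and b: x(1-y) + (1-x)y summed
        cross = bits @ (1 - bits).T
        diff = cross + cross.T
        iu = np.triu_indices(n_plates, k=1)
        minima[rep] = int(diff[iu].min())

    min_central = float(np.median(minima))
    return {
        "n_plates": n_plates,
        "n_reps": n_reps,
        "same_sex_pairs_mean": float(counts.mean()),
        "same_sex_pairs_sd": float(counts.std(ddof=1)),
        "same_sex_pairs_n": int(len(counts)),
        "min_well_difference_median": min_central,
        "min_well_difference_q025": float(np.quantile(minima, 0.025)),
        "min_well_difference_q975": float(np.quantile(minima, 0.975)),
        "min_swaps_to_explain_median_difference": min_central / 2.0,
    }


def min_swaps_for_difference(d: int) -> float:
    """Minimum number of simple switches explaining a d-well difference
    between two balanced layouts (each switch fixes at most two wells)."""
    if d % 2:
        raise ValueError("two balanced layouts differ in an even number of wells")
    return d / 2


# ---------------------------------------------------------------------------
# sex-check diagnostic


def sex_check_diagnostic(
    expected: PlateLayout,
    inferred_sexes: np.ndarray,
    alternates: list[PlateLayout] | None = None,
) -> dict:
    """Compare externally inferred sexes against the expected layout.

    Tests the identity, the 180-degree rotation, and any supplied alternate
    plates (and their rotations); reports the best-fitting explanation and
    the residual mismatched wells under it.  Same-sex neighbour switches are
    invisible to this check by construction.
    """
    inferred = np.asarray(inferred_sexes, dtype=object)
    if inferred.shape != (PLATE_N_ROWS, PLATE_N_COLS):
        raise ValueError("inferred sexes must form an 8x12 grid")

    candidates: list[tuple[str, PlateLayout]] = [("identity", expected)]
    candidates.append(("rotation_180", expected.rotate180()))
    for alt in alternates or []:
        candidates.append((f"plate:{alt.plate_id}", alt))
        candidates.append((f"plate:{alt.plate_id}+rotation_180", alt.rotate180()))

    results = []
    for name, lay in candidates:
        mismatch = [
            (r, c)
            for r in range(PLATE_N_ROWS)
            for c in range(PLATE_N_COLS)
            if lay.sexes[r, c] is not None and lay.sexes[r, c] != inferred[r, c]
        ]
        results.append((len(mismatch), name, mismatch))
    results.sort(key=lambda t: t[0])
    best_n, best_name, best_mismatch = results[0]
    from .core import rc_to_well

    return {
        "best_explanation": best_name,
        "n_mismatches": best_n,
        "mismatched_wells": [rc_to_well(r, c) for r, c in best_mismatch],
        "candidates": {name: n for n, name, _ in results},
    }
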