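import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfpri import (
    FilterConfig,
    ValidationError,
    apply_rules,
    filter_indicators,
    gene_stats,
    interval_overlap,
    threshold_sweep,
)
from cfpri.filtration import (
    DOWN,
    RULE_FOLD,
    RULE_FULL_OVERLAP,
    RULE_OVERLAP,
    RULE_ZERO,
    UP,
    stats_from_values,
)

from conftest import make_matrix, random_matrix


# --------------------------------------------------------------- overlap
@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((2, 5), (2, 5), 1.0),
        ((0, 1), (2, 3), 0.0),
        ((0, 10), (5, 20), 0.5),       # intersection 5 / min(10, 15)
        ((0, 10), (2, 4), 1.0),        # nesting counts as full overlap
        ((5, 5), (5, 5), 1.0),         # coincident points
        ((5, 5), (6, 6), 0.0),
        ((3, 3), (1, 5), 1.0),         # point inside interval
        ((7, 7), (1, 5), 0.0),
        ((0, 4), (4, 8), 0.0),         # touching endpoints: zero-length overlap
    ],
)
def test_interval_overlap_cases(a, b, expected):
    assert interval_overlap(*a, *b) == pytest.approx(expected)


def test_interval_overlap_rejects_inverted():
    with pytest.raises(ValidationError):
        interval_overlap(5, 2, 0, 1)


@settings(deadline=None, max_examples=200)
@given(
    st.tuples(*[st.floats(-100, 100, allow_nan=False) for _ in range(4)])
)
def test_interval_overlap_symmetric_and_bounded(vals):
    a0, a1, b0, b1 = vals
    a_min, a_max = min(a0, a1), max(a0, a1)
    b_min, b_max = min(b0, b1), max(b0, b1)
    r1 = interval_overlap(a_min, a_max, b_min, b_max)
    r2 = interval_overlap(b_min, b_max, a_min, a_max)
    assert r1 == pytest.approx(r2)
    assert 0.0 <= r1 <= 1.0


# ------------------------------------------------------------ gene stats
def test_gene_stats_hand_computed(toy_matrix):
    stats = gene_stats(toy_matrix, "G0")  # NP [1,3], PE [2,6]
    assert stats.np_mean == 2.0 and stats.pe_mean == 4.0
    assert stats.fold == 2.0
    assert stats.overlap_rate == pytest.approx(0.5)  # [2,3] / min(2,4)
    assert not stats.np_has_zero and not stats.pe_has_zero


def test_gene_stats_all_zero_degenerate():
    stats = stats_from_values("g", [0.0, 0.0], [0.0, 0.0])
    assert stats.np_has_zero and stats.pe_has_zero
    assert stats.fold == 1.0
    assert stats.all_zero


def test_gene_stats_identical_points():
    stats = stats_from_values("g", [5.0], [5.0])
    assert stats.overlap_rate == 1.0
    assert stats.fold == 1.0


def test_gene_stats_infinite_fold():
    stats = stats_from_values("g", [0.0, 0.0], [1.0, 3.0])
    assert math.isinf(stats.fold)


def test_gene_stats_missing_gene(toy_matrix):
    with pytest.raises(KeyError, match="NOPE"):
        gene_stats(toy_matrix, "NOPE")


# ------------------------------------------------------------ rule logic
def test_rules_all_zero_gene_fails_zero_and_full_overlap():
    stats = stats_from_values("g", [0.0, 0.0], [0.0, 0.0])
    passed, failed = apply_rules(stats, FilterConfig())
    assert not passed
    assert RULE_ZERO in failed and RULE_FULL_OVERLAP in failed


def test_rules_pass_just_inside_thresholds():
    stats = stats_from_values("g", [1.0, 2.0], [2.59, 4.8])
    assert stats.overlap_rate < 0.6 and stats.fold >= 1.5
    passed, failed = apply_rules(stats, FilterConfig())
    assert passed and failed == []


def test_rules_fold_only_failure():
    # disjoint-ish ranges but weak mean shift
    stats = stats_from_values("g", [1.0, 1.1], [1.15, 1.3])
    assert stats.overlap_rate < 0.6
    passed, failed = apply_rules(stats, FilterConfig())
    assert not passed and failed == [RULE_FOLD]


def test_rules_zero_rule_variants():
    stats = stats_from_values("g", [0.0, 10.0], [0.0, 30.0])
    assert not apply_rules(stats, FilterConfig())[0]
    failed = apply_rules(stats, FilterConfig())[1]
    assert RULE_ZERO in failed
    # the all_zero reading keeps genes that merely contain zeros
    ok, failed = apply_rules(stats, FilterConfig(zero_rule="all_zero"))
    assert RULE_ZERO not in failed


def test_rules_fold_cap():
    stats = stats_from_values("g", [1.0, 2.0], [30.0, 40.0])
    assert apply_rules(stats, FilterConfig())[0]
    passed, failed = apply_rules(stats, FilterConfig(fold_max=2.0))
    assert not passed and failed == [RULE_FOLD]


# ------------------------------------------------------ filter_indicators
@pytest.fixture
def six_gene_matrix():
    """One all-zero, one identical-range, one high-overlap, one low-fold,
    two clear indicators (one up, one down in PE)."""
    rows = [
        [0, 0, 0, 0, 0, 0],                  # rule 1
        [1, 5, 3, 1, 5, 3],                  # identical ranges -> rule 2
        [1.0, 10.0, 2.0, 12.0, 6.0, 9.0],    # overlap ~0.8 -> rule 3
        [10.0, 12.0, 11.0, 11.5, 12.5, 12.0],  # fold ~1.09 -> rule 4
        [1.0, 2.0, 1.5, 4.0, 6.0, 5.0],      # up_in_PE indicator
        [40.0, 60.0, 50.0, 10.0, 20.0, 15.0],  # down_in_PE indicator
    ]
    return make_matrix(rows, ["NP", "NP", "NP", "PE", "PE", "PE"])


def test_filter_toy_matrix_selects_the_two_real_indicators(six_gene_matrix):
    panel = filter_indicators(six_gene_matrix)
    assert panel.gene_ids == ["G4", "G5"]
    assert panel.directions == [UP, DOWN]


def test_filter_preserves_input_gene_order(default_cohort, default_panel):
    matrix, _ = default_cohort
    order = {g: i for i, g in enumerate(matrix.gene_ids)}
    positions = [order[g] for g in default_panel.gene_ids]
    assert positions == sorted(positions)


def test_filter_matches_per_gene_brute_force():
    """Panel equals independent gene-by-gene rule evaluation."""
    cfg = FilterConfig()
    for seed in range(5):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, n_genes=50, n_np=6, n_pe=5)
        panel = filter_indicators(matrix, cfg)
        expected = []
        np_mask = matrix.labels == "NP"
        for i, gid in enumerate(matrix.gene_ids):
            a = matrix.abundances[i, np_mask]
            b = matrix.abundances[i, ~np_mask]
            if np.any(a == 0) and np.any(b == 0):
                continue
            ov = interval_overlap(a.min(), a.max(), b.min(), b.max())
            if ov >= 1 or ov >= cfg.overlap_threshold:
                continue
            ma, mb = a.mean(), b.mean()
            if min(ma, mb) == 0:
                fold = math.inf if max(ma, mb) > 0 else 1.0
            else:
                fold = max(ma, mb) / min(ma, mb)
            if fold < cfg.fold_min or ma == mb:
                continue
            expected.append((gid, UP if mb > ma else DOWN))
        assert list(zip(panel.gene_ids, panel.directions)) == expected


def test_direction_matches_mean_sign(default_panel):
    for entry in default_panel.entries:
        if entry.direction == UP:
            assert entry.stats.pe_mean > entry.stats.np_mean
        else:
            assert entry.stats.pe_mean < entry.stats.np_mean


def test_filter_rejects_mixed_windows():
    matrix = make_matrix([[1.0, 2.0]], ["NP", "PE"])
    matrix.window = np.array(["early", "mid"], dtype=object)
    with pytest.raises(ValidationError, match="window"):
        filter_indicators(matrix)


def test_empty_panel_is_warning_not_error(six_gene_matrix, caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        panel = filter_indicators(six_gene_matrix, FilterConfig(fold_min=100.0))
    assert panel.s == 0
    assert any("panel is empty" in r.message for r in caplog.records)


# --------------------------------------------------------------- sweep
def test_sweep_single_config_matches_filter(six_gene_matrix):
    table = threshold_sweep(six_gene_matrix, [FilterConfig()])
    assert len(table) == 1
    assert table["s"].iloc[0] == filter_indicators(six_gene_matrix).s


def test_sweep_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    matrix = random_matrix(rng, n_genes=50, n_np=8, n_pe=6)
    grid = [
        FilterConfig(overlap_threshold=o, fold_min=f)
        for o in (0.4, 0.6, 1.0)
        for f in (1.0, 1.5, 2.0)
    ]
    table = threshold_sweep(matrix, grid)
    # s never decreases when overlap_threshold rises or fold_min drops
    for f in (1.0, 1.5, 2.0):
        sizes = table[table.fold_min == f].sort_values("overlap_threshold")["s"]
        assert sizes.is_monotonic_increasing
    for o in (0.4, 0.6, 1.0):
        sizes = table[table.overlap_threshold == o].sort_values(
            "fold_min", ascending=False
        )["s"]
        assert sizes.is_monotonic_increasing


def test_sweep_extreme_fold_floor_empties_panel(six_gene_matrix):
    table = threshold_sweep(six_gene_matrix, [FilterConfig(fold_min=10.0)])
    assert table["s"].iloc[0] == 0


def test_sweep_empty_grid_rejected(six_gene_matrix):
    with pytest.raises(ValidationError):
        threshold_sweep(six_gene_matrix, [])
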