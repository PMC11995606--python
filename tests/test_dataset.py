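import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfpri import (
    GenConfig,
    ValidationError,
    build_dataset,
    envelope,
    generate_x,
    ground_truth_pri,
    pri,
    pri_of_matrix,
    probability_vectors,
)
from cfpri.dataset import to_channel_major, to_sample_major
from cfpri.filtration import DOWN, UP

from conftest import make_matrix, panel_from_groups


@pytest.fixture
def mixed_panel():
    """Three up and two down indicators with assorted ranges."""
    rng = np.random.default_rng(2)
    np_cols = [rng.uniform(1, 3, 6) for _ in range(3)] + [
        rng.uniform(10, 20, 6) for _ in range(2)
    ]
    pe_cols = [rng.uniform(4, 9, 5) for _ in range(3)] + [
        rng.uniform(2, 5, 5) for _ in range(2)
    ]
    return panel_from_groups(np_cols, pe_cols)


# ------------------------------------------------------------- envelope
def test_envelope_definition():
    panel = panel_from_groups([[1.0, 3.0]], [[2.0, 6.0]])
    assert envelope(panel).tolist() == [[1.0, 6.0]]


def test_envelope_degenerate_constant():
    panel = panel_from_groups([[5.0, 5.0]], [[5.0, 5.0, 6.0]])
    lo, hi = envelope(panel)[0]
    assert (lo, hi) == (5.0, 6.0)


def test_envelope_matches_concatenated_min_max(mixed_panel):
    env = envelope(mixed_panel)
    for i, e in enumerate(mixed_panel.entries):
        both = [e.stats.np_min, e.stats.np_max, e.stats.pe_min, e.stats.pe_max]
        assert env[i, 0] == min(both) and env[i, 1] == max(both)


# ------------------------------------------------------------ generate_x
def test_generate_constant_for_degenerate_envelope():
    # a truly degenerate envelope needs an explicit override, since panels
    # cannot carry tied group means
    panel = panel_from_groups([[1.0, 2.0]], [[3.0, 4.0]])
    x = generate_x(panel, 20, GenConfig(seed=0), envelopes=np.array([[5.0, 5.0]]))
    assert np.all(x == 5.0)


def test_generate_shapes_follow_requested_counts(mixed_panel):
    x = generate_x(mixed_panel, 100, GenConfig(seed=1))
    assert x.shape == (100, mixed_panel.s)


def test_generate_within_envelope_and_mean_near_midpoint(mixed_panel):
    cfg = GenConfig(seed=5)
    x = generate_x(mixed_panel, 10_000, cfg)
    env = envelope(mixed_panel)
    assert np.all(x >= env[:, 0]) and np.all(x <= env[:, 1])
    mid = env.mean(axis=1)
    sd = (env[:, 1] - env[:, 0]) * cfg.gaussian_sd_fraction
    se = sd / np.sqrt(10_000)
    assert np.all(np.abs(x.mean(axis=0) - mid) < 3 * se)


def test_generate_seed_determinism(mixed_panel):
    a = generate_x(mixed_panel, 500, GenConfig(seed=9))
    b = generate_x(mixed_panel, 500, GenConfig(seed=9))
    assert np.array_equal(a, b)
    c = generate_x(mixed_panel, 500, GenConfig(seed=10))
    assert not np.array_equal(a, c)


def test_generate_uniform_distribution_supported(mixed_panel):
    x = generate_x(mixed_panel, 1000, GenConfig(distribution="uniform", seed=3))
    env = envelope(mixed_panel)
    assert np.all(x >= env[:, 0]) and np.all(x <= env[:, 1])


# ---------------------------------------------------- probability_vectors
def test_probability_up_column_hand_values():
    panel = panel_from_groups([[1.0, 2.0]], [[3.0, 4.0]])
    y = probability_vectors(np.array([[1.0], [2.0], [4.0]]), panel)
    assert y[:, 0] == pytest.approx([0.0, 1.0 / 3.0, 1.0])


def test_probability_down_column_endpoints():
    panel = panel_from_groups([[10.0, 20.0]], [[1.0, 2.0]])
    assert panel.directions == [DOWN]
    x = np.array([[3.0], [15.0], [9.0]])
    y = probability_vectors(x, panel)
    assert y[x[:, 0].argmax(), 0] == 0.0
    assert y[x[:, 0].argmin(), 0] == 1.0


def test_probability_constant_column_is_half():
    panel = panel_from_groups([[1.0, 2.0]], [[3.0, 4.0]])
    y = probability_vectors(np.full((4, 1), 7.0), panel)
    assert np.all(y == 0.5)


def test_probability_matches_brute_force(mixed_panel):
    """Independent elementwise reimplementation of the min-max transform."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.uniform(0, 50, size=(5, mixed_panel.s))
        y = probability_vectors(x, mixed_panel)
        for i in range(mixed_panel.s):
            col = x[:, i]
            lo, hi = col.min(), col.max()
            for j in range(5):
                if mixed_panel.entries[i].direction == UP:
                    expected = (col[j] - lo) / (hi - lo)
                else:
                    expected = (hi - col[j]) / (hi - lo)
                assert y[j, i] == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=50)
@given(
    scale=st.floats(0.1, 50.0),
    shift=st.floats(-100.0, 100.0),
    seed=st.integers(0, 1000),
)
def test_probability_invariant_to_positive_affine_rescaling(scale, shift, seed):
    panel = panel_from_groups([[1.0, 2.0], [9.0, 11.0]], [[3.0, 4.0], [2.0, 4.0]])
    x = np.random.default_rng(seed).uniform(0, 10, size=(6, 2))
    x[0], x[1] = x.min(axis=0) - 1, x.max(axis=0) + 1  # ensure distinct extremes
    y1 = probability_vectors(x, panel)
    y2 = probability_vectors(scale * x + shift, panel)
    assert np.allclose(y1, y2, atol=1e-9)


def test_probability_shape_mismatch_rejected(mixed_panel):
    with pytest.raises(ValidationError):
        probability_vectors(np.zeros((3, mixed_panel.s + 1)), mixed_panel)


# ------------------------------------------------------------------ PRI
def test_pri_endpoints_and_average():
    assert pri(np.zeros(7)) == 0.0
    assert pri(np.ones(7)) == 1.0
    assert pri(np.array([0.0, 0.5, 1.0])) == 0.5


def test_pri_rejects_empty_and_out_of_range():
    with pytest.raises(ValidationError):
        pri(np.array([]))
    with pytest.raises(ValidationError):
        pri(np.array([0.5, 1.2]))


# ---------------------------------------------------------- build_dataset
def test_build_dataset_shapes_and_y_extremes(mixed_panel):
    ds = build_dataset(mixed_panel, GenConfig(seed=4), M=300, Q=50)
    assert ds.x_train.shape == (300, mixed_panel.s)
    assert ds.x_test.shape == (50, mixed_panel.s)
    assert ds.y_test.shape == (50, mixed_panel.s)
    # non-degenerate columns attain 0 and 1 at the observed extremes
    assert np.allclose(ds.y_train.min(axis=0), 0.0)
    assert np.allclose(ds.y_train.max(axis=0), 1.0)


def test_build_dataset_deterministic(mixed_panel):
    a = build_dataset(mixed_panel, GenConfig(seed=12), M=100, Q=20)
    b = build_dataset(mixed_panel, GenConfig(seed=12), M=100, Q=20)
    assert np.array_equal(a.x_train, b.x_train)
    assert np.array_equal(a.y_test, b.y_test)


def test_layout_round_trip(mixed_panel):
    ds = build_dataset(mixed_panel, GenConfig(seed=4), M=40, Q=10)
    cm = ds.as_layout("channel_major")
    assert cm.x_train.shape == (1, mixed_panel.s, 40)
    back = cm.as_layout("sample_major")
    assert np.array_equal(back.x_train, ds.x_train)
    assert np.array_equal(to_sample_major(to_channel_major(ds.x_test)), ds.x_test)


def test_dataset_save_load_round_trip(mixed_panel, tmp_path):
    ds = build_dataset(mixed_panel, GenConfig(seed=4), M=30, Q=8)
    ds.save(tmp_path / "ds")
    from cfpri import SyntheticDataset

    back = SyntheticDataset.load(tmp_path / "ds")
    assert np.array_equal(back.x_train, ds.x_train)
    assert np.array_equal(back.y_test, ds.y_test)
    assert back.panel.gene_ids == ds.panel.gene_ids


def test_real_fraction_envelope_subset(mixed_panel):
    """Envelopes fitted on a 30% subsample keep x inside the full envelope."""
    rng = np.random.default_rng(1)
    genes = [e.gene_id for e in mixed_panel.entries]
    x_real = rng.uniform(0, 30, size=(len(genes), 20))
    matrix = make_matrix(x_real, ["NP"] * 12 + ["PE"] * 8, gene_ids=genes)
    ds = build_dataset(
        mixed_panel, GenConfig(seed=2, real_fraction=0.3), M=200, Q=20,
        matrix=matrix,
    )
    # the subsample envelope is nested in the full data envelope
    assert ds.x_train.min() >= x_real.min() - 1e-12
    assert ds.x_train.max() <= x_real.max() + 1e-12


# ------------------------------------------------------- ground truth PRI
def test_ground_truth_extreme_sample_scores_one():
    # sample S3 sits at the up-gene max and the down-gene min
    matrix = make_matrix(
        [[1.0, 2.0, 3.0, 9.0], [8.0, 7.0, 5.0, 1.0]],
        ["NP", "NP", "PE", "PE"],
    )
    panel = panel_from_groups([[1.0, 2.0], [8.0, 7.0]], [[3.0, 9.0], [5.0, 1.0]])
    assert panel.directions == [UP, DOWN]
    result = ground_truth_pri(matrix, panel)
    assert result.pri_truth[3] == pytest.approx(1.0)


def test_ground_truth_separates_simulated_groups(default_cohort, default_panel):
    matrix, _ = default_cohort
    result = ground_truth_pri(matrix, default_panel)
    means = result.group_means()
    assert means["PE"] > means["NP"]


def test_ground_truth_missing_gene_is_named(toy_matrix):
    panel = panel_from_groups([[1.0, 2.0]], [[3.0, 4.0]], gene_ids=["ABSENT"])
    with pytest.raises(KeyError, match="ABSENT"):
        ground_truth_pri(toy_matrix, panel)
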