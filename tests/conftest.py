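import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests, no on-disk example database
settings.register_profile("ci", derandomize=True, database=None)
settings.load_profile("ci")

from cfpri import (
    CohortSpec,
    ExpressionMatrix,
    FilterConfig,
    IndicatorPanel,
    filter_indicators,
    simulate_cohort,
)
from cfpri.filtration import PanelEntry, stats_from_values, UP, DOWN


def make_matrix(abundances, labels, gene_ids=None, window="early"):
    abundances = np.asarray(abundances, dtype=float)
    g, n = abundances.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"G{i}" for i in range(g)],
        abundances=abundances,
        sample_ids=[f"S{j}" for j in range(n)],
        labels=np.asarray(labels, dtype=object),
        window=np.array([window] * n, dtype=object),
    )


def random_matrix(rng, n_genes=20, n_np=5, n_pe=4, zero_prob=0.1):
    """Random nonnegative matrix with occasional exact zeros."""
    x = rng.gamma(2.0, 10.0, size=(n_genes, n_np + n_pe))
    x[rng.random(x.shape) < zero_prob] = 0.0
    labels = ["NP"] * n_np + ["PE"] * n_pe
    return make_matrix(x, labels)


def panel_from_groups(np_cols, pe_cols, gene_ids=None):
    """Build an IndicatorPanel directly from per-gene group value arrays."""
    entries = []
    for i, (a, b) in enumerate(zip(np_cols, pe_cols)):
        gid = gene_ids[i] if gene_ids else f"G{i}"
        stats = stats_from_values(gid, np.asarray(a, float), np.asarray(b, float))
        if stats.pe_mean == stats.np_mean:
            raise ValueError("tied means have no direction; adjust the fixture")
        direction = UP if stats.pe_mean > stats.np_mean else DOWN
        entries.append(PanelEntry(gene_id=gid, direction=direction, stats=stats))
    return IndicatorPanel(entries=entries, window="early")


@pytest.fixture
def toy_matrix():
    """Two NP + two PE samples, three genes, all strictly positive."""
    return make_matrix(
        [[1.0, 3.0, 2.0, 6.0], [5.0, 5.0, 5.0, 5.0], [10.0, 20.0, 1.0, 2.0]],
        ["NP", "NP", "PE", "PE"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_panel(default_cohort):
    matrix, _ = default_cohort
    return filter_indicators(matrix, FilterConfig())
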