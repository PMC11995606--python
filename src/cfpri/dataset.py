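"""Synthetic training data and probability ground truth for PRI regression.

Training and validation matrices are generated indicator-by-indicator inside
each indicator's observed abundance envelope — the global [min, max] over
both diagnostic groups. The default generator is a truncated Gaussian
centred at the envelope midpoint with standard deviation range/6 (the
bounds sit at about three sigma); out-of-range draws are rejected and
redrawn. A uniform alternative is available.

Each generated expression matrix is paired with a per-indicator PE
probability matrix by direction-aware min-max normalisation over the matrix
being transformed: for an indicator whose mean abundance is higher in PE,
probability rises linearly from 0 at the column minimum to 1 at the column
maximum; for a down-regulated indicator the ramp is reversed. The
Preeclamptic Risk Index (PRI) of a sample is the arithmetic mean of its
probability vector, so 0 is the ideal normotensive value and 1 the ideal
preeclamptic value, with every indicator weighted equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .filtration import IndicatorPanel
from .io import ExpressionMatrix, ValidationError, write_panel, read_panel

logger = logging.getLogger(__name__)

SAMPLE_MAJOR = "sample_major"    # [rows, N]
CHANNEL_MAJOR = "channel_major"  # [1, N, rows]


@dataclass
class GenConfig:
    """Configuration of the range-constrained random generator.

    ``real_fraction`` < 1 fits the generation envelopes on a seeded random
    subset of the real samples (default 30%), leaving all real samples
    available as an untouched final evaluation set.
    """

    distribution: str = "truncated_gaussian"
    gaussian_sd_fraction: float = 1.0 / 6.0
    real_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in ("truncated_gaussian", "uniform"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        if self.gaussian_sd_fraction <= 0:
            raise ValidationError("gaussian_sd_fraction must be > 0")
        if not (0.0 <= self.real_fraction <= 1.0):
            raise ValidationError("real_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def envelope(panel: IndicatorPanel) -> np.ndarray:
    """Per-indicator global (lo, hi) over both groups, shape (N, 2)."""
    if panel.s == 0:
        raise ValidationError("envelope of an empty panel is undefined")
    out = np.empty((panel.s, 2), dtype=float)
    for i, e in enumerate(panel.entries):
        out[i, 0] = min(e.stats.np_min, e.stats.pe_min)
        out[i, 1] = max(e.stats.np_max, e.stats.pe_max)
    return out


def envelope_from_matrix(matrix: ExpressionMatrix, panel: IndicatorPanel) -> np.ndarray:
    """Envelopes recomputed from a (possibly subsampled) matrix."""
    sub = matrix.subset_genes(panel.gene_ids)
    lo = sub.abundances.min(axis=1)
    hi = sub.abundances.max(axis=1)
    return np.column_stack([lo, hi])


def generate_x(
    panel: IndicatorPanel,
    count: int,
    cfg: GenConfig | None = None,
    rng: np.random.Generator | None = None,
    envelopes: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a ``count x N`` expression matrix inside the panel envelopes.

    Columns are independent. The truncated Gaussian uses rejection
    sampling, so every value lies strictly inside its envelope; a
    degenerate envelope (lo == hi) yields a constant column.
    """
    cfg = cfg or GenConfig()
    if count < 1:
        raise ValidationError("count must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    env = envelope(panel) if envelopes is None else np.asarray(envelopes, float)
    if env.shape != (panel.s, 2):
        raise ValidationError(f"envelopes must have shape ({panel.s}, 2)")
    x = np.empty((count, panel.s), dtype=float)
    for i, (lo, hi) in enumerate(env):
        if hi < lo:
            raise ValidationError(f"envelope {i} inverted: ({lo}, {hi})")
        if hi == lo:
            x[:, i] = lo
            continue
        if cfg.distribution == "uniform":
            x[:, i] = rng.uniform(lo, hi, size=count)
        else:
            mean = 0.5 * (lo + hi)
            sd = (hi - lo) * cfg.gaussian_sd_fraction
            col = rng.normal(mean, sd, size=count)
            bad = (col < lo) | (col > hi)
            while np.any(bad):
                col[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = (col < lo) | (col > hi)
            x[:, i] = col
    return x


def probability_vectors(x: np.ndarray, panel: IndicatorPanel) -> np.ndarray:
    """Direction-aware min-max transform of each column of ``x`` to [0, 1].

    The min and max are taken over the matrix being transformed. A
    degenerate column (constant) is mapped to the uninformative value 0.5.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != panel.s:
        raise ValidationError(
            f"x has {x.shape[1] if x.ndim == 2 else '?'} columns for a "
            f"{panel.s}-indicator panel"
        )
    y = np.empty_like(x)
    up = panel.up_mask
    mn = x.min(axis=0)
    mx = x.max(axis=0)
    span = mx - mn
    degenerate = span == 0
    if np.any(degenerate):
        logger.info(
            "%d degenerate column(s) mapped to probability 0.5",
            int(degenerate.sum()),
        )
    for i in range(panel.s):
        if degenerate[i]:
            y[:, i] = 0.5
        elif up[i]:
            y[:, i] = (x[:, i] - mn[i]) / span[i]
        else:
            y[:, i] = (mx[i] - x[:, i]) / span[i]
    return y


def pri(y_row: np.ndarray) -> float:
    """PRI of one sample: the mean of its PE-probability vector."""
    y_row = np.asarray(y_row, dtype=float)
    if y_row.size == 0:
        raise ValidationError("PRI of an empty probability vector is undefined")
    if np.any(y_row < 0) or np.any(y_row > 1):
        raise ValidationError("probability values must lie in [0, 1]")
    return float(y_row.mean())


def pri_of_matrix(y: np.ndarray) -> np.ndarray:
    """Row-wise PRI for a samples x indicators probability matrix."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] == 0:
        raise ValidationError("probability matrix must be 2-D with >= 1 column")
    return y.mean(axis=1)


def to_channel_major(x: np.ndarray) -> np.ndarray:
    """Reshape ``[rows, N]`` to ``[1, N, rows]`` (lossless)."""
    return np.ascontiguousarray(x.T)[np.newaxis, :, :]


def to_sample_major(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_channel_major`."""
    if x.ndim != 3 or x.shape[0] != 1:
        raise ValidationError("channel-major layout must have shape [1, N, rows]")
    return np.ascontiguousarray(x[0].T)


@dataclass
class SyntheticDataset:
    """Generated training/validation matrices plus their probability truth."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    panel: IndicatorPanel
    gen_config: GenConfig
    generation_seed: int
    layout: str = SAMPLE_MAJOR

    def __post_init__(self) -> None:
        if self.layout not in (SAMPLE_MAJOR, CHANNEL_MAJOR):
            raise ValidationError(f"unknown layout {self.layout!r}")

    @property
    def N(self) -> int:
        return self.panel.s

    @property
    def M(self) -> int:
        return self.x_train.shape[0] if self.layout == SAMPLE_MAJOR else self.x_train.shape[2]

    @property
    def Q(self) -> int:
        return self.x_test.shape[0] if self.layout == SAMPLE_MAJOR else self.x_test.shape[2]

    def as_layout(self, layout: str) -> "SyntheticDataset":
        if layout == self.layout:
            return self
        convert = to_channel_major if layout == CHANNEL_MAJOR else to_sample_major
        return SyntheticDataset(
            x_train=convert(self.x_train),
            y_train=convert(self.y_train),
            x_test=convert(self.x_test),
            y_test=convert(self.y_test),
            panel=self.panel,
            gen_config=self.gen_config,
            generation_seed=self.generation_seed,
            layout=layout,
        )

    def save(self, directory: str | Path) -> None:
        """Store as delimited text matrices plus a JSON manifest."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ds = self.as_layout(SAMPLE_MAJOR)
        for name in ("x_train", "y_train", "x_test", "y_test"):
            arr = getattr(ds, name)
            pd.DataFrame(arr, columns=ds.panel.gene_ids).to_csv(
                directory / f"{name}.tsv", sep="\t", index=False,
                float_format="%.17g",
            )
        write_panel(ds.panel, directory / "panel.json")
        manifest = {
            "M": ds.M,
            "Q": ds.Q,
            "N": ds.N,
            "generation_seed": ds.generation_seed,
            "gen_config": ds.gen_config.to_dict(),
        }
        with open(directory / "dataset_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "SyntheticDataset":
        import json

        directory = Path(directory)
        with open(directory / "dataset_manifest.json") as fh:
            manifest = json.load(fh)
        panel = read_panel(directory / "panel.json")
        arrays = {
            name: pd.read_csv(
                directory / f"{name}.tsv", sep="\t", float_precision="round_trip"
            ).to_numpy(float)
            for name in ("x_train", "y_train", "x_test", "y_test")
        }
        return cls(
            panel=panel,
            gen_config=GenConfig(**manifest["gen_config"]),
            generation_seed=manifest["generation_seed"],
            **arrays,
        )


def build_dataset(
    panel: IndicatorPanel,
    cfg: GenConfig | None = None,
    M: int = 8000,
    Q: int = 500,
    matrix: ExpressionMatrix | None = None,
    include_real: bool = False,
) -> SyntheticDataset:
    """Generate paired train/validation datasets from one master seed.

    Independent substreams of the master seed drive the training draw, the
    validation draw and the real-sample subsetting, so a dataset is fully
    reproducible from (panel, config, M, Q).

    When ``matrix`` is given and ``real_fraction`` < 1, envelopes are fitted
    on a random fraction of the real samples instead of the panel's stored
    group stats; with ``include_real`` the subsampled real profiles are also
    appended as training rows (a mixed real/synthetic training set).
    """
    cfg = cfg or GenConfig()
    if panel.s == 0:
        raise ValidationError("cannot build a dataset from an empty panel")
    ss = np.random.SeedSequence(cfg.seed)
    train_seed, test_seed, subset_seed = ss.spawn(3)

    envelopes = None
    real_rows = None
    if matrix is not None and cfg.real_fraction < 1.0:
        sub_rng = np.random.default_rng(subset_seed)
        n = matrix.n_samples
        k = max(2, int(round(cfg.real_fraction * n)))
        cols = np.sort(sub_rng.choice(n, size=min(k, n), replace=False))
        sub = matrix.subset_genes(panel.gene_ids)
        sub_x = sub.abundances[:, cols]        # N x k
        envelopes = np.column_stack([sub_x.min(axis=1), sub_x.max(axis=1)])
        if include_real:
            real_rows = sub_x.T                # k x N
    elif matrix is not None:
        envelopes = envelope_from_matrix(matrix, panel)

    x_train = generate_x(
        panel, M, cfg, rng=np.random.default_rng(train_seed), envelopes=envelopes
    )
    if real_rows is not None:
        x_train = np.vstack([x_train, real_rows])
    x_test = generate_x(
        panel, Q, cfg, rng=np.random.default_rng(test_seed), envelopes=envelopes
    )
    return SyntheticDataset(
        x_train=x_train,
        y_train=probability_vectors(x_train, panel),
        x_test=x_test,
        y_test=probability_vectors(x_test, panel),
        panel=panel,
        gen_config=cfg,
        generation_seed=cfg.seed,
    )


@dataclass
class PRIResult:
    """Per-sample PRI values (ground truth and, once predicted, the model's)."""

    sample_ids: list[str]
    labels: np.ndarray
    window: str
    pri_truth: np.ndarray
    pri_pred: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pri_truth = np.asarray(self.pri_truth, dtype=float)
        if np.any((self.pri_truth < 0) | (self.pri_truth > 1)):
            raise ValidationError("PRI values must lie in [0, 1]")
        if self.pri_pred is not None:
            self.pri_pred = np.asarray(self.pri_pred, dtype=float)
            if np.any((self.pri_pred < 0) | (self.pri_pred > 1)):
                raise ValidationError("predicted PRI values must lie in [0, 1]")

    def group_means(self, which: str = "truth") -> dict[str, float]:
        values = self.pri_truth if which == "truth" else self.pri_pred
        if values is None:
            raise ValidationError("no predicted PRI available")
        return {
            label: float(values[self.labels == label].mean())
            for label in ("NP", "PE")
            if np.any(self.labels == label)
        }

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": self.sample_ids,
            "label": self.labels,
            "pri_truth": self.pri_truth,
        }
        if self.pri_pred is not None:
            data["pri_pred"] = self.pri_pred
        return pd.DataFrame(data)


def ground_truth_pri(matrix: ExpressionMatrix, panel: IndicatorPanel) -> PRIResult:
    """Calculated PRI: the direction-aware min-max transform applied to the
    observed expression of the panel genes, averaged per sample.

    The min/max are those of the real data itself, so the most extreme
    sample per indicator anchors the probability at exactly 0 or 1.
    """
    windows = set(matrix.window)
    if len(windows) > 1:
        raise ValidationError("matrix mixes gestational windows")
    if windows and panel.window not in windows:
        raise ValidationError(
            f"panel window {panel.window!r} does not match matrix window "
            f"{sorted(windows)}"
        )
    sub = matrix.subset_genes(panel.gene_ids)   # raises naming missing genes
    x = sub.abundances.T                         # samples x N
    y = probability_vectors(x, panel)
    return PRIResult(
        sample_ids=list(matrix.sample_ids),
        labels=matrix.labels,
        window=panel.window,
        pri_truth=pri_of_matrix(y),
    )
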