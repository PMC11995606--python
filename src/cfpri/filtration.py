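"""Rule-based selection of cfRNA indicators separating PE from NP samples.

A gene qualifies as a preeclampsia indicator when its expression ranges in
the two diagnostic groups are sufficiently distinct. Four rules are applied
to per-gene group statistics:

1. genes whose abundance contains zeros in *both* groups are removed (such
   a gene can never shift the risk index one way or the other);
2. genes whose NP and PE ranges overlap completely are removed;
3. the range overlap rate must fall below a threshold (default 0.6);
4. the ratio of group means (fold) must reach a minimum (default 1.5),
   optionally capped by a maximum.

Overlap rate is the Szymkiewicz-Simpson coefficient on intervals:
intersection length divided by the *smaller* range length, so a range fully
nested inside the other counts as 100% overlap.

Each surviving gene is assigned a direction: ``up_in_PE`` when its mean
abundance is higher in the PE group, ``down_in_PE`` otherwise. Genes with
exactly equal group means have no defined direction and are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

UP = "up_in_PE"
DOWN = "down_in_PE"

RULE_ZERO = "rule1_zero_abundance"
RULE_FULL_OVERLAP = "rule2_full_overlap"
RULE_OVERLAP = "rule3_overlap_threshold"
RULE_FOLD = "rule4_fold_change"


def interval_overlap(a_min: float, a_max: float, b_min: float, b_max: float) -> float:
    """Overlap rate of two closed intervals, in [0, 1].

    Defined as intersection length / min(length a, length b). Degenerate
    (zero-length) intervals are handled by membership: two coincident points
    overlap fully, a point inside the other interval overlaps fully, and
    disjoint configurations score 0.
    """
    if a_min > a_max or b_min > b_max:
        raise ValidationError(
            f"inverted interval: [{a_min}, {a_max}] vs [{b_min}, {b_max}]"
        )
    len_a = a_max - a_min
    len_b = b_max - b_min
    if len_a == 0 and len_b == 0:
        return 1.0 if a_min == b_min else 0.0
    if len_a == 0:
        return 1.0 if b_min <= a_min <= b_max else 0.0
    if len_b == 0:
        return 1.0 if a_min <= b_min <= a_max else 0.0
    inter = min(a_max, b_max) - max(a_min, b_min)
    if inter <= 0:
        return 0.0
    return inter / min(len_a, len_b)


@dataclass
class GeneGroupStats:
    """Per-gene summary statistics for the NP and PE groups."""

    gene_id: str
    np_min: float
    np_max: float
    np_mean: float
    pe_min: float
    pe_max: float
    pe_mean: float
    np_has_zero: bool
    pe_has_zero: bool
    overlap_rate: float
    fold: float

    def __post_init__(self) -> None:
        if not (self.np_min <= self.np_mean <= self.np_max):
            raise ValidationError(f"{self.gene_id}: NP min/mean/max not ordered")
        if not (self.pe_min <= self.pe_mean <= self.pe_max):
            raise ValidationError(f"{self.gene_id}: PE min/mean/max not ordered")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise ValidationError(f"{self.gene_id}: overlap_rate outside [0, 1]")
        if not (self.fold >= 1.0):
            raise ValidationError(f"{self.gene_id}: fold must be >= 1")

    @property
    def all_zero(self) -> bool:
        return (
            self.np_min == self.np_max == 0.0 and self.pe_min == self.pe_max == 0.0
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fold"] = "inf" if math.isinf(self.fold) else self.fold
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneGroupStats":
        d = dict(d)
        if d.get("fold") == "inf":
            d["fold"] = math.inf
        return cls(**d)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Larger group mean over smaller; 1 for two zero means, +inf when only
    the smaller mean is zero."""
    lo, hi = sorted((mean_a, mean_b))
    if hi == 0.0:
        return 1.0
    if lo == 0.0:
        return math.inf
    return hi / lo


def gene_stats(matrix: ExpressionMatrix, gene_id: str) -> GeneGroupStats:
    """Exact group-wise min/max/mean, zero flags, overlap rate and fold."""
    matrix.require_both_groups()
    row = matrix.gene_row(gene_id)
    np_vals = row[matrix.group_columns("NP")]
    pe_vals = row[matrix.group_columns("PE")]
    return stats_from_values(gene_id, np_vals, pe_vals)


def stats_from_values(
    gene_id: str, np_vals: np.ndarray, pe_vals: np.ndarray
) -> GeneGroupStats:
    np_vals = np.asarray(np_vals, dtype=float)
    pe_vals = np.asarray(pe_vals, dtype=float)
    if np_vals.size == 0 or pe_vals.size == 0:
        raise ValidationError(f"{gene_id}: both groups must be non-empty")
    np_min, np_max = float(np_vals.min()), float(np_vals.max())
    pe_min, pe_max = float(pe_vals.min()), float(pe_vals.max())
    np_mean, pe_mean = float(np_vals.mean()), float(pe_vals.mean())
    return GeneGroupStats(
        gene_id=gene_id,
        np_min=np_min,
        np_max=np_max,
        np_mean=np_mean,
        pe_min=pe_min,
        pe_max=pe_max,
        pe_mean=pe_mean,
        np_has_zero=bool(np.any(np_vals == 0.0)),
        pe_has_zero=bool(np.any(pe_vals == 0.0)),
        overlap_rate=interval_overlap(np_min, np_max, pe_min, pe_max),
        fold=fold_change(np_mean, pe_mean),
    )


@dataclass
class FilterConfig:
    """Thresholds for the four selection rules.

    ``zero_rule`` selects the reading of rule 1: ``both_groups_contain_zero``
    drops any gene with at least one zero in each group (the literal rule);
    ``all_zero`` drops only genes that are identically zero everywhere.
    """

    overlap_threshold: float = 0.6
    fold_min: float = 1.5
    fold_max: float | None = None
    zero_rule: str = "both_groups_contain_zero"

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValidationError("overlap_threshold must be in (0, 1]")
        if self.fold_min < 1.0:
            raise ValidationError("fold_min must be >= 1")
        if self.fold_max is not None and self.fold_max < self.fold_min:
            raise ValidationError("fold_max must be >= fold_min")
        if self.zero_rule not in ("both_groups_contain_zero", "all_zero"):
            raise ValidationError(f"unknown zero_rule {self.zero_rule!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


def apply_rules(
    stats: GeneGroupStats, cfg: FilterConfig
) -> tuple[bool, list[str]]:
    """Evaluate all four rules; returns (passed, list of violated rules)."""
    failed: list[str] = []
    if cfg.zero_rule == "both_groups_contain_zero":
        if stats.np_has_zero and stats.pe_has_zero:
            failed.append(RULE_ZERO)
    else:  # all_zero
        if stats.all_zero:
            failed.append(RULE_ZERO)
    if stats.overlap_rate >= 1.0:
        failed.append(RULE_FULL_OVERLAP)
    if not (stats.overlap_rate < cfg.overlap_threshold):
        failed.append(RULE_OVERLAP)
    fold_ok = stats.fold >= cfg.fold_min
    if cfg.fold_max is not None:
        fold_ok = fold_ok and stats.fold <= cfg.fold_max
    if not fold_ok:
        failed.append(RULE_FOLD)
    return (len(failed) == 0, failed)


@dataclass
class PanelEntry:
    gene_id: str
    direction: str
    stats: GeneGroupStats

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValidationError(f"unknown direction {self.direction!r}")
        consistent = (
            self.stats.pe_mean > self.stats.np_mean
            if self.direction == UP
            else self.stats.pe_mean < self.stats.np_mean
        )
        if not consistent:
            raise ValidationError(
                f"{self.gene_id}: direction {self.direction} inconsistent with "
                f"group means (NP {self.stats.np_mean}, PE {self.stats.pe_mean})"
            )


@dataclass
class IndicatorPanel:
    """Ordered set of selected cfRNA indicators with stats and directions."""

    entries: list[PanelEntry]
    window: str
    config: FilterConfig = field(default_factory=FilterConfig)

    @property
    def s(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    @property
    def directions(self) -> list[str]:
        return [e.direction for e in self.entries]

    @property
    def up_mask(self) -> np.ndarray:
        return np.array([e.direction == UP for e in self.entries])

    def __len__(self) -> int:
        return self.s

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "config": self.config.to_dict(),
            "n_indicators": self.s,
            "entries": [
                {
                    "gene_id": e.gene_id,
                    "direction": e.direction,
                    "stats": e.stats.to_dict(),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndicatorPanel":
        try:
            entries = [
                PanelEntry(
                    gene_id=e["gene_id"],
                    direction=e["direction"],
                    stats=GeneGroupStats.from_dict(e["stats"]),
                )
                for e in d["entries"]
            ]
            return cls(
                entries=entries,
                window=d["window"],
                config=FilterConfig.from_dict(d["config"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed panel record: {exc}") from exc


def filter_indicators(
    matrix: ExpressionMatrix, cfg: FilterConfig | None = None, window: str | None = None
) -> IndicatorPanel:
    """Apply the four rules to every gene, preserving input gene order.

    The matrix must hold samples from a single gestational window; pass
    ``window`` explicitly when the matrix metadata is heterogeneous by
    mistake — a mixed-window matrix is rejected.
    """
    cfg = cfg or FilterConfig()
    matrix.require_both_groups()
    windows = set(matrix.window)
    if len(windows) > 1:
        raise ValidationError(
            f"matrix mixes gestational windows {sorted(windows)}; "
            "restrict to one window before filtering"
        )
    window = window or next(iter(windows))

    np_mask = matrix.group_columns("NP")
    pe_mask = matrix.group_columns("PE")
    entries: list[PanelEntry] = []
    n_ties = 0
    for i, gene_id in enumerate(matrix.gene_ids):
        stats = stats_from_values(
            gene_id, matrix.abundances[i, np_mask], matrix.abundances[i, pe_mask]
        )
        passed, _ = apply_rules(stats, cfg)
        if not passed:
            continue
        if stats.pe_mean == stats.np_mean:
            n_ties += 1
            logger.info(
                "gene %s passed rules but has equal group means; "
                "direction undefined, excluded",
                gene_id,
            )
            continue
        direction = UP if stats.pe_mean > stats.np_mean else DOWN
        entries.append(PanelEntry(gene_id=gene_id, direction=direction, stats=stats))
    if not entries:
        logger.warning(
            "no gene passed the selection rules (overlap<%.3g, fold>=%.3g); "
            "panel is empty",
            cfg.overlap_threshold,
            cfg.fold_min,
        )
    return IndicatorPanel(entries=entries, window=window, config=cfg)


def threshold_sweep(
    matrix: ExpressionMatrix, grid: Sequence[FilterConfig]
) -> pd.DataFrame:
    """Panel size for each configuration in a grid; one row per config."""
    if len(grid) == 0:
        raise ValidationError("threshold sweep needs a non-empty grid")
    rows = []
    for cfg in grid:
        panel = filter_indicators(matrix, cfg)
        rows.append(
            {
                "overlap_threshold": cfg.overlap_threshold,
                "fold_min": cfg.fold_min,
                "fold_max": cfg.fold_max,
                "zero_rule": cfg.zero_rule,
                "s": panel.s,
            }
        )
    return pd.DataFrame(rows)
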