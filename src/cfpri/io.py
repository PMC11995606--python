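"""Reading and writing expression matrices, sample sheets and indicator panels.

The on-disk formats are deliberately plain: delimited text for matrices
(first column = gene identifier, header row = sample identifiers), a TSV
sample sheet mapping each sample to its diagnostic label (``NP`` or ``PE``)
and gestational window (``early`` for samples drawn at or before 12
gestational weeks, ``mid`` for 13-20 weeks), and JSON for indicator panels
and reports so that artifacts diff cleanly under version control.

Abundance values are treated as already normalised and cleaned upstream;
no library-size or other normalisation is applied here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("NP", "PE")
WINDOWS = ("early", "mid")

# Aliases accepted in sample sheets for the two gestational windows.
_WINDOW_ALIASES: Mapping[str, str] = {
    "early": "early",
    "mid": "mid",
    "<=12": "early",
    "le12": "early",
    "<=12 gws": "early",
    "13-20": "mid",
    "13-20 gws": "mid",
    "13_20": "mid",
}


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


def _normalise_window(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _WINDOW_ALIASES:
        raise ValidationError(
            f"unrecognised gestational window {value!r}; expected one of "
            f"{sorted(set(_WINDOW_ALIASES))}"
        )
    return _WINDOW_ALIASES[key]


@dataclass
class ExpressionMatrix:
    """A genes x samples nonnegative cfRNA abundance matrix with metadata.

    Parameters
    ----------
    gene_ids
        Stable gene identifiers (ENSEMBL-style strings), unique.
    abundances
        ``(n_genes, n_samples)`` nonnegative, finite array.
    sample_ids
        Unique sample identifiers, one per column.
    labels
        Per-sample diagnostic class, ``"NP"`` or ``"PE"``.
    window
        Per-sample gestational window, ``"early"`` or ``"mid"``.
    """

    gene_ids: list[str]
    abundances: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray
    window: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.window = np.asarray(self.window, dtype=object)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        g, n = self.abundances.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != g:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if self.labels.shape != (n,) or self.window.shape != (n,):
            raise ValidationError("labels/window length must match sample count")
        bad_label = set(self.labels) - set(LABELS)
        if bad_label:
            raise ValidationError(f"unknown labels {sorted(bad_label)}")
        bad_window = set(self.window) - set(WINDOWS)
        if bad_window:
            raise ValidationError(f"unknown windows {sorted(bad_window)}")
        if not np.all(np.isfinite(self.abundances)):
            i, j = np.argwhere(~np.isfinite(self.abundances))[0]
            raise ValidationError(
                f"non-finite abundance for gene {self.gene_ids[i]!r} "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.abundances < 0):
            i, j = np.argwhere(self.abundances < 0)[0]
            raise ValidationError(
                f"negative abundance for gene {self.gene_ids[i]!r} "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- accessors ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    def group_columns(self, label: str) -> np.ndarray:
        """Boolean mask over samples for one diagnostic class."""
        if label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
        return self.labels == label

    def require_both_groups(self) -> None:
        for label in LABELS:
            if not np.any(self.labels == label):
                raise ValidationError(
                    f"group-wise operation requires at least one {label} sample"
                )

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None
        return self.abundances[idx]

    def subset_window(self, window: str) -> "ExpressionMatrix":
        """Restrict to samples drawn in one gestational window."""
        if window not in WINDOWS:
            raise ValidationError(f"window must be one of {WINDOWS}")
        mask = self.window == window
        if not np.any(mask):
            raise ValidationError(f"no samples in window {window!r}")
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            abundances=self.abundances[:, mask],
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            labels=self.labels[mask],
            window=self.window[mask],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            abundances=self.abundances[rows],
            sample_ids=list(self.sample_ids),
            labels=self.labels,
            window=self.window,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=self.gene_ids, columns=self.sample_ids
        )


@dataclass
class SampleSheet:
    """Per-sample metadata: label, gestational window, free-form covariates."""

    sample_ids: list[str]
    labels: list[str]
    window: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in sheet")
        if len(self.labels) != n or len(self.window) != n:
            raise ValidationError("sheet columns must have equal length")
        self.labels = [str(x).strip().upper() for x in self.labels]
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValidationError(f"sheet labels must be NP or PE, got {sorted(bad)}")
        self.window = [_normalise_window(w) for w in self.window]

    def lookup(self, sample_id: str) -> tuple[str, str]:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(
                f"sample {sample_id!r} missing from sample sheet"
            ) from None
        return self.labels[i], self.window[i]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV/CSV sample sheet with columns sample_id, label, window."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    required = {"sample_id", "label", "window"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
    covars = df.drop(columns=list(required))
    return SampleSheet(
        sample_ids=df["sample_id"].tolist(),
        labels=df["label"].tolist(),
        window=df["window"].tolist(),
        covariates=covars if covars.shape[1] else None,
    )


def write_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": sheet.sample_ids,
            "label": sheet.labels,
            "window": sheet.window,
        }
    )
    if sheet.covariates is not None:
        df = pd.concat([df, sheet.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Read a delimited expression matrix plus its companion sample sheet.

    Gene rows, sample columns; the first column carries gene identifiers.
    Labels and windows are assigned strictly by sample id through the sheet,
    never by column position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    sheet = read_sheet(sheet_path)
    labels, windows = [], []
    for sample in df.columns:
        label, window = sheet.lookup(str(sample))
        labels.append(label)
        windows.append(window)
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=df.index.tolist(),
        abundances=values,
        sample_ids=[str(c) for c in df.columns],
        labels=np.array(labels, dtype=object),
        window=np.array(windows, dtype=object),
    )


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the abundance matrix as TSV with full float precision."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_series_matrix(path: str | Path, sheet_path: str | Path) -> ExpressionMatrix:
    """Thin adapter for GEO series-matrix text files.

    Series-matrix files are plain TSV tables bracketed by ``!``-prefixed
    metadata lines and ``!series_matrix_table_begin``/``_end`` sentinels.
    Metadata is ignored; labels come from the companion sheet as usual.
    """
    path = Path(path)
    rows: list[str] = []
    inside = False
    with open(path) as fh:
        for line in fh:
            low = line.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if low.startswith("!series_matrix_table_end"):
                break
            if inside and line.strip() and not line.startswith("!"):
                rows.append(line)
    if not rows:
        raise ValidationError(f"no series-matrix table found in {path}")
    import io as _io

    buffer = _io.StringIO("".join(rows))
    df = pd.read_csv(buffer, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    sheet = read_sheet(sheet_path)
    labels, windows = [], []
    for sample in df.columns:
        label, window = sheet.lookup(sample)
        labels.append(label)
        windows.append(window)
    return ExpressionMatrix(
        gene_ids=df.index.tolist(),
        abundances=df.to_numpy(dtype=float),
        sample_ids=list(df.columns),
        labels=np.array(labels, dtype=object),
        window=np.array(windows, dtype=object),
    )


# ---------------------------------------------------------------------------
# Indicator panel serialisation (JSON)
# ---------------------------------------------------------------------------

def write_panel(panel, path: str | Path) -> None:
    """Serialise an :class:`~cfpri.filtration.IndicatorPanel` to JSON."""
    payload = panel.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_panel(path: str | Path):
    """Read an indicator panel written by :func:`write_panel`."""
    from .filtration import IndicatorPanel

    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(
            f"malformed panel file {path}: line {exc.lineno}: {exc.msg}"
        ) from exc
    return IndicatorPanel.from_dict(payload)


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
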