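"""Model/Results front end for the full PRI pipeline.

:class:`PreeclampsiaRiskModel` is constructed from an expression matrix
(or a DataFrame plus labels) restricted to one gestational window; its
``fit`` method runs indicator selection, synthetic-dataset generation and
network training, and returns a :class:`PRIRiskResults` carrying the panel,
the fitted network, per-sample PRI estimates and the evaluation report,
with a ``summary()`` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenConfig, SyntheticDataset, build_dataset, ground_truth_pri
from .evaluation import EvalReport, evaluate
from .filtration import FilterConfig, IndicatorPanel, filter_indicators
from .io import ExpressionMatrix, ValidationError
from .nn import NetConfig, TrainConfig, TrainedModel, build_model, train


class PreeclampsiaRiskModel:
    """Continuous preeclampsia-risk model over a cfRNA expression cohort.

    Parameters
    ----------
    matrix
        Expression matrix restricted to a single gestational window, with
        NP and PE samples.
    filter_config, gen_config, net_config, train_config
        Stage configurations; defaults follow the reference pipeline
        (overlap < 0.6, fold >= 1.5; truncated-Gaussian generation;
        pyramid-pooling network; Adam on MAE).
    M, Q
        Generated training and validation sample counts.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        filter_config: FilterConfig | None = None,
        gen_config: GenConfig | None = None,
        net_config: NetConfig | None = None,
        train_config: TrainConfig | None = None,
        M: int = 8000,
        Q: int = 500,
    ) -> None:
        matrix.require_both_groups()
        if len(set(matrix.window)) > 1:
            raise ValidationError(
                "restrict the matrix to one gestational window "
                "(ExpressionMatrix.subset_window) before modelling"
            )
        self.matrix = matrix
        self.filter_config = filter_config or FilterConfig()
        self.gen_config = gen_config
        self.net_config = net_config or NetConfig()
        self.train_config = train_config
        self.M = M
        self.Q = Q

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        labels,
        window: str = "early",
        **kwargs,
    ) -> "PreeclampsiaRiskModel":
        """Build from a genes x samples DataFrame and per-sample labels."""
        labels = np.asarray(labels, dtype=object)
        matrix = ExpressionMatrix(
            gene_ids=[str(g) for g in frame.index],
            abundances=frame.to_numpy(dtype=float),
            sample_ids=[str(c) for c in frame.columns],
            labels=labels,
            window=np.array([window] * frame.shape[1], dtype=object),
        )
        return cls(matrix, **kwargs)

    def fit(self, seed: int = 0) -> "PRIRiskResults":
        """Select indicators, generate data, train the network, evaluate.

        One master seed drives independent substreams for generation and
        network training, so a fit is reproducible end to end.
        """
        panel = filter_indicators(self.matrix, self.filter_config)
        if panel.s == 0:
            raise ValidationError(
                "no indicator passed the selection rules; relax the filter "
                "thresholds (see threshold_sweep) before fitting"
            )
        ss = np.random.SeedSequence(seed)
        gen_seed, net_seed = (
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)
        )
        gen_config = self.gen_config or GenConfig(seed=gen_seed)
        if self.gen_config is not None:
            gen_config = self.gen_config
        train_config = self.train_config or TrainConfig(seed=net_seed)

        dataset = build_dataset(
            panel, gen_config, M=self.M, Q=self.Q, matrix=self.matrix
        )
        network = build_model(self.net_config, panel.s, seed=train_config.seed)
        trained = train(network, dataset, train_config)

        truth = ground_truth_pri(self.matrix, panel)
        x_real = self.matrix.subset_genes(panel.gene_ids).abundances.T
        pri_pred = trained.predict_pri(x_real)
        report = evaluate(
            labels=self.matrix.labels,
            pri_truth=truth.pri_truth,
            pri_pred=pri_pred,
            y_truth=dataset.y_test,
            y_pred=trained.predict(dataset.x_test),
            sample_ids=list(self.matrix.sample_ids),
            arch=self.net_config.arch,
        )
        return PRIRiskResults(
            model=self,
            panel=panel,
            dataset=dataset,
            trained=trained,
            pri_truth=truth.pri_truth,
            pri_pred=pri_pred,
            report=report,
            seed=seed,
        )


@dataclass
class PRIRiskResults:
    """Fitted-pipeline results: panel, network, PRI estimates, diagnostics."""

    model: PreeclampsiaRiskModel
    panel: IndicatorPanel
    dataset: SyntheticDataset
    trained: TrainedModel
    pri_truth: np.ndarray
    pri_pred: np.ndarray
    report: EvalReport
    seed: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-indicator PE probabilities for new samples x indicators."""
        return self.trained.predict(x)

    def predict_pri(self, x: np.ndarray) -> np.ndarray:
        """PRI for new samples (rows aligned with the panel's genes)."""
        return self.trained.predict_pri(x)

    def pri_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.model.matrix.sample_ids,
                "label": self.model.matrix.labels,
                "pri_calculated": self.pri_truth,
                "pri_predicted": self.pri_pred,
            }
        )

    def summary(self) -> str:
        rep = self.report
        labels = self.model.matrix.labels
        lines = [
            "Preeclamptic Risk Index — pipeline fit",
            "=" * 54,
            f"window:                {self.panel.window}",
            f"samples (NP/PE):       {int((labels == 'NP').sum())}/"
            f"{int((labels == 'PE').sum())}",
            f"indicators selected:   {self.panel.s}"
            f"  ({sum(self.panel.up_mask)} up, "
            f"{self.panel.s - int(sum(self.panel.up_mask))} down in PE)",
            f"architecture:          {self.trained.net_config.arch}"
            f"  ({self.trained.network.n_parameters()} parameters)",
            f"training:              M={self.dataset.M}, Q={self.dataset.Q}, "
            f"epochs={self.trained.train_config.epochs}, seed={self.seed}",
            "-" * 54,
            f"final validation MAE:  {self.trained.history['val_loss'][-1]:.4f}",
        ]
        if rep.vector_mae is not None:
            lines.append(f"vector MAE:            {rep.vector_mae:.4f}")
        truth_np = float(self.pri_truth[labels == "NP"].mean())
        truth_pe = float(self.pri_truth[labels == "PE"].mean())
        lines += [
            f"calculated PRI means:  NP {truth_np:.3f} / PE {truth_pe:.3f}",
            f"predicted PRI means:   NP {rep.group_means.get('NP', float('nan')):.3f}"
            f" / PE {rep.group_means.get('PE', float('nan')):.3f}",
            f"PRI errors:            max {rep.max_abs_error:.3f}, "
            f"PV {rep.pv_error:.3f}, mean {rep.mean_abs_error:.3f}",
            f"classification:        AUC {rep.auc:.3f}, "
            f"precision {rep.precision:.3f}, recall {rep.recall:.3f}, "
            f"F1 {rep.f1:.3f} @ threshold {rep.threshold:.3f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_pri(self, ax=None):
        """Scatter of calculated vs predicted PRI by sample index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(len(self.pri_truth))
        ax.plot(idx, self.pri_truth, "o", label="calculated PRI", alpha=0.7)
        ax.plot(idx, self.pri_pred, "x", label="predicted PRI", alpha=0.7)
        ax.set_xlabel("sample index")
        ax.set_ylabel("PRI")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax
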