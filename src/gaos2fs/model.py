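"""Model/Results facade over the streaming selection pipeline.

``OnlineFeatureSelector`` is constructed from data (a stream of sparse
feature columns, or a pandas DataFrame with NaN for missing cells) plus a
label vector; ``fit()`` runs the buffered impute -> GA-select -> prune cycle
and returns a :class:`FeatureSelectionResults` carrying the selected set,
per-block diagnostics and a ``summary()`` table.

``LatentFactorImputer`` exposes the completion step on its own for users who
only want the matrix-completion half.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import lfa as _lfa
from .bench import cross_validated_accuracy
from .fitness import ClassifierSpec
from .stream import (
    SelectionState,
    SparseFeatureBlock,
    StreamConfig,
    buffer_stream,
    process_stream,
)

__all__ = [
    "OnlineFeatureSelector",
    "FeatureSelectionResults",
    "LatentFactorImputer",
    "LatentFactorResults",
]


class OnlineFeatureSelector:
    """Online sparse streaming feature selection model.

    Parameters
    ----------
    stream : sequence of SparseFeatureBlock, or of (id, column) pairs
        The feature stream.  Columns may contain NaN for missing entries;
        (id, column) pairs are buffered into blocks of ``config.buffer_width``.
    labels : length-M sequence
        Class label per sample; at least two distinct classes.
    config : StreamConfig, optional
        All pipeline parameters and the master seed.
    """

    def __init__(self, stream, labels, config: StreamConfig | None = None):
        self.config = config or StreamConfig()
        stream = list(stream)
        if stream and not isinstance(stream[0], SparseFeatureBlock):
            stream = buffer_stream(stream, self.config.buffer_width)
        self.blocks = stream
        self.labels = np.asarray(labels)

    @classmethod
    def from_dataframe(cls, df, labels, config: StreamConfig | None = None):
        """Build from a samples x features DataFrame (NaN = missing).

        Columns stream in the DataFrame's column order.
        """
        cols = [(str(c), df[c].to_numpy(dtype=float)) for c in df.columns]
        return cls(cols, labels, config)

    def fit(self) -> "FeatureSelectionResults":
        state = process_stream(self.blocks, self.labels, self.config)
        return FeatureSelectionResults(self, state)


class FeatureSelectionResults:
    """Fitted selection state with diagnostics and reporting helpers."""

    def __init__(self, model: OnlineFeatureSelector, state: SelectionState):
        self.model = model
        self.state = state

    @property
    def selected_ids(self) -> list:
        return list(self.state.selected_ids)

    @property
    def n_selected(self) -> int:
        return len(self.state.selected_ids)

    @property
    def convergence_curves(self) -> list[np.ndarray]:
        return [r.ga_curve for r in self.state.records]

    def selected_matrix(self) -> np.ndarray:
        """Completed values of the selected features (samples x selected)."""
        return self.state.selected_matrix()

    def accuracy(self, spec: ClassifierSpec | None = None, folds: int = 5,
                 repeats: int = 10, seed: int = 0) -> tuple[float, float]:
        """Repeated stratified CV accuracy (percent) of the selected subset."""
        if self.n_selected == 0:
            raise ValueError("no features selected; accuracy undefined")
        return cross_validated_accuracy(
            self.selected_matrix(), self.model.labels, spec,
            folds=folds, repeats=repeats, seed=seed,
        )

    def summary(self) -> str:
        """Human-readable per-block account of the run."""
        cfg = self.model.config
        lines = [
            "Online sparse streaming feature selection",
            "=" * 57,
            f"samples: {self.model.labels.shape[0]}   "
            f"features seen: {self.state.total_features_seen}   "
            f"blocks: {len(self.state.records)}",
            f"buffer width H: {cfg.buffer_width}   latent rank L: {cfg.lfa.L}   "
            f"GA pop/iters: {cfg.ga.population_size}/{cfg.ga.max_iterations}",
            f"classifier: {cfg.classifier.kind}   alpha(CI): {cfg.redundancy_alpha}   "
            f"seed: {cfg.master_seed}",
            "-" * 57,
            f"{'block':>5} {'rho':>6} {'pool':>5} {'GA sel':>7} "
            f"{'dropped':>8} {'pruned':>7} {'|S_t|':>6}",
        ]
        for r in self.state.records:
            lines.append(
                f"{r.block_index:>5} {r.missing_rate:>6.3f} {r.candidate_count:>5} "
                f"{len(r.ga_selected):>7} {len(r.relevance_dropped):>8} "
                f"{len(r.prune_removed):>7} {len(r.selected_after):>6}"
            )
        lines.append("-" * 57)
        lines.append(f"final selected set ({self.n_selected}): "
                     + ", ".join(str(i) for i in self.selected_ids))
        return "\n".join(lines)


class LatentFactorImputer:
    """Rank-L latent-factor completion model for one sparse block."""

    def __init__(self, block: SparseFeatureBlock, params: _lfa.LfaParams | None = None):
        self.block = block
        self.params = params or _lfa.LfaParams()

    def fit(self) -> "LatentFactorResults":
        factors, losses = _lfa.train(self.block, self.params)
        return LatentFactorResults(self, factors, losses)


class LatentFactorResults:
    """Trained factors, the loss trajectory, and completion."""

    def __init__(self, model: LatentFactorImputer, factors: _lfa.FactorPair,
                 loss_curve: np.ndarray):
        self.model = model
        self.factors = factors
        self.loss_curve = loss_curve

    def complete(self) -> np.ndarray:
        """Dense completion; observed cells pass through unchanged."""
        return _lfa.complete_block(self.model.block, self.factors)

    def summary(self) -> str:
        b = self.model.block
        rho = 1.0 - b.n_observed / b.values.size
        return "\n".join([
            "Latent factor completion",
            f"block: {b.values.shape[0]} x {b.values.shape[1]}   "
            f"missing rate: {rho:.3f}   L: {self.factors.L}",
            f"epochs run: {len(self.loss_curve) - 1}   "
            f"loss: {self.loss_curve[0]:.4g} -> {self.loss_curve[-1]:.4g}",
        ])
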