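"""Feature-stream buffering and the per-block impute/select/prune pipeline.

Streaming features arrive one column at a time, each column possibly
containing missing entries.  Columns are accumulated into fixed-width
``M x H`` buffers (:class:`SparseFeatureBlock`).  For every block the
pipeline (:func:`process_stream`)

1. completes the block with a rank-L latent-factor model trained on the
   observed cells (skipped when nothing is missing),
2. forms a candidate pool from the previously selected features and the
   block's features,
3. evolves a binary-inclusion genetic algorithm over the pool, minimising
   classification error plus a sparsity penalty,
4. classifies the relevance of each winning feature against the label and
   drops irrelevant ones, then prunes conditionally redundant features
   (Markov-blanket criterion),
5. commits the surviving set as the running selection.

Features rejected in an earlier block are not recalled later; the candidate
pool at block t therefore never exceeds ``|S_{t-1}| + H`` features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from . import lfa as _lfa
from . import ga as _ga
from . import fitness as _fitness
from . import redundancy as _redundancy
from ._utils import seed_to_int

log = logging.getLogger(__name__)

__all__ = [
    "SparseFeatureBlock",
    "StreamConfig",
    "BlockRecord",
    "SelectionState",
    "buffer_stream",
    "compute_missing_rate",
    "process_stream",
]


@dataclass
class SparseFeatureBlock:
    """An ``M x H`` block of streamed feature columns with an observation mask.

    ``mask`` is True where the value was observed; consumers must never read
    ``values`` where ``mask`` is False (such cells may hold NaN or garbage).
    """

    values: np.ndarray
    mask: np.ndarray
    feature_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if self.values.ndim != 2:
            raise ValueError("a feature block must be a 2-D matrix")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must equal block width")

    @property
    def sample_count(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        """|Lambda|: number of observed cells."""
        return int(self.mask.sum())

    def is_fully_observed(self) -> bool:
        return bool(self.mask.all())


@dataclass
class StreamConfig:
    """Every knob of the per-block pipeline plus the master seed.

    The master seed is split into independent substreams (factor init, GA,
    hold-out splits) so component order never perturbs another component's
    randomness.
    """

    buffer_width: int = 20
    lfa: "_lfa.LfaParams" = field(default_factory=lambda: _lfa.LfaParams())
    ga: "_ga.GAParams" = field(default_factory=lambda: _ga.GAParams())
    classifier: "_fitness.ClassifierSpec" = field(
        default_factory=lambda: _fitness.ClassifierSpec("svm_linear")
    )
    protocol: "_fitness.EvalProtocol" = field(
        default_factory=lambda: _fitness.EvalProtocol(k=2)
    )
    redundancy_alpha: float = 0.05
    max_cond: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer_width < 1:
            raise ValueError("buffer_width must be >= 1")
        if not 0.0 < self.redundancy_alpha < 1.0:
            raise ValueError("redundancy_alpha must lie in (0, 1)")


@dataclass
class BlockRecord:
    """Per-block history entry kept by :class:`SelectionState`."""

    block_index: int
    feature_ids: list
    missing_rate: float
    candidate_count: int
    ga_curve: np.ndarray
    ga_selected: list
    relevance_dropped: list
    prune_removed: list
    selected_after: list


@dataclass
class SelectionState:
    """The evolving selected-feature set with full per-block history."""

    selected_ids: list = field(default_factory=list)
    records: list = field(default_factory=list)
    total_features_seen: int = 0
    # completed values of currently selected features (id -> length-M column)
    selected_values: dict = field(default_factory=dict)

    def selected_matrix(self) -> np.ndarray:
        if not self.selected_ids:
            return np.empty((0, 0))
        return np.column_stack([self.selected_values[i] for i in self.selected_ids])


def buffer_stream(
    feature_columns: Iterable[tuple[Hashable, np.ndarray]],
    H: int,
) -> list[SparseFeatureBlock]:
    """Collect streamed ``(id, column)`` pairs into blocks of width ``H``.

    Columns may contain NaN to mark missing entries.  Every block except
    possibly the last has width ``H``; a final remainder is emitted as a
    narrower block rather than discarded.  An empty stream yields an empty
    list (selection operations reject it downstream).
    """
    if H < 1:
        raise ValueError("buffer width H must be >= 1")
    cols = [(fid, np.asarray(v, dtype=float).ravel()) for fid, v in feature_columns]
    if not cols:
        return []
    M = cols[0][1].shape[0]
    for fid, v in cols:
        if v.shape[0] != M:
            raise ValueError(
                f"ragged stream: column {fid!r} has length {v.shape[0]}, expected {M}"
            )
    blocks = []
    for start in range(0, len(cols), H):
        chunk = cols[start : start + H]
        values = np.column_stack([v for _, v in chunk])
        mask = ~np.isnan(values)
        blocks.append(
            SparseFeatureBlock(values=values, mask=mask, feature_ids=[fid for fid, _ in chunk])
        )
    return blocks


def compute_missing_rate(block: SparseFeatureBlock) -> float:
    """Missing rate rho = 1 - |Lambda| / (number of cells).

    For a single streamed column this reduces to the per-column definition
    ``1 - |Lambda|/M``; for a block all ``M*H`` cells form the denominator.
    """
    n_cells = block.values.size
    if n_cells == 0:
        raise ValueError("cannot compute a missing rate for a zero-cell block")
    return 1.0 - block.n_observed / n_cells


def _validate_labels(labels: Sequence, M: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.ndim != 1 or y.shape[0] != M:
        raise ValueError(f"labels must be a length-{M} vector")
    if len(np.unique(y)) < 2:
        raise ValueError("selection requires at least 2 distinct classes")
    return y


def process_stream(
    stream: Sequence[SparseFeatureBlock],
    labels: Sequence,
    config: StreamConfig | None = None,
) -> SelectionState:
    """Run the impute -> GA-select -> prune cycle over every block in order.

    Returns the final :class:`SelectionState`; re-running with the same
    ``config.master_seed`` reproduces it exactly.
    """
    if config is None:
        config = StreamConfig()
    stream = list(stream)
    if not stream:
        raise ValueError("empty stream: nothing to select from")
    M = stream[0].sample_count
    y = _validate_labels(labels, M)

    state = SelectionState()
    block_seeds = np.random.SeedSequence(config.master_seed).spawn(len(stream))

    for t, block in enumerate(stream):
        if block.sample_count != M:
            raise ValueError("all blocks must share the same sample count")
        lfa_ss, ga_ss, eval_ss = block_seeds[t].spawn(3)
        log.debug(
            "block %d substream seeds: lfa=%d ga=%d eval=%d",
            t, seed_to_int(lfa_ss), seed_to_int(ga_ss), seed_to_int(eval_ss),
        )

        # 1. completion — identical bypass when nothing is missing
        if block.is_fully_observed():
            completed = block.values.copy()
        else:
            params = _lfa.LfaParams(
                L=config.lfa.L,
                learning_rate=config.lfa.learning_rate,
                regularization=config.lfa.regularization,
                max_epochs=config.lfa.max_epochs,
                rel_tol=config.lfa.rel_tol,
                min_epochs=config.lfa.min_epochs,
                init_scale=config.lfa.init_scale,
                seed=seed_to_int(lfa_ss),
            )
            fp, _ = _lfa.train(block, params)
            completed = _lfa.complete_block(block, fp)

        # 2. candidate pool: previous selection plus this block's columns
        pool_ids = list(state.selected_ids)
        pool_cols = [state.selected_values[i] for i in pool_ids]
        for j, fid in enumerate(block.feature_ids):
            pool_ids.append(fid)
            pool_cols.append(completed[:, j])
        X_pool = np.column_stack(pool_cols)

        # 3. GA over the pool
        evaluator = _fitness.make_evaluator(
            y, config.classifier, config.protocol, seed=seed_to_int(eval_ss)
        )
        ga_params = _ga.GAParams(
            population_size=config.ga.population_size,
            max_iterations=config.ga.max_iterations,
            crossover_prob=config.ga.crossover_prob,
            mutation_prob=config.ga.mutation_prob,
            init_prob=config.ga.init_prob,
            selection_floor=config.ga.selection_floor,
            alpha=config.ga.alpha,
            beta=config.ga.beta,
            mutation_strength=config.ga.mutation_strength,
            seed=seed_to_int(ga_ss),
        )
        result = _ga.run_ga(X_pool, y, ga_params, evaluator)
        winner_idx = sorted(result.selected_indices)
        winner_ids = [pool_ids[j] for j in winner_idx]
        winner_cols = {fid: X_pool[:, j] for fid, j in zip(winner_ids, winner_idx)}

        # 4a. relevance: drop features irrelevant to the label
        kept_ids, dropped_ids = [], []
        for fid in winner_ids:
            others = [winner_cols[g] for g in winner_ids if g != fid]
            col = winner_cols[fid]
            if np.std(col) < 1e-12:
                dropped_ids.append(fid)  # constant column carries no signal
                continue
            rel = _redundancy.classify_relevance(
                col, y, others,
                alpha=config.redundancy_alpha, max_cond=config.max_cond,
            )
            (kept_ids if rel != "irrelevant" else dropped_ids).append(fid)

        # 4b. redundancy pruning (Markov-blanket criterion)
        kept_cols = [winner_cols[fid] for fid in kept_ids]
        survivors = _redundancy.redundancy_prune(
            kept_cols, y, alpha=config.redundancy_alpha, max_cond=config.max_cond
        )
        final_ids = [kept_ids[j] for j in survivors]
        pruned_ids = [fid for fid in kept_ids if fid not in final_ids]

        # 5. commit
        state.selected_ids = final_ids
        state.selected_values = {fid: winner_cols[fid] for fid in final_ids}
        state.total_features_seen += block.width
        state.records.append(
            BlockRecord(
                block_index=t,
                feature_ids=list(block.feature_ids),
                missing_rate=compute_missing_rate(block),
                candidate_count=len(pool_ids),
                ga_curve=result.convergence_curve,
                ga_selected=winner_ids,
                relevance_dropped=dropped_ids,
                prune_removed=pruned_ids,
                selected_after=list(final_ids),
            )
        )
    return state
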