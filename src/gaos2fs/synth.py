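"""Synthetic sparse feature streams with known ground truth.

The generator emulates the structure the selection pipeline assumes:

* an approximately low-rank feature matrix — every column is ``A @ w_j``
  for a shared M x L_true standard-normal latent matrix ``A`` plus i.i.d.
  measurement noise;
* a planted subset of label-informative columns, each aligned with its own
  orthogonal latent direction so that every one is an independent additive
  contributor to the label score (and hence conditionally dependent on the
  label given any subset of the others);
* redundant columns, each a scalar multiple of a single informative source
  column (a "planted duplicate") degraded by idiosyncratic per-sample jitter
  proportional to the source's scale — a noisy proxy that is conditionally
  independent of the label given its source, yet identifiably the weaker
  channel of the pair.  The jitter is measurement-type corruption: with
  ``noise_sd = 0`` the generator is fully noiseless, duplicates are exact
  multiples and the matrix has rank exactly the latent rank;
* pure-noise columns: idiosyncratic Gaussian columns scaled to match the
  informative columns, carrying no shared latent content.  (Noise columns
  built inside the informative latent space — even with weights orthogonal
  to the label direction — are linear contrasts of the clean informative
  components, and a multivariate classifier can combine them with a single
  informative column to reconstruct the full label score; truly
  uninformative features must be idiosyncratic.)  Like all stochastic
  corruption they vanish when ``noise_sd = 0``;
* a missing-completely-at-random mask hiding each cell independently with
  probability rho.

Labels derive from the noiseless latent combination ``A @ g`` — by the
linear-threshold rule ``sign(A @ g)`` or by XOR of two thresholded
informative columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stream import SparseFeatureBlock, buffer_stream

__all__ = [
    "SyntheticStreamSpec",
    "GroundTruth",
    "generate_stream",
    "inject_mcar",
    "full_matrix",
]


@dataclass
class SyntheticStreamSpec:
    """Parameters of the synthetic stream generator."""

    samples: int = 200
    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 90
    latent_rank: int = 5
    label_model: str = "linear-threshold"  # or "xor-pair"
    noise_sd: float = 0.1
    missing_rate: float = 0.1
    buffer_width: int = 20
    redundant_jitter: float = 0.75  # duplicate jitter sd / source sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples < 20:
            raise ValueError("need at least 20 samples")
        if min(self.n_informative, self.latent_rank) < 1 or self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("inconsistent feature counts")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.label_model not in ("linear-threshold", "xor-pair"):
            raise ValueError("label_model must be 'linear-threshold' or 'xor-pair'")
        if self.label_model == "xor-pair" and self.n_informative < 2:
            raise ValueError("xor-pair labels need >= 2 informative features")

    @property
    def total_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    """Role of every generated feature, for validating selection output."""

    informative: list = field(default_factory=list)
    redundant: list = field(default_factory=list)
    noise: list = field(default_factory=list)
    redundant_source: dict = field(default_factory=dict)
    latent_rank: int = 0

    def role_of(self, fid) -> str:
        if fid in self.informative:
            return "informative"
        if fid in self.redundant:
            return "redundant"
        return "noise"


def inject_mcar(matrix: np.ndarray, rho: float, seed, feature_ids=None) -> SparseFeatureBlock:
    """Hide each cell independently with probability rho (MCAR)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    matrix = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.shape) >= rho
    if feature_ids is None:
        feature_ids = [f"f{j:04d}" for j in range(matrix.shape[1])]
    return SparseFeatureBlock(values=matrix, mask=mask, feature_ids=list(feature_ids))


def generate_stream(spec: SyntheticStreamSpec):
    """Generate ``(blocks, labels, ground_truth)`` for a synthetic stream.

    Features arrive informative -> redundant -> noise shuffled into a random
    order, buffered into width-``buffer_width`` blocks with an MCAR mask at
    ``missing_rate``.  Fully seed-reproducible.
    """
    M, L = spec.samples, spec.latent_rank
    rng = np.random.default_rng(spec.seed)
    A = rng.standard_normal((M, L))

    # informative weights: one orthonormal latent direction per feature, so
    # each is an independent additive contributor to the label score; if more
    # informative features are requested than the rank allows, directions are
    # reused cyclically (the extras are then mutually redundant by necessity)
    basis = np.linalg.qr(rng.standard_normal((L, L)))[0]
    W_inf = np.empty((L, spec.n_informative))
    for j in range(spec.n_informative):
        coef = rng.uniform(0.9, 1.1) * rng.choice([-1.0, 1.0])
        W_inf[:, j] = coef * basis[:, j % L]

    informative_clean = A @ W_inf  # noiseless columns defining the label

    # label direction g = sum_j w_j: every planted feature contributes an
    # equal (up to the coef spread) share of the label score, so each one is
    # individually recoverable
    g = W_inf.sum(axis=1)
    score = A @ g

    if spec.label_model == "linear-threshold":
        labels = (score > np.median(score)).astype(int)
    else:
        t0 = informative_clean[:, 0] > np.median(informative_clean[:, 0])
        t1 = informative_clean[:, 1] > np.median(informative_clean[:, 1])
        labels = (t0 ^ t1).astype(int)

    columns: list[np.ndarray] = []
    roles: list[str] = []
    sources: dict[int, int] = {}

    for j in range(spec.n_informative):
        col = informative_clean[:, j] + spec.noise_sd * rng.standard_normal(M)
        columns.append(col)
        roles.append("informative")

    # each duplicate mirrors a distinct informative source where possible
    src_order = rng.permutation(spec.n_informative)
    for j in range(spec.n_redundant):
        src = int(src_order[j % spec.n_informative])
        scale = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
        source = informative_clean[:, src]
        col = scale * source
        if spec.noise_sd > 0 and spec.redundant_jitter > 0:
            # idiosyncratic degradation of the duplicate channel: per-sample
            # noise no other feature can reconstruct, so the source stays the
            # identifiably better member of the pair while the duplicate
            # remains conditionally independent of the label given the source
            col = col + spec.redundant_jitter * float(np.std(source)) * abs(
                scale
            ) * rng.standard_normal(M)
        col = col + spec.noise_sd * rng.standard_normal(M)
        sources[spec.n_informative + j] = src
        columns.append(col)
        roles.append("redundant")

    typical_sd = float(np.mean(np.std(informative_clean, axis=0)))
    for j in range(spec.n_noise):
        if spec.noise_sd > 0:
            scale = rng.uniform(0.8, 1.2) * typical_sd
            col = scale * rng.standard_normal(M)
        else:
            col = np.zeros(M)
        columns.append(col)
        roles.append("noise")

    # stream order: random permutation of all features
    order = rng.permutation(spec.total_features)
    ids = [f"f{j:04d}" for j in range(spec.total_features)]
    truth = GroundTruth(
        informative=[ids[j] for j in range(spec.total_features) if roles[j] == "informative"],
        redundant=[ids[j] for j in range(spec.total_features) if roles[j] == "redundant"],
        noise=[ids[j] for j in range(spec.total_features) if roles[j] == "noise"],
        redundant_source={ids[k]: ids[v] for k, v in sources.items()},
        latent_rank=L,
    )

    stream_cols = []
    mask_rng = np.random.default_rng(rng.integers(2**31 - 1))
    for j in order:
        col = columns[j].copy()
        if spec.missing_rate > 0:
            hidden = mask_rng.random(M) < spec.missing_rate
            col[hidden] = np.nan
        stream_cols.append((ids[j], col))

    blocks = buffer_stream(stream_cols, spec.buffer_width)
    return blocks, labels, truth


def full_matrix(spec: SyntheticStreamSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """The complete (un-masked) feature matrix in stream order, with labels.

    Convenience for rank / recoverability checks on the generator itself.
    """
    spec_dense = SyntheticStreamSpec(**{**spec.__dict__, "missing_rate": 0.0})
    blocks, labels, truth = generate_stream(spec_dense)
    X = np.column_stack([b.values for b in blocks])
    return X, labels, truth
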