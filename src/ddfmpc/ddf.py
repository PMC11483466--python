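"""Data-driven forecasting of membrane voltage.

The forecaster is a voltage-increment map built on a time-delay embedding
of the observed voltage: with embedding state
``S_n = (V_n, V_{n-tau}, ..., V_{n-(D_e-1) tau})`` the one-step model is

    V_{n+1} = V_n + F_RBF(S_n) + alpha (I_{n+1} + I_n),

where ``F_RBF`` is a Gaussian radial-basis-function network with centers
found by k-means in embedding space and ``alpha`` scales the additive
injected-current term (the trapezoidal contribution of the current over
one sampling period).  The output weights and ``alpha`` are linear in the
regression, so training is ridge regression with the regularization
strength chosen by contiguous-block cross-validation.

The embedding dimension is chosen by simplex projection: a nearest-
neighbor one-step forecaster whose out-of-sample skill (Pearson
correlation) is compared across candidate dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from . import _kernels
from .traces import CurrentTrace, VoltageTrace

__all__ = [
    "EmbeddingSpec", "RBFNModel", "DesignMatrices", "embed",
    "select_embedding_dim", "fit_centers", "rbf_activation", "build_design",
    "ridge_fit", "cross_validate_lambda", "predict_step",
    "forecast_open_loop", "train_ddf", "DEFAULT_LAMBDA_GRID",
]

#: logarithmic ridge-penalty grid searched by cross-validation
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-8, 2, 11))


@dataclass(frozen=True)
class EmbeddingSpec:
    """Time-delay embedding: dimension ``D_e`` and delay ``tau`` (samples)."""

    dimension: int = 2
    delay: int = 1

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.delay < 1:
            raise ValueError("embedding dimension and delay must be >= 1")

    @property
    def history(self) -> int:
        """Number of past samples needed in addition to the current one."""
        return (self.dimension - 1) * self.delay


def embed(v: VoltageTrace | np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Delay-embed a series; row k is ``S_{L+k}`` with L = (D_e-1) tau.

    The first column of each state is the current sample ``V_n``; column d
    holds ``V_{n - d tau}``.
    """
    x = v.values if isinstance(v, VoltageTrace) else np.asarray(v, dtype=float)
    L = spec.history
    if len(x) <= L:
        raise ValueError(
            f"series of length {len(x)} too short for embedding history {L}")
    n_states = len(x) - L
    cols = [x[L - d * spec.delay: L - d * spec.delay + n_states]
            for d in range(spec.dimension)]
    return np.column_stack(cols)


def _simplex_skill(x: np.ndarray, dim: int, delay: int,
                   library_frac: float) -> float:
    """One-step simplex-projection forecast skill for one embedding dimension.

    Library = first ``library_frac`` of the embedded states, prediction set
    = remainder.  Each prediction uses the ``dim + 1`` nearest library
    states with exponential distance weights w_i = exp(-d_i / d_1).
    """
    spec = EmbeddingSpec(dimension=dim, delay=delay)
    states = embed(x, spec)
    # target: next value of the observable for each state
    targets = x[spec.history + 1:]
    states = states[:-1]
    n = len(states)
    split = int(n * library_frac)
    if split < dim + 1 or split >= n:
        raise ValueError("series too short for simplex library/prediction split")
    tree = cKDTree(states[:split])
    dist, idx = tree.query(states[split:], k=dim + 1)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    d1 = dist[:, :1].copy()
    exact = d1[:, 0] == 0.0
    d1[exact, 0] = 1.0  # weights below handle exact matches explicitly
    w = np.exp(-dist / d1)
    w[exact] = (dist[exact] == 0.0).astype(float)
    pred = np.sum(w * targets[idx], axis=1) / np.sum(w, axis=1)
    obs = targets[split:]
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def select_embedding_dim(v: VoltageTrace | np.ndarray,
                         candidate_dims=range(1, 11),
                         delay: int = 1,
                         library_frac: float = 0.75) -> int:
    """Embedding dimension maximizing simplex one-step forecast skill.

    Ties break toward the smallest dimension.  Raises on a constant series
    (no forecastable structure).
    """
    x = v.values if isinstance(v, VoltageTrace) else np.asarray(v, dtype=float)
    if np.std(x) == 0.0:
        raise ValueError("cannot select an embedding for a constant series")
    best_dim, best_skill = None, -np.inf
    for dim in candidate_dims:
        skill = _simplex_skill(x, int(dim), delay, library_frac)
        if skill > best_skill + 1e-12:
            best_dim, best_skill = int(dim), skill
    return best_dim


def fit_centers(states: np.ndarray, n_centers: int = 50,
                seed: int = 0) -> np.ndarray:
    """RBF centers by k-means clustering of the embedded states."""
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    if len(states) < n_centers:
        raise ValueError(
            f"{len(states)} states cannot support {n_centers} centers")
    km = KMeans(n_clusters=n_centers, random_state=seed, n_init=10)
    km.fit(states)
    return km.cluster_centers_


def rbf_activation(S: np.ndarray, mu: np.ndarray, R: float) -> float | np.ndarray:
    """Gaussian kernel exp(-R ||S - mu||^2); R in 1/mV^2."""
    if R <= 0:
        raise ValueError("length-scale parameter R must be positive")
    S = np.asarray(S, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d2 = np.sum((S - mu) ** 2, axis=-1)
    return np.exp(-R * d2)


@dataclass
class DesignMatrices:
    """Ridge-regression design for the voltage-increment model.

    ``X`` has one row per usable transition: N RBF activations of the
    embedded state followed by the summed current ``I_{k+1} + I_k``;
    ``Y`` holds the voltage increments ``V_{k+1} - V_k``.
    """

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")


def build_design(v: VoltageTrace, i: CurrentTrace, centers: np.ndarray,
                 R: float, spec: EmbeddingSpec) -> DesignMatrices:
    """Assemble the regression matrices from aligned voltage/current traces."""
    if len(v) != len(i) or abs(v.dt - i.dt) > 1e-12:
        raise ValueError("voltage and current traces must share length and dt")
    states = embed(v, spec)[:-1]          # S_L .. S_{T-1}
    L = spec.history
    acts = rbf_activation(states[:, None, :], centers[None, :, :], R)
    i_sum = i.values[L + 1:] + i.values[L:-1]
    X = np.column_stack([acts, i_sum])
    Y = np.diff(v.values[L:])
    return DesignMatrices(X=X, Y=Y)


def ridge_fit(design: DesignMatrices, lam: float) -> np.ndarray:
    """Ridge (Tikhonov) solution of the design system.

    Solved as an augmented least-squares problem ``[X; sqrt(lam) I] W =
    [Y; 0]``, which is numerically better conditioned than forming the
    normal equations; the result satisfies ``(X'X + lam I) W = X'Y``.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    X, Y = design.X, design.Y
    p = X.shape[1]
    if lam == 0.0:
        W, *_ = lstsq(X, Y)
        return W
    Xa = np.vstack([X, np.sqrt(lam) * np.eye(p)])
    Ya = np.concatenate([Y, np.zeros(p)])
    W, *_ = lstsq(Xa, Ya)
    return W


def cross_validate_lambda(design: DesignMatrices, folds: int = 10,
                          grid=DEFAULT_LAMBDA_GRID) -> float:
    """Ridge penalty minimizing mean held-out squared error.

    Folds are contiguous blocks in time (shuffled folds would leak
    temporally adjacent, strongly correlated samples into the training
    side).  Ties break toward the larger penalty.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    X, Y = design.X, design.Y
    n = len(Y)
    if n < folds:
        raise ValueError("fewer rows than folds")
    bounds = np.linspace(0, n, folds + 1).astype(int)
    gram = X.T @ X
    xty = X.T @ Y
    p = X.shape[1]
    errors = np.zeros(len(grid))
    for f in range(folds):
        lo, hi = bounds[f], bounds[f + 1]
        Xv, Yv = X[lo:hi], Y[lo:hi]
        gram_t = gram - Xv.T @ Xv
        xty_t = xty - Xv.T @ Yv
        for g, lam in enumerate(grid):
            W = np.linalg.solve(gram_t + lam * np.eye(p), xty_t)
            errors[g] += np.mean((Xv @ W - Yv) ** 2)
    errors /= folds
    # argmin with ties toward larger lambda
    order = np.argsort([-lam for lam in grid], kind="stable")
    best = min((errors[g], g) for g in order)[1]
    return float(grid[best])


@dataclass
class RBFNModel:
    """Learned voltage-increment forecaster."""

    centers: np.ndarray            # (N, D_e), mV coordinates
    weights: np.ndarray            # (N,) RBF output weights
    alpha: float                   # current-sum coefficient, mV/µA
    R: float                       # kernel length scale, 1/mV²
    embedding: EmbeddingSpec
    lam: float = 0.0
    dt: float = 0.1                # sampling period the model was trained at, ms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != self.embedding.dimension:
            raise ValueError("centers must be (N, D_e)")
        if len(self.weights) != len(self.centers):
            raise ValueError("one weight per center required")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if not (np.all(np.isfinite(self.centers))
                and np.all(np.isfinite(self.weights))):
            raise ValueError("centers and weights must be finite")

    def f_rbf(self, S: np.ndarray) -> float | np.ndarray:
        """Network output sum_c w_c psi_c(S)."""
        S = np.asarray(S, dtype=float)
        acts = rbf_activation(S[..., None, :], self.centers, self.R)
        return acts @ self.weights

    def to_json(self, path) -> None:
        doc = {
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "alpha": self.alpha,
            "R": self.R,
            "embedding": {"dimension": self.embedding.dimension,
                          "delay": self.embedding.delay},
            "lambda": self.lam,
            "dt": self.dt,
            "metadata": self.metadata,
        }
        with open(path, "w") as fp:
            json.dump(doc, fp)

    @classmethod
    def from_json(cls, path) -> "RBFNModel":
        with open(path) as fp:
            doc = json.load(fp)
        return cls(centers=np.array(doc["centers"]),
                   weights=np.array(doc["weights"]),
                   alpha=doc["alpha"], R=doc["R"],
                   embedding=EmbeddingSpec(**doc["embedding"]),
                   lam=doc.get("lambda", 0.0), dt=doc.get("dt", 0.1),
                   metadata=doc.get("metadata", {}))


def predict_step(model: RBFNModel, S_n: np.ndarray, i_n: float,
                 i_next: float) -> float:
    """One forecaster step: V_{n+1} = V_n + F_RBF(S_n) + alpha (I_{n+1} + I_n)."""
    S_n = np.asarray(S_n, dtype=float)
    if S_n.shape != (model.embedding.dimension,):
        raise ValueError(
            f"state has shape {S_n.shape}, expected ({model.embedding.dimension},)")
    return float(S_n[0] + model.f_rbf(S_n) + model.alpha * (i_next + i_n))


def forecast_open_loop(model: RBFNModel, v_seed, i: CurrentTrace,
                       v_guard: float = 500.0
                       ) -> tuple[VoltageTrace, dict]:
    """Free-running forecast: predictions are fed back into the embedding.

    ``v_seed`` must hold exactly ``(D_e - 1) tau + 1`` voltage samples; the
    true voltage is never consulted afterwards.  If |V| exceeds ``v_guard``
    the rollout is truncated (held constant) and flagged in the returned
    info dict.
    """
    v_seed = np.asarray(
        v_seed.values if isinstance(v_seed, VoltageTrace) else v_seed,
        dtype=float)
    L = model.embedding.history
    if len(v_seed) != L + 1:
        raise ValueError(f"seed must have exactly {L + 1} samples")
    v, diverged = _kernels.rbf_forecast(
        v_seed, i.values, model.centers, model.weights,
        model.alpha, model.R, model.embedding.delay, v_guard)
    info = {"diverged": diverged >= 0,
            "diverged_at_ms": diverged * i.dt if diverged >= 0 else None}
    return VoltageTrace(values=v, dt=i.dt, t0=i.t0), info


def train_ddf(v: VoltageTrace, i: CurrentTrace, n_centers: int = 50,
              R: float = 0.01, spec: EmbeddingSpec | None = None,
              folds: int = 10, grid=DEFAULT_LAMBDA_GRID,
              seed: int = 0) -> RBFNModel:
    """Fit the full forecaster from one training recording.

    The embedding must already be chosen (pass ``spec``); use
    :func:`select_embedding_dim` to pick the dimension from data.
    """
    if spec is None:
        spec = EmbeddingSpec(dimension=2, delay=1)
    states = embed(v, spec)
    centers = fit_centers(states, n_centers=n_centers, seed=seed)
    design = build_design(v, i, centers, R, spec)
    lam = cross_validate_lambda(design, folds=folds, grid=grid)
    W = ridge_fit(design, lam)
    return RBFNModel(centers=centers, weights=W[:-1], alpha=float(W[-1]),
                     R=R, embedding=spec, lam=lam, dt=v.dt,
                     metadata={"n_train": len(v), "seed": seed})
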