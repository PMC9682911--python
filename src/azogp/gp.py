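"""Exact Gaussian process regression with the Tanimoto kernel.

Single-task model
-----------------
Molecules are represented as non-negative bit/count vectors x and the
covariance between two molecules is the Tanimoto kernel

    k(x, x') = sigma_f^2 * <x, x'> / (|x|^2 + |x'|^2 - <x, x'>),

a valid positive-semidefinite kernel on non-negative vectors. Targets are
z-scored, the prior mean is zero, observation noise is homoscedastic
Gaussian with variance sigma_y^2, and (sigma_f^2, sigma_y^2) are set by
maximising the log marginal likelihood with a multi-restart quasi-Newton
optimiser.

Multioutput model
-----------------
For P related tasks the intrinsic model of coregionalisation (ICM) defines
the covariance between observation (x, task i) and (x', task j) as
k(x, x') * B[i, j], where B = L L^T is a learned positive-semidefinite
task-covariance matrix parametrised through its Cholesky factor L.
Molecules missing a task's label simply contribute no row for that task.
Inference is the standard exact-GP conditional on the stacked
(molecule, task) observations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize

LOG_2PI = float(np.log(2.0 * np.pi))

SERIALIZATION_VERSION = 1


class NumericalError(RuntimeError):
    """Kernel matrix not positive definite even at maximum jitter."""


class DegenerateTargetError(ValueError):
    """Targets have zero variance; standardisation is impossible."""


# ---------------------------------------------------------------------------
# kernels


def tanimoto_kernel(x, x2, sigma_f2: float = 1.0) -> float:
    """Tanimoto covariance between two non-negative count vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    dot = float(x @ x2)
    denom = float(x @ x) + float(x2 @ x2) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto similarity undefined: both vectors all-zero")
    return sigma_f2 * dot / denom


def tanimoto_matrix(X, Y=None) -> np.ndarray:
    """Unit-variance Tanimoto kernel matrix between rows of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    xx = np.einsum("ij,ij->i", X, X)
    yy = np.einsum("ij,ij->i", Y, Y)
    if np.any(xx == 0.0) or np.any(yy == 0.0):
        raise ValueError("all-zero feature vector: Tanimoto similarity undefined")
    xy = X @ Y.T
    return xy / (xx[:, None] + yy[None, :] - xy)


@dataclass
class KernelParams:
    sigma_f2: float = 1.0
    sigma_y2: float = 0.1

    def __post_init__(self):
        if self.sigma_f2 <= 0:
            raise ValueError("sigma_f2 must be > 0")
        if self.sigma_y2 < 0:
            raise ValueError("sigma_y2 must be >= 0")


@dataclass
class Coregionalisation:
    """Task covariance B = L L^T over P tasks, L lower-triangular."""

    L: np.ndarray

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2 or self.L.shape[0] < self.L.shape[1]:
            raise ValueError("L must be square or tall (P x rank)")
        if not np.allclose(self.L, np.tril(self.L)):
            raise ValueError("L must be lower-triangular")

    @property
    def n_tasks(self) -> int:
        return self.L.shape[0]

    @property
    def B(self) -> np.ndarray:
        return self.L @ self.L.T


def icm_covariance(x, x2, i: int, j: int, base_params: KernelParams,
                   coreg: Coregionalisation) -> float:
    """ICM covariance k(x, x') * B[i, j] between (x, task i) and (x', task j)."""
    i, j = _task_index(i), _task_index(j)
    B = coreg.B
    P = coreg.n_tasks
    if not (0 <= i < P and 0 <= j < P):
        raise ValueError(f"task index out of range for P={P}")
    return tanimoto_kernel(x, x2, base_params.sigma_f2) * B[i, j]


# ---------------------------------------------------------------------------
# numerics


def _chol_with_jitter(K: np.ndarray, jitter0: float, max_jitter: float):
    """Lower Cholesky of K + jitter*mean(diag)*I, escalating jitter x10."""
    scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        scale = 1.0
    jitter = jitter0
    while True:
        try:
            L = cholesky(K + jitter * scale * np.eye(K.shape[0]), lower=True)
            return L, jitter * scale
        except np.linalg.LinAlgError:
            if jitter >= max_jitter:
                raise NumericalError(
                    f"kernel matrix not PD at maximum jitter {max_jitter:g} "
                    f"(n={K.shape[0]}, mean diag={scale:g})"
                )
            jitter *= 10.0


def _mvn_logpdf_chol(y: np.ndarray, L: np.ndarray) -> tuple[float, np.ndarray]:
    """Zero-mean Gaussian log-density given the lower Cholesky of the
    covariance; also returns alpha = K^{-1} y."""
    a = solve_triangular(L, y, lower=True)
    alpha = solve_triangular(L.T, a, lower=False)
    lml = -0.5 * float(y @ alpha) - float(np.sum(np.log(np.diag(L)))) \
        - 0.5 * len(y) * LOG_2PI
    return lml, alpha


def log_marginal_likelihood(params: KernelParams, X, y_standardised) -> float:
    """Log marginal likelihood of standardised targets under the
    zero-mean Tanimoto-kernel GP: log N(y; 0, sigma_f2*T + sigma_y2*I)."""
    y = np.asarray(y_standardised, dtype=float)
    T = tanimoto_matrix(X)
    K = params.sigma_f2 * T + params.sigma_y2 * np.eye(len(y))
    L, _ = _chol_with_jitter(K, 1e-10, 1e-2)
    lml, _ = _mvn_logpdf_chol(y, L)
    return lml


# ---------------------------------------------------------------------------
# single-task GP


@dataclass
class GPConfig:
    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-6
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    log_bounds: tuple[float, float] = (-12.0, 8.0)


@dataclass
class GPState:
    X_train: np.ndarray
    y_mean: float
    y_std: float
    params: KernelParams
    chol: np.ndarray
    alpha: np.ndarray
    z: np.ndarray
    jitter: float = 0.0


def _pick_best(results):
    """Best (highest-LML) optimiser result; near-ties broken by smaller
    noise variance."""
    best = None
    for lml, sy2, payload in results:
        if best is None:
            best = (lml, sy2, payload)
            continue
        if lml > best[0] + 1e-9 * max(1.0, abs(best[0])):
            best = (lml, sy2, payload)
        elif abs(lml - best[0]) <= 1e-9 * max(1.0, abs(best[0])) and sy2 < best[1]:
            best = (lml, sy2, payload)
    return best


def fit_gp(X, y, config: GPConfig | None = None) -> GPState:
    """Fit sigma_f2, sigma_y2 by multi-restart marginal-likelihood
    maximisation on z-scored targets."""
    config = config or GPConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    y_mean = float(np.mean(y))
    y_std = float(np.std(y))
    if y_std == 0.0:
        raise DegenerateTargetError("constant targets: zero variance")
    z = (y - y_mean) / y_std

    T = tanimoto_matrix(X)
    n = len(z)
    eye = np.eye(n)

    def nlml_and_grad(theta):
        sf2, sy2 = np.exp(theta)
        K = sf2 * T + sy2 * eye
        try:
            L, _ = _chol_with_jitter(K, config.jitter, config.max_jitter)
        except NumericalError:
            return 1e25, np.zeros(2)
        lml, alpha = _mvn_logpdf_chol(z, L)
        Kinv = solve_triangular(
            L.T, solve_triangular(L, eye, lower=True), lower=False
        )
        W = np.outer(alpha, alpha) - Kinv
        g_sf2 = 0.5 * np.sum(W * T) * sf2
        g_sy2 = 0.5 * np.trace(W) * sy2
        return -lml, -np.array([g_sf2, g_sy2])

    rng = np.random.default_rng(config.seed)
    inits = [np.log([1.0, 0.1])]
    for _ in range(max(0, config.n_restarts - 1)):
        inits.append(rng.normal(loc=np.log([1.0, 0.1]), scale=1.5))

    results = []
    for x0 in inits:
        res = minimize(
            nlml_and_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[config.log_bounds] * 2, tol=config.tol,
        )
        if not res.success:
            warnings.warn(f"GP hyperparameter optimisation: {res.message}")
        sf2, sy2 = np.exp(res.x)
        results.append((-res.fun, sy2, (sf2, sy2)))

    _, _, (sf2, sy2) = _pick_best(results)
    params = KernelParams(sigma_f2=float(sf2), sigma_y2=float(sy2))
    K = params.sigma_f2 * T + params.sigma_y2 * eye
    L, jit = _chol_with_jitter(K, config.jitter, config.max_jitter)
    _, alpha = _mvn_logpdf_chol(z, L)
    return GPState(X_train=X, y_mean=y_mean, y_std=y_std, params=params,
                   chol=L, alpha=alpha, z=z, jitter=jit)


def predict_gp(state: GPState, X_star, include_noise: bool = False):
    """Posterior mean (original units) and latent variance at X_star.

    mean = K(X*,X) [K + sigma_y2 I]^{-1} y,
    var  = k(x*,x*) - K(X*,X) [K + sigma_y2 I]^{-1} K(X,X*),
    both de-standardised. ``include_noise`` adds sigma_y2 to the variance.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if X_star.shape[1] != state.X_train.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X_star.shape[1]} != "
            f"{state.X_train.shape[1]}"
        )
    sf2 = state.params.sigma_f2
    Ks = sf2 * tanimoto_matrix(X_star, state.X_train)
    mean = (Ks @ state.alpha) * state.y_std + state.y_mean
    v = solve_triangular(state.chol, Ks.T, lower=True)
    var_z = sf2 - np.einsum("ij,ij->j", v, v)
    if include_noise:
        var_z = var_z + state.params.sigma_y2
    var = np.clip(var_z, 0.0, None) * state.y_std**2
    return mean, var


# ---------------------------------------------------------------------------
# multioutput (ICM) GP


@dataclass(frozen=True)
class TaskObservation:
    molecule_index: int
    task: int
    value: float


def _task_index(task) -> int:
    idx = getattr(task, "index", None)
    if idx is not None and not callable(idx):
        return int(idx)
    return int(task)


@dataclass
class MOGPConfig:
    n_tasks: int = 4
    rank: int | None = None          # None -> full rank
    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-6
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    learn_sigma_f2: bool = False     # scale is absorbed into B by default
    per_task_noise: bool = False


@dataclass
class MOGPState:
    X_mols: np.ndarray
    mol_idx: np.ndarray
    task_idx: np.ndarray
    z: np.ndarray
    task_means: np.ndarray
    task_stds: np.ndarray
    coreg: Coregionalisation
    sigma_f2: float
    sigma_y2: np.ndarray            # shape (1,) shared or (P,) per-task
    chol: np.ndarray
    alpha: np.ndarray
    jitter: float
    n_tasks: int
    per_task_noise: bool = False

    def noise_for_task(self, t: int) -> float:
        return float(self.sigma_y2[t] if self.per_task_noise
                     else self.sigma_y2[0])


def _tril_indices(P: int, rank: int):
    rows, cols = [], []
    for i in range(P):
        for j in range(min(i + 1, rank)):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def _unpack_L(theta_L, P, rank, rows, cols):
    L = np.zeros((P, rank))
    L[rows, cols] = theta_L
    d = np.arange(rank)
    L[d, d] = np.exp(np.clip(np.diag(L[:rank, :rank]), -15.0, 15.0))
    return L


def _normalise_observations(observations):
    mol_idx, task_idx, values = [], [], []
    for obs in observations:
        if isinstance(obs, TaskObservation):
            m, t, v = obs.molecule_index, obs.task, obs.value
        else:
            m, t, v = obs
        mol_idx.append(int(m))
        task_idx.append(_task_index(t))
        values.append(float(v))
    return (np.asarray(mol_idx), np.asarray(task_idx),
            np.asarray(values, dtype=float))


def observations_from_table(Y: np.ndarray) -> list[TaskObservation]:
    """Turn an (n_molecules x P) label table with NaN for missing entries
    into a flat observation list."""
    Y = np.asarray(Y, dtype=float)
    obs = []
    for m in range(Y.shape[0]):
        for t in range(Y.shape[1]):
            if np.isfinite(Y[m, t]):
                obs.append(TaskObservation(m, t, float(Y[m, t])))
    return obs


def fit_mogp(observations, features, config: MOGPConfig | None = None
             ) -> MOGPState:
    """Fit the ICM multioutput GP on stacked (molecule, task) observations.

    Targets are z-scored per task using that task's observed labels; the
    coregionalisation factor L (diagonal through a log transform) and the
    noise variance are optimised jointly by multi-restart L-BFGS on the
    marginal likelihood.
    """
    config = config or MOGPConfig()
    features = np.atleast_2d(np.asarray(features, dtype=float))
    mol_idx, task_idx, values = _normalise_observations(observations)
    if len(values) == 0:
        raise ValueError("no observations")
    if len(values) < 2:
        raise ValueError("need at least 2 observations")
    P = config.n_tasks
    if task_idx.min() < 0 or task_idx.max() >= P:
        raise ValueError(f"task index out of range for n_tasks={P}")
    if mol_idx.min() < 0 or mol_idx.max() >= features.shape[0]:
        raise ValueError("molecule index out of range")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite observation values")

    task_means = np.full(P, np.nan)
    task_stds = np.full(P, np.nan)
    for t in np.unique(task_idx):
        vals = values[task_idx == t]
        task_means[t] = vals.mean()
        s = vals.std()
        if s == 0.0:
            raise DegenerateTargetError(
                f"task {t}: zero-variance labels cannot be standardised"
            )
        task_stds[t] = s
    z = (values - task_means[task_idx]) / task_stds[task_idx]

    T_obs = tanimoto_matrix(features)[np.ix_(mol_idx, mol_idx)]
    n = len(z)
    eye = np.eye(n)
    rank = config.rank or P
    rows, cols = _tril_indices(P, rank)
    n_L = len(rows)
    onehot = np.zeros((n, P))
    onehot[np.arange(n), task_idx] = 1.0
    n_noise = P if config.per_task_noise else 1
    learn_sf2 = config.learn_sigma_f2

    def unpack(theta):
        k = 0
        if learn_sf2:
            sf2 = float(np.exp(theta[0]))
            k = 1
        else:
            sf2 = 1.0
        sy2 = np.exp(theta[k:k + n_noise])
        L = _unpack_L(theta[k + n_noise:], P, rank, rows, cols)
        return sf2, sy2, L

    def noise_diag(sy2):
        return sy2[task_idx] if config.per_task_noise else np.full(n, sy2[0])

    def nlml_and_grad(theta):
        sf2, sy2, L = unpack(theta)
        B = L @ L.T
        Kf = sf2 * T_obs * B[np.ix_(task_idx, task_idx)]
        K = Kf + np.diag(noise_diag(sy2))
        try:
            Lc, _ = _chol_with_jitter(K, config.jitter, config.max_jitter)
        except NumericalError:
            return 1e25, np.zeros_like(theta)
        lml, alpha = _mvn_logpdf_chol(z, Lc)
        Kinv = solve_triangular(
            Lc.T, solve_triangular(Lc, eye, lower=True), lower=False
        )
        W = np.outer(alpha, alpha) - Kinv
        grad = np.empty_like(theta)
        k = 0
        if learn_sf2:
            grad[0] = -0.5 * np.sum(W * Kf)   # d/dlog sf2 = sf2 * Kf/sf2
            k = 1
        if config.per_task_noise:
            dW = np.diag(W)
            for t in range(P):
                grad[k + t] = -0.5 * float(dW[task_idx == t].sum()) * sy2[t]
        else:
            grad[k] = -0.5 * np.trace(W) * sy2[0]
        # C[i,j] aggregates (W * sf2 * T_obs) over observation pairs by task
        M = W * (sf2 * T_obs)
        C = onehot.T @ M @ onehot
        G = (C + C.T) @ L                      # d sum(W.K)/dL
        gL = -0.5 * G[rows, cols]
        diag_mask = rows == cols
        gL[diag_mask] *= L[rows[diag_mask], cols[diag_mask]]
        grad[k + n_noise:] = gL
        return -lml, grad

    rng = np.random.default_rng(config.seed)
    # start from L = I (diag entries are log-parametrised), sigma_y2 = 0.1
    base = np.concatenate([
        np.zeros(1 if learn_sf2 else 0),
        np.log(np.full(n_noise, 0.1)),
        np.zeros(n_L),
    ])
    inits = [base]
    for _ in range(max(0, config.n_restarts - 1)):
        pert = base + rng.normal(scale=0.5, size=base.shape)
        inits.append(pert)

    lo, hi = -12.0, 8.0
    bounds = []
    if learn_sf2:
        bounds.append((lo, hi))
    bounds += [(lo, hi)] * n_noise
    bounds += [((-8.0, 6.0) if r == c else (-20.0, 20.0))
               for r, c in zip(rows, cols)]

    results = []
    for x0 in inits:
        res = minimize(nlml_and_grad, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds, tol=config.tol)
        if not res.success:
            warnings.warn(f"MOGP optimisation: {res.message}")
        sf2, sy2, L = unpack(res.x)
        results.append((-res.fun, float(sy2.max()), (sf2, sy2, L)))

    _, _, (sf2, sy2, L) = _pick_best(results)
    B = L @ L.T
    K = sf2 * T_obs * B[np.ix_(task_idx, task_idx)] + np.diag(noise_diag(sy2))
    Lc, jit = _chol_with_jitter(K, config.jitter, config.max_jitter)
    _, alpha = _mvn_logpdf_chol(z, Lc)
    return MOGPState(
        X_mols=features, mol_idx=mol_idx, task_idx=task_idx, z=z,
        task_means=task_means, task_stds=task_stds,
        coreg=Coregionalisation(L=L), sigma_f2=float(sf2),
        sigma_y2=np.asarray(sy2, dtype=float), chol=Lc, alpha=alpha,
        jitter=jit, n_tasks=P, per_task_noise=config.per_task_noise,
    )


def predict_mogp(state: MOGPState, X_star, task, include_noise: bool = False):
    """Per-task posterior mean (original units) and latent variance."""
    t = _task_index(task)
    if not (0 <= t < state.n_tasks):
        raise ValueError(f"unknown task index {t} (n_tasks={state.n_tasks})")
    if not np.isfinite(state.task_stds[t]):
        raise ValueError(f"task {t} had no training observations")
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if X_star.shape[1] != state.X_mols.shape[1]:
        raise ValueError("feature dimension mismatch")
    B = state.coreg.B
    Tx = tanimoto_matrix(X_star, state.X_mols)[:, state.mol_idx]
    Ks = state.sigma_f2 * Tx * B[t, state.task_idx][None, :]
    mean = (Ks @ state.alpha) * state.task_stds[t] + state.task_means[t]
    v = solve_triangular(state.chol, Ks.T, lower=True)
    var_z = state.sigma_f2 * B[t, t] - np.einsum("ij,ij->j", v, v)
    if include_noise:
        var_z = var_z + state.noise_for_task(t)
    var = np.clip(var_z, 0.0, None) * state.task_stds[t]**2
    return mean, var


# ---------------------------------------------------------------------------
# serialisation


def save_model(state, path, feature_config: dict | None = None) -> None:
    """Serialise a fitted GP/MOGP to a versioned JSON bundle."""
    if isinstance(state, GPState):
        payload = {
            "kind": "gp",
            "X_train": state.X_train.tolist(),
            "y_mean": state.y_mean, "y_std": state.y_std,
            "sigma_f2": state.params.sigma_f2,
            "sigma_y2": state.params.sigma_y2,
            "z": state.z.tolist(), "jitter": state.jitter,
        }
    elif isinstance(state, MOGPState):
        payload = {
            "kind": "mogp",
            "X_mols": state.X_mols.tolist(),
            "mol_idx": state.mol_idx.tolist(),
            "task_idx": state.task_idx.tolist(),
            "z": state.z.tolist(),
            "task_means": state.task_means.tolist(),
            "task_stds": state.task_stds.tolist(),
            "L": state.coreg.L.tolist(),
            "sigma_f2": state.sigma_f2,
            "sigma_y2": state.sigma_y2.tolist(),
            "jitter": state.jitter, "n_tasks": state.n_tasks,
            "per_task_noise": state.per_task_noise,
        }
    else:
        raise TypeError(f"cannot serialise {type(state).__name__}")
    payload["version"] = SERIALIZATION_VERSION
    if feature_config is not None:
        payload["feature_config"] = feature_config
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a model bundle written by :func:`save_model`, rebuilding the
    Cholesky factor and alpha from the stored data."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    if payload["kind"] == "gp":
        X = np.asarray(payload["X_train"], dtype=float)
        z = np.asarray(payload["z"], dtype=float)
        params = KernelParams(payload["sigma_f2"], payload["sigma_y2"])
        K = params.sigma_f2 * tanimoto_matrix(X) \
            + params.sigma_y2 * np.eye(len(z))
        L, jit = _chol_with_jitter(K, 1e-6, 1e-2)
        _, alpha = _mvn_logpdf_chol(z, L)
        return GPState(X_train=X, y_mean=payload["y_mean"],
                       y_std=payload["y_std"], params=params, chol=L,
                       alpha=alpha, z=z, jitter=jit)
    if payload["kind"] == "mogp":
        X = np.asarray(payload["X_mols"], dtype=float)
        mol_idx = np.asarray(payload["mol_idx"], dtype=int)
        task_idx = np.asarray(payload["task_idx"], dtype=int)
        z = np.asarray(payload["z"], dtype=float)
        L_factor = np.asarray(payload["L"], dtype=float)
        sy2 = np.asarray(payload["sigma_y2"], dtype=float)
        per_task = bool(payload.get("per_task_noise", False))
        B = L_factor @ L_factor.T
        noise = sy2[task_idx] if per_task else np.full(len(z), sy2[0])
        K = payload["sigma_f2"] * tanimoto_matrix(X)[np.ix_(mol_idx, mol_idx)] \
            * B[np.ix_(task_idx, task_idx)] + np.diag(noise)
        Lc, jit = _chol_with_jitter(K, 1e-6, 1e-2)
        _, alpha = _mvn_logpdf_chol(z, Lc)
        return MOGPState(
            X_mols=X, mol_idx=mol_idx, task_idx=task_idx, z=z,
            task_means=np.asarray(payload["task_means"], dtype=float),
            task_stds=np.asarray(payload["task_stds"], dtype=float),
            coreg=Coregionalisation(L=L_factor),
            sigma_f2=payload["sigma_f2"], sigma_y2=sy2, chol=Lc, alpha=alpha,
            jitter=jit, n_tasks=payload["n_tasks"], per_task_noise=per_task,
        )
    raise ValueError(f"unknown model kind {payload['kind']!r}")
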