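"""Rate-network dynamics, latent projections and dimensionality.

The network obeys the classical firing-rate equation

    tau dx_i/dt = -x_i + sum_j W_ij phi(x_j) + I_i u(t),

with ``phi = tanh`` (so phi(0) = 0 and phi'(0) = 1, which ties the
stability of the zero fixed point directly to the eigenspectrum of W).
Integration is forward Euler with additive noise entering with
Euler-Maruyama sqrt(dt) scaling.  Rank-one structure makes the population
activity low-dimensional; the latent variables

    kappa_r = m^T x / ||m||^2,   kappa_I = I^T x / ||I||^2,
    kappa_rec = (1/N) sum_j n_j phi(x_j)

track the projection on the output pattern m, on the input pattern I, and
the recurrent drive (overlap of phi(x) with n); at any autonomous
equilibrium kappa_r == kappa_rec.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import scipy.sparse

from .connectivity import WeightMatrix

__all__ = [
    "NetworkModel",
    "SimulationConfig",
    "Trajectory",
    "LatentTrajectory",
    "DimensionalityReport",
    "SimulationDivergence",
    "FixedPointNotConverged",
    "simulate",
    "latent_projections",
    "participation_ratio",
    "pca_alignment",
    "find_fixed_point",
    "draw_input_vector",
    "save_trajectory",
]

# density below which the coupling is applied through a CSR operator
_SPARSE_DENSITY_CUTOFF = 0.3


class SimulationDivergence(RuntimeError):
    """Raised when the integrator produces non-finite state."""


class FixedPointNotConverged(RuntimeError):
    """Raised when the fixed-point search does not reach tolerance."""


@dataclass
class NetworkModel:
    """A rate network: coupling W, input pattern I, time constant tau (ms)."""

    W: Union[WeightMatrix, np.ndarray]
    I: Optional[np.ndarray] = None
    tau: float = 100.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        dense = self.W.W if isinstance(self.W, WeightMatrix) else np.asarray(self.W, float)
        if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
            raise ValueError("W must be square")
        self._dense = dense
        if self.I is not None:
            self.I = np.asarray(self.I, dtype=float)
            if self.I.shape != (dense.shape[0],):
                raise ValueError("input pattern I must be a length-N vector")
        density = np.count_nonzero(dense) / dense.size
        self._op = (
            scipy.sparse.csr_matrix(dense) if density < _SPARSE_DENSITY_CUTOFF else dense
        )

    @property
    def N(self) -> int:
        return self._dense.shape[0]

    def recurrent_drive(self, x: np.ndarray) -> np.ndarray:
        """W phi(x) for the current state."""
        return self._op @ np.tanh(x)


@dataclass
class SimulationConfig:
    """Integration settings.

    ``dt`` defaults to tau/20 and is capped at tau/10 (forward Euler
    accuracy).  ``x0`` is an explicit state or one of the presets ``zero``
    and ``random`` (iid N(0,1) scaled by ``x0_scale``).  ``input_signal``
    is a scalar function of time, an array with one value per step, or
    None for autonomous dynamics.  ``noise_std`` adds per-unit white noise.
    """

    T: float
    dt: Optional[float] = None
    x0: Union[np.ndarray, str] = "zero"
    x0_scale: float = 1.0
    input_signal: Union[None, Callable[[float], float], np.ndarray] = None
    noise_std: float = 0.0
    seed: Optional[int] = None
    record_every: int = 1

    def resolve_dt(self, tau: float) -> float:
        dt = tau / 20.0 if self.dt is None else float(self.dt)
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > tau / 10.0 + 1e-12:
            raise ValueError(f"dt={dt} exceeds the cap tau/10={tau / 10.0}")
        return dt


@dataclass
class Trajectory:
    """Time-indexed network state: times (T,) and activations x (T, N)."""

    times: np.ndarray
    x: np.ndarray
    model: Optional[NetworkModel] = None

    def __post_init__(self) -> None:
        if len(self.times) != self.x.shape[0]:
            raise ValueError("times and x must have the same number of rows")


@dataclass
class LatentTrajectory:
    kappa_r: np.ndarray
    kappa_I: Optional[np.ndarray]
    kappa_rec: np.ndarray


@dataclass
class DimensionalityReport:
    participation_ratio: float
    pca_variance_fractions: np.ndarray
    alignment_m: np.ndarray
    alignment_I: Optional[np.ndarray]


def _initial_state(config: SimulationConfig, N: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.x0, str):
        if config.x0 == "zero":
            return np.zeros(N)
        if config.x0 == "random":
            return config.x0_scale * rng.standard_normal(N)
        raise ValueError(f"unknown x0 preset: {config.x0!r}")
    x0 = np.asarray(config.x0, dtype=float)
    if x0.shape != (N,):
        raise ValueError("x0 must be a length-N vector")
    return x0.copy()


def simulate(
    model: NetworkModel,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Forward-Euler integration of the rate equation.

    Per step: ``x += (dt/tau) (-x + W phi(x) + I u_t) + noise_std
    sqrt(dt)/tau * xi`` with xi iid standard normal.  Raises
    :class:`SimulationDivergence` if the state leaves float range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.resolve_dt(model.tau)
    n_steps = int(round(config.T / dt))
    N = model.N
    x = _initial_state(config, N, rng)

    u = config.input_signal
    if isinstance(u, np.ndarray) and len(u) < n_steps:
        raise ValueError("input_signal array shorter than the number of steps")

    rec = range(0, n_steps + 1, config.record_every)
    times = np.empty(len(rec))
    xs = np.empty((len(rec), N))
    times[0], xs[0] = 0.0, x
    k = 1
    alpha = dt / model.tau
    noise_scale = config.noise_std * np.sqrt(dt) / model.tau
    for step in range(n_steps):
        drive = -x + model.recurrent_drive(x)
        if u is not None and model.I is not None:
            u_t = u[step] if isinstance(u, np.ndarray) else u(step * dt)
            drive = drive + model.I * u_t
        x = x + alpha * drive
        if noise_scale > 0:
            x = x + noise_scale * rng.standard_normal(N)
        if step % 50 == 0 or step == n_steps - 1:
            if not np.isfinite(x).all():
                raise SimulationDivergence(
                    f"non-finite state at step {step + 1} (t = {(step + 1) * dt:g})"
                )
        if (step + 1) % config.record_every == 0 and k < len(rec):
            times[k] = (step + 1) * dt
            xs[k] = x
            k += 1
    return Trajectory(times=times[:k], x=xs[:k], model=model)


def latent_projections(
    traj: Trajectory,
    m: np.ndarray,
    I: Optional[np.ndarray],
    n: np.ndarray,
) -> LatentTrajectory:
    """Project activity on the m and I axes and compute the recurrent drive.

    kappa_r(t) = m^T x(t) / ||m||^2, kappa_I(t) = I^T x(t) / ||I||^2 (when
    an input pattern is supplied), kappa_rec(t) = (1/N) sum_j n_j phi(x_j).
    """
    m = np.asarray(m, float)
    n = np.asarray(n, float)
    m_norm2 = float(m @ m)
    if m_norm2 == 0.0:
        raise ValueError("m must have non-zero norm")
    kappa_r = traj.x @ m / m_norm2
    kappa_I = None
    if I is not None:
        I = np.asarray(I, float)
        I_norm2 = float(I @ I)
        if I_norm2 == 0.0:
            raise ValueError("I must have non-zero norm")
        kappa_I = traj.x @ I / I_norm2
    kappa_rec = np.tanh(traj.x) @ n / len(n)
    return LatentTrajectory(kappa_r=kappa_r, kappa_I=kappa_I, kappa_rec=kappa_rec)


def participation_ratio(traj: Union[Trajectory, np.ndarray]) -> float:
    """Effective dimensionality (sum lambda)^2 / sum lambda^2 of the
    activation covariance over time."""
    x = traj.x if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if x.shape[0] < 2:
        raise ValueError("need at least two time samples")
    centred = x - x.mean(axis=0)
    # covariance eigenvalues via singular values of the centred trajectory
    sv = np.linalg.svd(centred, compute_uv=False)
    lam = sv**2
    total = lam.sum()
    if total == 0.0:
        raise ValueError("trajectory has zero variance")
    return float(total**2 / (lam**2).sum())


def pca_alignment(
    traj: Trajectory,
    m: np.ndarray,
    I: Optional[np.ndarray] = None,
    k: int = 3,
) -> DimensionalityReport:
    """PCA of the trajectory: variance fractions of the first k components
    and their absolute cosine similarity with m (and I when given)."""
    from sklearn.decomposition import PCA

    x = traj.x
    if k > x.shape[1]:
        raise ValueError("k cannot exceed the number of units")
    n_comp = min(k, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(x)
    fractions = np.zeros(k)
    fractions[:n_comp] = pca.explained_variance_ratio_
    comps = pca.components_
    m_hat = np.asarray(m, float)
    m_hat = m_hat / np.linalg.norm(m_hat)
    align_m = np.zeros(k)
    align_m[:n_comp] = np.abs(comps @ m_hat)
    align_I = None
    if I is not None:
        I_hat = np.asarray(I, float)
        I_hat = I_hat / np.linalg.norm(I_hat)
        align_I = np.zeros(k)
        align_I[:n_comp] = np.abs(comps @ I_hat)
    return DimensionalityReport(
        participation_ratio=participation_ratio(traj),
        pca_variance_fractions=fractions,
        alignment_m=align_m,
        alignment_I=align_I,
    )


def find_fixed_point(
    model: NetworkModel,
    direction: np.ndarray,
    sign: int = 1,
    eps: float = 1e-2,
    tol: float = 1e-6,
    t_max: Optional[float] = None,
    dt: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Locate an autonomous equilibrium by integrating from a small kick.

    Starts at ``sign * eps * direction`` and integrates the autonomous
    dynamics until ``max|dx/dt| < tol`` (per unit time).  Returns the
    equilibrium state and its kappa_r along ``direction``.  For a dense
    rank-one network the result satisfies the scalar self-consistency
    ``kappa = (1/N) sum_j n_j phi(kappa m_j)``.
    """
    direction = np.asarray(direction, float)
    norm2 = float(direction @ direction)
    if norm2 == 0.0:
        raise ValueError("direction must have non-zero norm")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    tau = model.tau
    dt = tau / 20.0 if dt is None else dt
    if t_max is None:
        t_max = 500.0 * tau
    x = sign * eps * direction
    t = 0.0
    alpha = dt / tau
    while t < t_max:
        drive = -x + model.recurrent_drive(x)
        if np.abs(drive).max() / tau < tol:
            return x, float(direction @ x / norm2)
        x = x + alpha * drive
        if not np.isfinite(x).all():
            raise SimulationDivergence(f"non-finite state at t = {t:g}")
        t += dt
    raise FixedPointNotConverged(
        f"no equilibrium within t_max = {t_max:g} (tol = {tol:g})"
    )


def draw_input_vector(
    n: np.ndarray, sigma_n_I: float, rng: np.random.Generator, sigma2: float
) -> np.ndarray:
    """Draw a unit-variance input pattern with covariance sigma_n_I with n.

    I = (sigma_n_I / sigma2) n + b xi with xi iid standard normal and b
    chosen so Var(I_i) = 1; requires sigma_n_I^2 <= sigma2.
    """
    if sigma_n_I < 0:
        raise ValueError("sigma_n_I must be non-negative")
    if sigma_n_I**2 > sigma2:
        raise ValueError("sigma_n_I^2 must not exceed sigma2 for unit-variance I")
    a = sigma_n_I / sigma2
    b = np.sqrt(1.0 - sigma_n_I**2 / sigma2)
    return a * np.asarray(n, float) + b * rng.standard_normal(len(n))


def save_trajectory(path, traj: Trajectory, latents: Optional[LatentTrajectory] = None):
    """Persist a trajectory (and latents, when given) as an array bundle."""
    arrays = {"times": traj.times, "x": traj.x}
    if latents is not None:
        arrays["kappa_r"] = latents.kappa_r
        arrays["kappa_rec"] = latents.kappa_rec
        if latents.kappa_I is not None:
            arrays["kappa_I"] = latents.kappa_I
    np.savez_compressed(path, **arrays)
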