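"""Go-Nogo evidence integration in sparse rank-one networks.

The task: report whether the mean magnitude c̄ of a fluctuating scalar
stimulus exceeds a threshold.  The connectivity solution is purely
geometric: the input pattern is fed into the recurrence by setting
``I = n``, the readout taps the recurrent axis by setting ``w = m``, and
m and n are given a common component (overlap σ_mn) large enough that the
outlier λ₁ = C σ_mn exceeds unity, creating a bistable pair of fixed
points along m.  Each trial starts in the lower (negative-readout) fixed
point; integrating a sufficiently strong stimulus drives the network over
the separatrix into the upper fixed point, switching the readout
``z(t) = (1/N) w^T phi(x(t))`` to positive.  The psychometric curve is the
fraction of positive decisions (mean readout over the final decision
window) across repeated noisy trials, as a function of c̄.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityVectors,
    WeightMatrix,
    build_gaussian,
    build_rank_one,
    draw_connectivity_vectors,
    draw_mask,
    sparsify,
)
from .dynamics import NetworkModel, SimulationConfig, Trajectory, find_fixed_point, simulate

__all__ = [
    "TaskNetwork",
    "TrialConfig",
    "TrialResult",
    "PsychometricCurve",
    "build_task_network",
    "build_control_network",
    "run_trial",
    "decision",
    "psychometric_curve",
    "locate_switch_threshold",
    "crossing_at_half",
    "CONTROL_PRESET",
]

# dense low-rank-plus-Gaussian control preset (convenience constructor only;
# its spectral equivalence to the sparse task network is not certified)
CONTROL_PRESET = {"sigma2": 9.0, "sigma_mn": 2.3, "g": 1.3}


@dataclass
class TaskNetwork:
    """A network wired for the Go-Nogo task: I = n, w = m."""

    vectors: ConnectivityVectors
    I: np.ndarray
    w: np.ndarray
    W: WeightMatrix
    N: int
    sigma2: float
    sigma_mn: float
    C: Optional[int] = None
    g: Optional[float] = None
    tau: float = 100.0
    _model: Optional[NetworkModel] = field(default=None, repr=False)
    _lower_fp: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def theory_outlier(self) -> float:
        """λ₁ = C σ_mn for the sparse rescaled network, σ_mn for the dense
        scaled control."""
        if self.C is not None:
            return self.C * self.sigma_mn
        return self.sigma_mn

    @property
    def model(self) -> NetworkModel:
        if self._model is None:
            self._model = NetworkModel(W=self.W, I=self.I, tau=self.tau)
        return self._model

    def lower_fixed_point(self) -> np.ndarray:
        """The negative-kappa_r equilibrium (cached)."""
        if self._lower_fp is None:
            x_star, kappa = find_fixed_point(self.model, self.vectors.m, sign=-1)
            if kappa > 0:
                raise RuntimeError("lower fixed point search converged to kappa_r > 0")
            self._lower_fp = x_star
        return self._lower_fp


def build_task_network(
    N: int,
    C: int,
    sigma2: float,
    sigma_mn: float,
    rng: np.random.Generator,
    tau: float = 100.0,
) -> TaskNetwork:
    """Sparse rescaled rank-one task network with C non-zero inputs per unit."""
    vectors = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
    dense = build_rank_one(vectors, rescaled=True)
    mask = draw_mask(N, rng, scheme="fixed_in_degree", C=C)
    W = sparsify(dense, mask)
    return TaskNetwork(
        vectors=vectors,
        I=vectors.n.copy(),
        w=vectors.m.copy(),
        W=W,
        N=N,
        sigma2=sigma2,
        sigma_mn=sigma_mn,
        C=C,
        tau=tau,
    )


def build_control_network(
    N: int,
    sigma2: float,
    sigma_mn: float,
    g: float,
    rng: np.random.Generator,
    tau: float = 100.0,
) -> TaskNetwork:
    """Dense control: Gaussian coupling of strength g plus a dense scaled
    rank-one part (m n^T / N) with the same task geometry (I = n, w = m).

    The outlier is σ_mn and the eigenvalue disk has radius g; bistability
    requires σ_mn > 1.
    """
    if g < 0:
        raise ValueError("g must be non-negative")
    vectors = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
    gauss = build_gaussian(N, g, rng)
    dense = build_rank_one(vectors, rescaled=False)
    W = WeightMatrix(W=gauss.W + dense.W, provenance="composite", vectors=vectors, g=g)
    return TaskNetwork(
        vectors=vectors,
        I=vectors.n.copy(),
        w=vectors.m.copy(),
        W=W,
        N=N,
        sigma2=sigma2,
        sigma_mn=sigma_mn,
        g=g,
        tau=tau,
    )


@dataclass
class TrialConfig:
    """One stimulus presentation.

    c(t) = c_bar + white fluctuations of amplitude ``c_noise_std`` (entering
    with Euler-Maruyama sqrt(dt) scaling through the input pattern), plus
    independent per-unit noise ``unit_noise_std``.  The decision is the sign
    of the mean readout over the final ``decision_window``.
    """

    c_bar: float
    c_noise_std: float = 0.0
    unit_noise_std: float = 0.0
    duration: float = 500.0
    decision_window: float = 50.0
    dt: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.decision_window > self.duration:
            raise ValueError("decision window cannot exceed the trial duration")


@dataclass
class TrialResult:
    times: np.ndarray
    z: np.ndarray
    trajectory: Optional[Trajectory] = None


def run_trial(
    net: TaskNetwork,
    trial: TrialConfig,
    rng: Optional[np.random.Generator] = None,
    keep_trajectory: bool = False,
) -> TrialResult:
    """Simulate one trial from the lower fixed point; returns the readout
    z(t) = (1/N) w^T phi(x(t))."""
    if rng is None:
        rng = np.random.default_rng(trial.seed)
    dt = net.tau / 20.0 if trial.dt is None else trial.dt
    n_steps = int(round(trial.duration / dt))
    # white stimulus fluctuation: the per-step input term (dt/tau) I u_t
    # acquires sqrt(dt) scaling when u_t = c_bar + sigma_c xi / sqrt(dt)
    if trial.c_noise_std > 0:
        u = trial.c_bar + trial.c_noise_std * rng.standard_normal(n_steps) / np.sqrt(dt)
    else:
        u = np.full(n_steps, float(trial.c_bar))
    config = SimulationConfig(
        T=trial.duration,
        dt=dt,
        x0=net.lower_fixed_point(),
        input_signal=u,
        noise_std=trial.unit_noise_std,
    )
    traj = simulate(net.model, config, rng=rng)
    z = np.tanh(traj.x) @ net.w / net.N
    return TrialResult(times=traj.times, z=z, trajectory=traj if keep_trajectory else None)


def decision(times: np.ndarray, z: np.ndarray, decision_window: float) -> str:
    """Go/Nogo decision: sign of the mean readout over the final window;
    an exact tie counts as negative (conservative Nogo default)."""
    times = np.asarray(times, float)
    z = np.asarray(z, float)
    if decision_window > times[-1] - times[0]:
        raise ValueError("decision window longer than the readout series")
    sel = times >= times[-1] - decision_window
    return "positive" if float(z[sel].mean()) > 0.0 else "negative"


@dataclass
class PsychometricCurve:
    """Fraction of positive decisions per mean stimulus strength."""

    c_bar: np.ndarray
    proportion_positive: np.ndarray
    repeats: int
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"c_bar": self.c_bar, "proportion": self.proportion_positive}
        )
        df["repeats"] = self.repeats
        for k, v in self.params.items():
            df[k] = v
        return df


def psychometric_curve(
    net: TaskNetwork,
    c_bar_grid: np.ndarray,
    repeats: int = 50,
    rng: Optional[np.random.Generator] = None,
    trial: Optional[TrialConfig] = None,
) -> PsychometricCurve:
    """Run ``repeats`` noisy trials per stimulus strength and tally the
    fraction of positive decisions."""
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    if trial is None:
        trial = TrialConfig(c_bar=0.0)
    c_bar_grid = np.asarray(c_bar_grid, float)
    props = np.empty(len(c_bar_grid))
    for i, c in enumerate(c_bar_grid):
        pos = 0
        for _ in range(repeats):
            res = run_trial(net, replace(trial, c_bar=float(c)), rng=rng)
            if decision(res.times, res.z, trial.decision_window) == "positive":
                pos += 1
        props[i] = pos / repeats
    return PsychometricCurve(
        c_bar=c_bar_grid,
        proportion_positive=props,
        repeats=repeats,
        params={
            "N": net.N,
            "C": net.C,
            "sigma2": net.sigma2,
            "sigma_mn": net.sigma_mn,
            "g": net.g,
        },
    )


def locate_switch_threshold(
    net: TaskNetwork,
    lo: float,
    hi: float,
    tol: float = 1e-3,
    trial: Optional[TrialConfig] = None,
) -> float:
    """Bisection on noise-free trials for the stimulus strength at which
    the readout switches from negative to positive.

    The threshold is not a free parameter — it emerges from the bistability
    of the autonomous dynamics.  ``lo`` must produce a negative decision and
    ``hi`` a positive one.
    """
    if trial is None:
        trial = TrialConfig(c_bar=0.0)
    base = replace(trial, c_noise_std=0.0, unit_noise_std=0.0)

    def outcome(c: float) -> str:
        res = run_trial(net, replace(base, c_bar=c), rng=np.random.default_rng(0))
        return decision(res.times, res.z, base.decision_window)

    if outcome(lo) != "negative":
        raise ValueError(f"lo = {lo} already yields a positive decision")
    if outcome(hi) != "positive":
        raise ValueError(f"hi = {hi} does not yield a positive decision")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) == "positive":
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def crossing_at_half(curve: PsychometricCurve) -> float:
    """Stimulus strength at which the psychometric curve crosses 0.5
    (linear interpolation between the bracketing grid points)."""
    c, p = curve.c_bar, curve.proportion_positive
    above = np.nonzero(p >= 0.5)[0]
    if len(above) == 0 or above[0] == 0:
        raise ValueError("curve does not cross 0.5 inside the grid")
    j = above[0]
    i = j - 1
    if p[j] == p[i]:
        return float(c[j])
    return float(c[i] + (0.5 - p[i]) * (c[j] - c[i]) / (p[j] - p[i]))
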