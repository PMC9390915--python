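"""Dynamical regimes of autonomous sparsified rank-one networks.

Three regimes are distinguished by the relative position of the spectral
outlier λ₁ and the bulk radius R with respect to the instability at unity:

* **decaying** — max(λ₁, R) ≤ 1: the zero fixed point is stable and all
  activity dies out.
* **structured_stationary** — λ₁ > 1 and λ₁ ≥ R: the outlier leads the
  instability and the network settles in a heterogeneous fixed point
  aligned with m (one of two, by symmetry).
* **chaotic** — R > 1 and R > λ₁: the bulk leads the instability, giving
  sustained irregular fluctuations.

In the high-sparsity (rescaled) branch λ₁ = C σ_mn and
R = σ² sqrt(C (N - C) / N), so the regime at fixed (C, N) is dictated
solely by the variance σ² and covariance σ_mn of the connectivity vectors
— the phase diagram lives in the (σ², σ_mn) plane.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .connectivity import draw_connectivity_vectors, build_rank_one, draw_mask, sparsify
from .dynamics import (
    LatentTrajectory,
    NetworkModel,
    SimulationConfig,
    Trajectory,
    latent_projections,
    simulate,
)
from .spectra import SpectralTheory, rank_one_theory

__all__ = [
    "RegimeLabel",
    "RegimeCriteria",
    "PhaseDiagram",
    "classify_regime",
    "phase_diagram",
    "empirical_regime",
    "simulate_autonomous_regime",
    "regime_concordance",
]


class RegimeLabel(str, enum.Enum):
    DECAYING = "decaying"
    STRUCTURED_STATIONARY = "structured_stationary"
    CHAOTIC = "chaotic"


def classify_regime(theory: SpectralTheory) -> RegimeLabel:
    """Label a parameter point from its analytic (outlier, bulk radius).

    Ties λ₁ = R > 1 go to structured_stationary: chaos requires the bulk
    to strictly surpass the outlier.
    """
    lam, R = theory.outlier, theory.bulk_radius
    if max(lam, R) <= 1.0:
        return RegimeLabel.DECAYING
    if lam >= R:
        return RegimeLabel.STRUCTURED_STATIONARY
    return RegimeLabel.CHAOTIC


@dataclass(frozen=True)
class PhaseDiagram:
    """Regime labels over a (sigma2, sigma_mn) grid at fixed (C, N)."""

    sigma2_grid: np.ndarray
    sigma_mn_grid: np.ndarray
    labels: np.ndarray  # shape (len(sigma_mn_grid), len(sigma2_grid)), dtype object
    outlier: np.ndarray
    bulk_radius: np.ndarray
    C: int
    N: int

    @property
    def boundaries(self) -> dict:
        """Analytic boundary curves of the diagram.

        outlier_unity: sigma_mn = 1/C; bulk_unity: sigma2 = 1/sqrt(C(N-C)/N);
        structured_chaotic: sigma2 = C sigma_mn / sqrt(C(N-C)/N).
        """
        scale = np.sqrt(self.C * (self.N - self.C) / self.N)
        return {
            "outlier_unity_sigma_mn": 1.0 / self.C,
            "bulk_unity_sigma2": 1.0 / scale,
            "structured_chaotic_sigma2_per_sigma_mn": self.C / scale,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (sigma2, sigma_mn) cell."""
        rows = []
        for i, smn in enumerate(self.sigma_mn_grid):
            for j, s2 in enumerate(self.sigma2_grid):
                rows.append(
                    {
                        "sigma2": s2,
                        "sigma_mn": smn,
                        "C": self.C,
                        "N": self.N,
                        "label": self.labels[i, j],
                        "outlier_theory": self.outlier[i, j],
                        "radius_theory": self.bulk_radius[i, j],
                    }
                )
        return pd.DataFrame(rows)


def phase_diagram(
    sigma2_grid: np.ndarray, sigma_mn_grid: np.ndarray, C: int, N: int
) -> PhaseDiagram:
    """Label every (sigma2, sigma_mn) cell via the rescaled-branch theory."""
    sigma2_grid = np.asarray(sigma2_grid, float)
    sigma_mn_grid = np.asarray(sigma_mn_grid, float)
    if (sigma2_grid <= 0).any() or (sigma_mn_grid < 0).any():
        raise ValueError("grids must be positive (sigma_mn non-negative)")
    if C > N:
        raise ValueError("C cannot exceed N")
    scale = np.sqrt(C * (N - C) / N)
    outlier = np.tile(C * sigma_mn_grid[:, None], (1, len(sigma2_grid)))
    radius = np.tile(sigma2_grid[None, :] * scale, (len(sigma_mn_grid), 1))
    labels = np.empty(outlier.shape, dtype=object)
    for i in range(outlier.shape[0]):
        for j in range(outlier.shape[1]):
            labels[i, j] = classify_regime(
                SpectralTheory(outlier=outlier[i, j], bulk_radius=radius[i, j])
            ).value
    return PhaseDiagram(
        sigma2_grid=sigma2_grid,
        sigma_mn_grid=sigma_mn_grid,
        labels=labels,
        outlier=outlier,
        bulk_radius=radius,
        C=C,
        N=N,
    )


@dataclass(frozen=True)
class RegimeCriteria:
    """Thresholds for the empirical regime diagnostic.

    activity_floor: RMS activity below which the network counts as decayed.
    cv_threshold: temporal coefficient of variation of kappa_r below which
    the state counts as stationary.  alignment_threshold: minimum absolute
    cosine similarity between the time-averaged state and m for a stationary
    state to count as structured — because every row of the sparse rank-one
    coupling is proportional to m_i, bulk-generated frozen states also carry
    a non-zero kappa_r, but their activity pattern x_i = m_i c_i has
    heterogeneous c and is only weakly aligned with m itself.  transient:
    initial fraction of the trajectory discarded before evaluation.
    min_duration_tau: required post-transient duration in units of tau.
    """

    activity_floor: float = 1e-3
    cv_threshold: float = 0.05
    alignment_threshold: float = 0.9
    transient: float = 0.25
    min_duration_tau: float = 50.0


def empirical_regime(
    traj: Trajectory,
    latents: LatentTrajectory,
    tau: Optional[float] = None,
    criteria: RegimeCriteria = RegimeCriteria(),
    m: Optional[np.ndarray] = None,
) -> RegimeLabel:
    """Diagnose the regime from a simulated autonomous trajectory.

    After discarding the transient: decaying if the RMS activity falls
    below the floor; structured_stationary if |kappa_r| settles to a
    non-zero constant (temporal CV below threshold) AND the time-averaged
    state aligns with m; chaotic otherwise (sustained irregular activity,
    or a stationary bulk-generated state not aligned with m).

    ``m`` is taken from the trajectory's model when not given; without it
    the alignment check is skipped.
    """
    if tau is None:
        tau = traj.model.tau if traj.model is not None else 100.0
    t0 = int(criteria.transient * len(traj.times))
    window_t = traj.times[-1] - traj.times[t0]
    if window_t < criteria.min_duration_tau * tau:
        raise ValueError(
            f"trajectory too short: {window_t:g} time units after transient, "
            f"need >= {criteria.min_duration_tau * tau:g}"
        )
    x = traj.x[t0:]
    rms = float(np.sqrt((x**2).mean()))
    if rms < criteria.activity_floor:
        return RegimeLabel.DECAYING
    if m is None and traj.model is not None:
        W = traj.model.W
        if hasattr(W, "vectors") and W.vectors is not None:
            m = W.vectors.m
    kr = latents.kappa_r[t0:]
    mean_kr = float(np.abs(kr.mean()))
    stationary = (
        mean_kr > criteria.activity_floor
        and float(kr.std()) / mean_kr < criteria.cv_threshold
    )
    if stationary and m is not None:
        xbar = x.mean(axis=0)
        cos = abs(float(xbar @ m)) / (np.linalg.norm(xbar) * np.linalg.norm(m))
        stationary = cos >= criteria.alignment_threshold
    if stationary:
        return RegimeLabel.STRUCTURED_STATIONARY
    return RegimeLabel.CHAOTIC


def simulate_autonomous_regime(
    sigma2: float,
    sigma_mn: float,
    C: int,
    N: int,
    rng: np.random.Generator,
    tau: float = 100.0,
    duration_tau: float = 80.0,
    criteria: RegimeCriteria = RegimeCriteria(),
) -> tuple[RegimeLabel, RegimeLabel]:
    """Build one rescaled sparse rank-one network, simulate autonomously
    from a random state, and return (theory label, empirical label)."""
    vectors = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
    W = sparsify(
        build_rank_one(vectors, rescaled=True),
        draw_mask(N, rng, scheme="fixed_in_degree", C=C),
    )
    theory = rank_one_theory(sigma2, sigma_mn, N=N, C=C, rescaled=True)
    model = NetworkModel(W=W, tau=tau)
    config = SimulationConfig(
        T=duration_tau * tau, x0="random", x0_scale=0.5, seed=int(rng.integers(2**31))
    )
    traj = simulate(model, config, rng=rng)
    latents = latent_projections(traj, vectors.m, None, vectors.n)
    return classify_regime(theory), empirical_regime(traj, latents, tau=tau, criteria=criteria)


def regime_concordance(
    sigma2_values: np.ndarray,
    sigma_mn_values: np.ndarray,
    C: int,
    N: int,
    seeds: list[int],
    boundary_margin: float = 0.1,
    tau: float = 100.0,
    duration_tau: float = 80.0,
) -> pd.DataFrame:
    """Theory vs simulation labels over a parameter grid.

    Cells whose theory point lies within ``boundary_margin`` (relative) of
    any regime boundary are flagged ``near_boundary`` so that finite-size
    blurring can be excluded from agreement statistics.
    """
    rows = []
    for s2 in sigma2_values:
        for smn in sigma_mn_values:
            th = rank_one_theory(s2, smn, N=N, C=C, rescaled=True)
            lam, R = th.outlier, th.bulk_radius
            near = (
                abs(lam - 1.0) < boundary_margin
                or abs(R - 1.0) < boundary_margin
                or abs(lam - R) < boundary_margin * max(lam, R, 1.0)
            )
            for seed in seeds:
                rng = np.random.default_rng([seed, int(1e6 * s2), int(1e6 * smn)])
                theory_label, empirical_label = simulate_autonomous_regime(
                    s2, smn, C, N, rng, tau=tau, duration_tau=duration_tau
                )
                rows.append(
                    {
                        "sigma2": s2,
                        "sigma_mn": smn,
                        "C": C,
                        "N": N,
                        "seed": seed,
                        "outlier_theory": lam,
                        "radius_theory": R,
                        "near_boundary": near,
                        "theory_label": theory_label.value,
                        "empirical_label": empirical_label.value,
                        "agree": theory_label == empirical_label,
                    }
                )
    return pd.DataFrame(rows)
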