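"""Reproducible experiment drivers.

Each experiment is a pure function of an :class:`ExperimentConfig`: a name,
a parameter dict, a base seed and an output directory.  Every random draw
is derived from ``(base_seed, instance_index)`` through
``numpy.random.default_rng([...])``, so re-running a config reproduces all
stochastic outputs bitwise.  Outputs are tidy CSV tables, compressed array
bundles and a JSON manifest (parameters, seeds, versions, wall time).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .connectivity import (
    build_gaussian,
    build_rank_one,
    draw_connectivity_vectors,
    draw_mask,
    save_weight_matrix,
    sparsify,
)
from .dynamics import (
    NetworkModel,
    SimulationConfig,
    draw_input_vector,
    latent_projections,
    participation_ratio,
    save_trajectory,
    simulate,
)
from .regimes import empirical_regime, phase_diagram, rank_one_theory
from .spectra import (
    compute_spectrum,
    estimate_outlier_and_bulk,
    theory_gaussian_radius,
)
from .task import TrialConfig, build_task_network, psychometric_curve, run_trial

logger = logging.getLogger("sparserank")


def _version() -> str:
    from sparserank import __version__

    return __version__

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "generate_fixtures",
    "EXPERIMENTS",
    "spectrum_sweep",
    "input_driven_point",
]


@dataclass
class ExperimentConfig:
    """A named experiment with parameters, a mandatory seed and an output
    directory; serialises round-trip through JSON."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; known: {sorted(EXPERIMENTS)}"
            )
        bad = set(self.params) - set(_ALLOWED_PARAMS[self.name])
        if bad:
            raise ValueError(
                f"invalid config keys for {self.name!r}: {sorted(bad)}; "
                f"allowed: {sorted(_ALLOWED_PARAMS[self.name])}"
            )
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer (seeds are mandatory)")


def _rng(base_seed: int, *indices: int) -> np.random.Generator:
    """Generator for one (base_seed, instance...) draw path."""
    return np.random.default_rng([int(base_seed)] + [int(i) for i in indices])


# ---------------------------------------------------------------------------
# spectrum sweep


def spectrum_sweep(
    kind: str,
    N: int,
    base_seed: int,
    s_grid: Optional[list] = None,
    C_grid: Optional[list] = None,
    instances: int = 50,
    g: float = 1.0,
    sigma2: float = 16.0,
    sigma_mn: float = 4.0,
    rescaled: bool = False,
    scheme: str = "bernoulli",
) -> pd.DataFrame:
    """Empirical vs theoretical spectral radius / outlier over a sparsity grid.

    ``kind`` is ``gaussian`` or ``rank_one``.  Sparsity varies either over a
    fraction grid ``s_grid`` (Bernoulli masks) or a connection-count grid
    ``C_grid`` (fixed in-degree masks).
    """
    if kind not in ("gaussian", "rank_one"):
        raise ValueError("kind must be 'gaussian' or 'rank_one'")
    points = [("s", s) for s in (s_grid or [])] + [("C", c) for c in (C_grid or [])]
    if not points:
        raise ValueError("provide s_grid or C_grid")
    rows = []
    for p, (axis, value) in enumerate(points):
        for inst in range(instances):
            rng = _rng(base_seed, p, inst)
            if axis == "s":
                mask = draw_mask(N, rng, scheme=scheme, s=float(value))
                s, C = float(value), None
            else:
                mask = draw_mask(N, rng, scheme="fixed_in_degree", C=int(value))
                s, C = 1.0 - int(value) / N, int(value)
            if kind == "gaussian":
                W = sparsify(build_gaussian(N, g, rng), mask)
                theory = None
                radius_theory = theory_gaussian_radius(g, s)
                outlier_theory = np.nan
            else:
                vec = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
                W = sparsify(build_rank_one(vec, rescaled=rescaled), mask)
                theory = rank_one_theory(
                    sigma2, sigma_mn, N=N, s=None if C else s, C=C, rescaled=rescaled
                )
                radius_theory = theory.bulk_radius
                outlier_theory = theory.outlier
            report = estimate_outlier_and_bulk(compute_spectrum(W), theory)
            rows.append(
                {
                    axis: value,
                    "N": N,
                    "g": g if kind == "gaussian" else np.nan,
                    "sigma2": np.nan if kind == "gaussian" else sigma2,
                    "sigma_mn": np.nan if kind == "gaussian" else sigma_mn,
                    "instance": inst,
                    "radius_hat": report.bulk_radius_hat,
                    "outlier_hat": report.outlier_hat,
                    "outlier_measurable": report.outlier_measurable,
                    "radius_theory": radius_theory,
                    "outlier_theory": outlier_theory,
                }
            )
        logger.info("spectrum_sweep %s=%s done (%d instances)", axis, value, instances)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# input-driven structure (step input along I with overlap sigma_nI with n)


def input_driven_point(
    kind: str,
    value: float,
    N: int,
    sigma2: float,
    sigma_nI: float,
    rng: np.random.Generator,
    tau: float = 100.0,
    u_amplitude: float = 1.0,
    lead_tau: float = 2.0,
    step_tau: float = 5.0,
    washout_tau: float = 5.0,
) -> dict:
    """One step-input simulation; returns terminal |kappa_r| (at the end of
    the step window) and the participation ratio over the stimulus period.

    ``kind='sparse'`` builds the rescaled rank-one network with C = value
    non-zero inputs per unit and zero m-n overlap; ``kind='gaussian'``
    builds the dense scaled rank-one plus a Gaussian component of strength
    g = value.
    """
    vectors = draw_connectivity_vectors(N, sigma2, 0.0, rng)
    if kind == "sparse":
        W = sparsify(
            build_rank_one(vectors, rescaled=True),
            draw_mask(N, rng, scheme="fixed_in_degree", C=int(value)),
        )
    elif kind == "gaussian":
        gauss = build_gaussian(N, float(value), rng)
        dense = build_rank_one(vectors, rescaled=False)
        from .connectivity import WeightMatrix

        W = WeightMatrix(
            W=gauss.W + dense.W, provenance="composite", vectors=vectors, g=float(value)
        )
    else:
        raise ValueError("kind must be 'sparse' or 'gaussian'")
    I = draw_input_vector(vectors.n, sigma_nI, rng, sigma2)
    model = NetworkModel(W=W, I=I, tau=tau)
    t_on, t_off = lead_tau * tau, (lead_tau + step_tau) * tau
    T = t_off + washout_tau * tau

    def u(t: float) -> float:
        return u_amplitude if t_on <= t < t_off else 0.0

    traj = simulate(model, SimulationConfig(T=T, input_signal=u))
    latents = latent_projections(traj, vectors.m, I, vectors.n)
    step_sel = (traj.times >= t_on) & (traj.times <= t_off)
    idx_end = int(np.nonzero(step_sel)[0][-1])
    from .dynamics import Trajectory

    pr = participation_ratio(Trajectory(times=traj.times[step_sel], x=traj.x[step_sel]))
    return {
        "kind": kind,
        "value": value,
        "terminal_abs_kappa_r": float(abs(latents.kappa_r[idx_end])),
        "participation_ratio": pr,
        "terminal_kappa_I": float(latents.kappa_I[idx_end]),
    }


def _input_driven_table(params: dict, base_seed: int) -> pd.DataFrame:
    N = params.get("N", 2000)
    sigma2 = params.get("sigma2", 0.043)
    sigma_nI = params.get("sigma_nI", 0.2)
    seeds = params.get("seeds_per_point", 10)
    rows = []
    points = [("sparse", c) for c in params.get("C_grid", [])] + [
        ("gaussian", g) for g in params.get("g_grid", [])
    ]
    for p, (kind, value) in enumerate(points):
        for inst in range(seeds):
            rng = _rng(base_seed, p, inst)
            row = input_driven_point(kind, value, N, sigma2, sigma_nI, rng)
            row.update({"N": N, "sigma2": sigma2, "sigma_nI": sigma_nI, "instance": inst})
            rows.append(row)
        logger.info("input_driven %s=%s done (%d seeds)", kind, value, seeds)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment registry and runner


def _run_spectrum(config: ExperimentConfig, outdir: Path) -> list[Path]:
    p = dict(config.params)
    df = spectrum_sweep(base_seed=config.seed, **p)
    out = outdir / "spectrum_sweep.csv"
    df.to_csv(out, index=False)
    return [out]

def _run_phase_diagram(config: ExperimentConfig, outdir: Path) -> list[Path]:
    p = config.params
    pd_ = phase_diagram(
        np.asarray(p["sigma2_grid"], float),
        np.asarray(p["sigma_mn_grid"], float),
        int(p["C"]),
        int(p["N"]),
    )
    out = outdir / "phase_diagram.csv"
    pd_.to_frame().to_csv(out, index=False)
    bout = outdir / "boundaries.json"
    bout.write_text(json.dumps(pd_.boundaries, indent=2, sort_keys=True))
    return [out, bout]

def _run_input_driven(config: ExperimentConfig, outdir: Path) -> list[Path]:
    df = _input_driven_table(config.params, config.seed)
    out = outdir / "input_driven.csv"
    df.to_csv(out, index=False)
    return [out]

def _run_autonomous(config: ExperimentConfig, outdir: Path) -> list[Path]:
    p = config.params
    rng = _rng(config.seed, 0)
    N, C = int(p.get("N", 1000)), int(p.get("C", 200))
    sigma2, sigma_mn = float(p["sigma2"]), float(p["sigma_mn"])
    tau = float(p.get("tau", 100.0))
    vectors = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
    W = sparsify(
        build_rank_one(vectors, rescaled=True),
        draw_mask(N, rng, scheme="fixed_in_degree", C=C),
    )
    model = NetworkModel(W=W, tau=tau)
    traj = simulate(
        model,
        SimulationConfig(
            T=float(p.get("duration_tau", 80.0)) * tau,
            x0="random",
            x0_scale=0.5,
            seed=int(rng.integers(2**31)),
        ),
        rng=rng,
    )
    latents = latent_projections(traj, vectors.m, None, vectors.n)
    label = empirical_regime(traj, latents, tau=tau)
    theory = rank_one_theory(sigma2, sigma_mn, N=N, C=C, rescaled=True)
    out = outdir / "trajectory.npz"
    save_trajectory(out, traj, latents)
    summary = outdir / "autonomous_summary.json"
    summary.write_text(
        json.dumps(
            {
                "empirical_label": label.value,
                "outlier_theory": theory.outlier,
                "radius_theory": theory.bulk_radius,
                "params": {"N": N, "C": C, "sigma2": sigma2, "sigma_mn": sigma_mn},
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [out, summary]

def _run_task(config: ExperimentConfig, outdir: Path) -> list[Path]:
    p = config.params
    rng = _rng(config.seed, 0)
    net = build_task_network(
        N=int(p.get("N", 2000)),
        C=int(p.get("C", 200)),
        sigma2=float(p.get("sigma2", 0.1)),
        sigma_mn=float(p.get("sigma_mn", 0.04)),
        rng=rng,
    )
    trial = TrialConfig(
        c_bar=0.0,
        c_noise_std=float(p.get("c_noise_std", 1.0)),
        unit_noise_std=float(p.get("unit_noise_std", 0.05)),
        duration=float(p.get("duration", 500.0)),
        decision_window=float(p.get("decision_window", 50.0)),
    )
    c_grid = np.asarray(p.get("c_bar_grid", np.linspace(1.0, 4.5, 8)), float)
    curve = psychometric_curve(
        net, c_grid, repeats=int(p.get("repeats", 50)), rng=_rng(config.seed, 1), trial=trial
    )
    out = outdir / "psychometric.csv"
    curve.to_frame().to_csv(out, index=False)
    # one sample trace above and one below the midpoint of the grid
    traces = {}
    for tag, c in (("low", c_grid[0]), ("high", c_grid[-1])):
        res = run_trial(
            net,
            TrialConfig(
                c_bar=float(c),
                c_noise_std=trial.c_noise_std,
                unit_noise_std=trial.unit_noise_std,
                duration=trial.duration,
                decision_window=trial.decision_window,
            ),
            rng=_rng(config.seed, 2),
        )
        traces[f"z_{tag}"] = res.z
        traces["times"] = res.times
    tout = outdir / "readout_traces.npz"
    np.savez_compressed(tout, **traces)
    return [out, tout]


EXPERIMENTS: dict[str, Callable[[ExperimentConfig, Path], list[Path]]] = {
    "spectrum_sweep": _run_spectrum,
    "phase_diagram": _run_phase_diagram,
    "input_driven": _run_input_driven,
    "autonomous": _run_autonomous,
    "task_psychometric": _run_task,
}

_ALLOWED_PARAMS = {
    "spectrum_sweep": {
        "kind", "N", "s_grid", "C_grid", "instances", "g", "sigma2", "sigma_mn",
        "rescaled", "scheme",
    },
    "phase_diagram": {"sigma2_grid", "sigma_mn_grid", "C", "N"},
    "input_driven": {"N", "sigma2", "sigma_nI", "seeds_per_point", "C_grid", "g_grid"},
    "autonomous": {"N", "C", "sigma2", "sigma_mn", "tau", "duration_tau"},
    "task_psychometric": {
        "N", "C", "sigma2", "sigma_mn", "c_bar_grid", "repeats", "c_noise_std",
        "unit_noise_std", "duration", "decision_window",
    },
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment; writes outputs, a log and a JSON manifest.

    Returns the manifest dict.  Identical configs produce bitwise-identical
    CSV and array outputs (the manifest's wall time is the only varying
    field).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "experiment.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.perf_counter()
    logger.info("experiment %s seed=%d params=%s", config.name, config.seed, config.params)
    try:
        outputs = EXPERIMENTS[config.name](config, outdir)
        wall = time.perf_counter() - t0
        manifest = {
            "experiment": config.name,
            "params": config.params,
            "seed": config.seed,
            "outputs": [p.name for p in outputs],
            "versions": {"sparserank": _version(), "numpy": np.__version__},
            "wall_time_s": wall,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        config.to_json(outdir / "config.json")
        logger.info("experiment %s finished in %.1fs", config.name, wall)
        return manifest
    except Exception:
        logger.exception("experiment %s failed", config.name)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# deterministic fixtures for offline testing


def generate_fixtures(size: str, seed: int, outdir: str | Path) -> dict:
    """Write small deterministic instances of every matrix type plus one
    short trajectory; returns a manifest of files and parameters."""
    N = {"tiny": 50, "small": 200}.get(size)
    if N is None:
        raise ValueError("size must be 'tiny' or 'small'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, 0)
    sigma2, sigma_mn, g, C = 1.0, 0.5, 1.0, max(2, N // 5)
    vectors = draw_connectivity_vectors(N, sigma2, sigma_mn, rng)
    files = {}
    files["gaussian"] = save_weight_matrix(build_gaussian(N, g, rng), outdir / "gaussian")
    files["rank_one_scaled"] = save_weight_matrix(
        build_rank_one(vectors, rescaled=False), outdir / "rank_one_scaled"
    )
    files["rank_one_rescaled"] = save_weight_matrix(
        build_rank_one(vectors, rescaled=True), outdir / "rank_one_rescaled"
    )
    mask = draw_mask(N, rng, scheme="fixed_in_degree", C=C)
    sparse = sparsify(build_rank_one(vectors, rescaled=False), mask)
    files["sparse_rank_one"] = save_weight_matrix(sparse, outdir / "sparse_rank_one")
    model = NetworkModel(W=sparse, I=vectors.n, tau=100.0)
    traj = simulate(
        model, SimulationConfig(T=300.0, x0="random", x0_scale=0.1, seed=seed)
    )
    latents = latent_projections(traj, vectors.m, vectors.n, vectors.n)
    save_trajectory(outdir / "trajectory.npz", traj, latents)
    files["trajectory"] = outdir / "trajectory.npz"
    manifest = {
        "size": size,
        "N": N,
        "seed": seed,
        "params": {"sigma2": sigma2, "sigma_mn": sigma_mn, "g": g, "C": C},
        "files": {k: str(v.name) for k, v in files.items()},
    }
    (outdir / "fixtures_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
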