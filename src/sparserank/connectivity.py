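"""Generative connectivity for sparsified low-rank recurrent networks.

This module builds the raw material every other module consumes:

* pairs of correlated connectivity vectors ``(m, n)`` with prescribed
  variance ``sigma2`` and covariance ``sigma_mn``,
* dense Gaussian coupling matrices with entrywise variance ``g**2 / N``,
* rank-one matrices in two scalings — the classical ``m_i n_j / N`` outer
  product and the rescaled ``m_i n_j`` form used in the high-sparsity limit,
* random binary sparsity masks (Bernoulli or fixed in/out-degree), and the
  elementwise sparsification ``W ⊙ X``.

All randomness flows through an explicit :class:`numpy.random.Generator`;
identical seeds and parameters yield bitwise-identical objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ConnectivityVectors",
    "SparsityMask",
    "WeightMatrix",
    "draw_connectivity_vectors",
    "build_gaussian",
    "build_rank_one",
    "draw_mask",
    "sparsify",
    "save_weight_matrix",
    "load_weight_matrix",
]


@dataclass(frozen=True)
class ConnectivityVectors:
    """A pair of correlated connectivity vectors.

    ``m`` is the right (output) pattern and ``n`` the left (input-selection)
    pattern of a rank-one coupling.  Entries of each are marginally
    ``N(0, sigma2)`` with population covariance ``cov(m_i, n_i) = sigma_mn``.
    """

    m: np.ndarray
    n: np.ndarray
    N: int
    sigma2: float
    sigma_mn: float

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        n = np.asarray(self.n, dtype=float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "n", n)
        if m.ndim != 1 or n.ndim != 1 or len(m) != len(n) or len(m) != self.N:
            raise ValueError("m and n must be 1-D vectors of length N")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not (0.0 <= self.sigma_mn <= self.sigma2):
            raise ValueError(
                f"sigma_mn must lie in [0, sigma2]; got sigma_mn={self.sigma_mn}, "
                f"sigma2={self.sigma2}"
            )

    @property
    def sample_overlap(self) -> float:
        """Realised normalised scalar product ``m^T n / N``."""
        return float(self.m @ self.n / self.N)


@dataclass(frozen=True)
class SparsityMask:
    """An N x N binary mask; 1 keeps a connection, 0 removes it.

    ``scheme`` is one of ``bernoulli``, ``fixed_in_degree`` (exactly C ones
    per row — C non-zero inputs per unit) or ``fixed_out_degree`` (exactly C
    ones per column).  ``s`` is the fraction of zeroed connections; for the
    fixed-degree schemes ``s = 1 - C/N`` exactly.
    """

    X: np.ndarray
    scheme: str
    s: float
    C: Optional[int] = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("mask must be a square matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "X", X.astype(np.uint8))
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("sparsity fraction s must lie in [0, 1]")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def density(self) -> float:
        """Realised fraction of retained connections."""
        return float(self.X.mean())


@dataclass(frozen=True)
class WeightMatrix:
    """An N x N coupling matrix with provenance tags.

    ``provenance`` records how W was built: ``gaussian``, ``rank_one_scaled``
    (``m_i n_j / N``), ``rank_one_rescaled`` (``m_i n_j``), ``composite``
    (Gaussian plus dense rank-one) or ``deflated``.  ``vectors`` and ``mask``
    are carried along when applicable; ``g`` is the Gaussian coupling
    strength when one was used.
    """

    W: np.ndarray
    provenance: str
    vectors: Optional[ConnectivityVectors] = None
    mask: Optional[SparsityMask] = None
    g: Optional[float] = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be a square matrix")
        object.__setattr__(self, "W", W)
        if self.mask is not None and self.mask.N != W.shape[0]:
            raise ValueError("mask dimension does not match W")

    @property
    def N(self) -> int:
        return self.W.shape[0]


def draw_connectivity_vectors(
    N: int, sigma2: float, sigma_mn: float, rng: np.random.Generator
) -> ConnectivityVectors:
    """Draw (m, n) from the three-vector construction.

    With x, y, z iid standard normal vectors,

        m = sqrt(sigma2 - sigma_mn) x + sqrt(sigma_mn) z
        n = sqrt(sigma2 - sigma_mn) y + sqrt(sigma_mn) z

    so each entry has variance ``sigma2`` and ``cov(m_i, n_i) = sigma_mn``.
    The covariance must satisfy ``0 <= sigma_mn <= sigma2``; at the upper
    boundary m == n elementwise.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not (0.0 <= sigma_mn <= sigma2):
        raise ValueError(
            f"sigma_mn must lie in [0, sigma2]; got sigma_mn={sigma_mn}, sigma2={sigma2}"
        )
    x = rng.standard_normal(N)
    y = rng.standard_normal(N)
    z = rng.standard_normal(N)
    a = np.sqrt(sigma2 - sigma_mn)
    b = np.sqrt(sigma_mn)
    m = a * x + b * z
    n = a * y + b * z
    return ConnectivityVectors(m=m, n=n, N=N, sigma2=sigma2, sigma_mn=sigma_mn)


def build_gaussian(N: int, g: float, rng: np.random.Generator) -> WeightMatrix:
    """Full-rank Gaussian coupling: entries iid ``N(0, g**2 / N)``."""
    if N < 2:
        raise ValueError("N must be at least 2")
    if g < 0:
        raise ValueError("coupling strength g must be non-negative")
    W = rng.normal(0.0, g / np.sqrt(N), size=(N, N))
    if g == 0.0:
        W = np.zeros((N, N))
    return WeightMatrix(W=W, provenance="gaussian", g=g)


def build_rank_one(vectors: ConnectivityVectors, rescaled: bool = False) -> WeightMatrix:
    """Rank-one coupling from a vector pair.

    ``rescaled=False`` gives the classical scaling ``W_ij = m_i n_j / N``
    whose single non-zero eigenvalue is ``m^T n / N``; ``rescaled=True``
    drops the 1/N and gives ``W_ij = m_i n_j``, the form whose sparsified
    spectrum stays finite when C is fixed and N grows.
    """
    outer = np.outer(vectors.m, vectors.n)
    if not rescaled:
        outer = outer / vectors.N
    provenance = "rank_one_rescaled" if rescaled else "rank_one_scaled"
    return WeightMatrix(W=outer, provenance=provenance, vectors=vectors)


def draw_mask(
    N: int,
    rng: np.random.Generator,
    *,
    scheme: str = "bernoulli",
    s: Optional[float] = None,
    C: Optional[int] = None,
) -> SparsityMask:
    """Draw a random binary sparsity mask.

    ``bernoulli`` keeps each connection independently with probability
    ``1 - s``.  ``fixed_in_degree`` keeps exactly C connections per row
    (inputs per unit), ``fixed_out_degree`` exactly C per column (outputs
    per unit); in both cases the surviving positions are sampled uniformly
    without replacement and ``s = 1 - C/N``.
    """
    if scheme == "bernoulli":
        if s is None:
            raise ValueError("bernoulli scheme requires s")
        if not (0.0 <= s <= 1.0):
            raise ValueError("s must lie in [0, 1]")
        X = (rng.random((N, N)) >= s).astype(np.uint8)
        return SparsityMask(X=X, scheme="bernoulli", s=float(s))
    if scheme in ("fixed_in_degree", "fixed_out_degree"):
        if C is None:
            raise ValueError(f"{scheme} scheme requires C")
        if not (1 <= C <= N):
            raise ValueError("C must satisfy 1 <= C <= N")
        # C smallest of N iid uniforms per row = uniform C-subset
        order = np.argpartition(rng.random((N, N)), C - 1, axis=1)[:, :C]
        X = np.zeros((N, N), dtype=np.uint8)
        np.put_along_axis(X, order, 1, axis=1)
        if scheme == "fixed_out_degree":
            X = X.T
        return SparsityMask(X=X, scheme=scheme, s=1.0 - C / N, C=int(C))
    raise ValueError(f"unknown mask scheme: {scheme!r}")


def sparsify(W: WeightMatrix, mask: SparsityMask) -> WeightMatrix:
    """Elementwise product ``W ⊙ X``; provenance and mask are recorded."""
    if mask.N != W.N:
        raise ValueError(
            f"dimension mismatch: W is {W.N}x{W.N}, mask is {mask.N}x{mask.N}"
        )
    return WeightMatrix(
        W=W.W * mask.X,
        provenance=W.provenance,
        vectors=W.vectors,
        mask=mask,
        g=W.g,
    )


# ---------------------------------------------------------------------------
# persistence: NPZ-style array container plus JSON parameter sidecar


def save_weight_matrix(wm: WeightMatrix, path: str | Path, **params) -> Path:
    """Persist a weight matrix (keys W, m, n, X) with a JSON sidecar."""
    path = Path(path)
    arrays = {"W": wm.W}
    if wm.vectors is not None:
        arrays["m"] = wm.vectors.m
        arrays["n"] = wm.vectors.n
    if wm.mask is not None:
        arrays["X"] = wm.mask.X
    np.savez_compressed(path, **arrays)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    meta = {
        "N": wm.N,
        "provenance": wm.provenance,
        "g": wm.g,
        "sigma2": wm.vectors.sigma2 if wm.vectors else None,
        "sigma_mn": wm.vectors.sigma_mn if wm.vectors else None,
        "scheme": wm.mask.scheme if wm.mask else None,
        "s": wm.mask.s if wm.mask else None,
        "C": wm.mask.C if wm.mask else None,
    }
    meta.update(params)
    sidecar = npz_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return npz_path


def load_weight_matrix(path: str | Path) -> WeightMatrix:
    """Load a weight matrix saved by :func:`save_weight_matrix`."""
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    vectors = None
    if "m" in data:
        vectors = ConnectivityVectors(
            m=data["m"],
            n=data["n"],
            N=int(meta["N"]),
            sigma2=float(meta["sigma2"]),
            sigma_mn=float(meta["sigma_mn"]),
        )
    mask = None
    if "X" in data:
        mask = SparsityMask(
            X=data["X"],
            scheme=meta["scheme"],
            s=float(meta["s"]),
            C=meta["C"],
        )
    return WeightMatrix(
        W=data["W"],
        provenance=meta["provenance"],
        vectors=vectors,
        mask=mask,
        g=meta.get("g"),
    )
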