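"""Eigenspectra of sparsified connectivity: analytic predictions and
empirical measurement.

Random sparsification splits the spectrum of a rank-one coupling into an
isolated real *outlier* inherited from the structure, plus a circular *bulk*
of eigenvalues around the origin whose radius follows Girko's circular law
``R = sqrt(Var * N)`` applied to the entrywise variance of the matrix with
the outlier deflated away.  Closed forms:

====================  =======================  ==============================
branch                outlier λ₁               bulk radius R
====================  =======================  ==============================
Gaussian, sparsity s  —                        g sqrt(1 - s)
rank-one  m n^T / N   (1 - s) σ_mn             σ² sqrt(s (1 - s) / N)
rescaled  m n^T       C σ_mn                   σ² sqrt(C (N - C) / N)
====================  =======================  ==============================

with ``s = 1 - C/N`` for the fixed-degree schemes.  The rescaled bulk radius
tends to ``σ² sqrt(C)`` as N → ∞ at fixed C, so both spectral components
survive arbitrarily high sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .connectivity import WeightMatrix

__all__ = [
    "SpectralTheory",
    "SpectralReport",
    "theory_gaussian_radius",
    "theory_rank_one_outlier",
    "theory_rank_one_bulk_radius",
    "rank_one_theory",
    "compute_spectrum",
    "estimate_outlier_and_bulk",
    "deflate_outlier",
]


@dataclass(frozen=True)
class SpectralTheory:
    """Analytic (outlier, bulk radius) prediction for one parameter point."""

    outlier: float
    bulk_radius: float
    regime_inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bulk_radius < 0:
            raise ValueError("bulk radius must be non-negative")


@dataclass(frozen=True)
class SpectralReport:
    """Empirical spectrum summary with optional theory attached.

    ``outlier_hat`` is the eigenvalue with largest real part, reported only
    when it separates from the bulk (``outlier_measurable``); the bulk radius
    is the largest modulus among the remaining eigenvalues.
    """

    eigenvalues: np.ndarray
    outlier_hat: Optional[float]
    bulk_radius_hat: float
    outlier_measurable: bool
    theory: Optional[SpectralTheory] = None


def theory_gaussian_radius(
    g: float, s: float = 0.0, C: Optional[int] = None, N: Optional[int] = None
) -> float:
    """Spectral radius ``g sqrt(1 - s)`` of a sparsified Gaussian matrix.

    Pass ``C`` and ``N`` instead of ``s`` for the fixed-degree form
    ``g sqrt(C / N)``.
    """
    if g < 0:
        raise ValueError("g must be non-negative")
    if C is not None:
        if N is None:
            raise ValueError("N is required when C is given")
        s = 1.0 - C / N
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    return g * np.sqrt(1.0 - s)


def theory_rank_one_outlier(
    sigma_mn: float,
    s: Optional[float] = None,
    C: Optional[int] = None,
    N: Optional[int] = None,
    rescaled: bool = False,
) -> float:
    """Predicted outlier of a sparsified rank-one matrix.

    Scaled branch (``m_i n_j / N``): ``λ₁ = (1 - s) σ_mn``, equivalently
    ``C σ_mn / N``.  Rescaled branch (``m_i n_j``): ``λ₁ = C σ_mn``,
    independent of both s and N.
    """
    if rescaled:
        if C is None:
            raise ValueError("rescaled branch requires C")
        return C * sigma_mn
    if s is None:
        if C is None or N is None:
            raise ValueError("scaled branch requires s, or C and N")
        s = 1.0 - C / N
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    return (1.0 - s) * sigma_mn


def theory_rank_one_bulk_radius(
    sigma2: float,
    s: Optional[float] = None,
    N: Optional[int] = None,
    C: Optional[int] = None,
    rescaled: bool = False,
) -> float:
    """Predicted bulk radius of a sparsified rank-one matrix.

    Scaled branch: ``R = σ² sqrt(s (1 - s) / N)`` — symmetric in
    ``s ↔ 1 - s`` with maximum at s = 0.5, and vanishing both in the dense
    and the fully-sparse limit.  Rescaled branch:
    ``R = σ² sqrt(C (N - C) / N)`` with ``C = (1 - s) N`` if only s is
    given; tends to ``σ² sqrt(C)`` as N → ∞ at fixed C.
    """
    if N is None:
        raise ValueError("N is required")
    if N < 2:
        raise ValueError("N must be at least 2")
    if rescaled:
        if C is None:
            if s is None:
                raise ValueError("rescaled branch requires C or s")
            C = (1.0 - s) * N
        return sigma2 * np.sqrt(C * (N - C) / N)
    if s is None:
        if C is None:
            raise ValueError("scaled branch requires s, or C with N")
        s = 1.0 - C / N
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    return sigma2 * np.sqrt(s * (1.0 - s) / N)


def rank_one_theory(
    sigma2: float,
    sigma_mn: float,
    N: int,
    s: Optional[float] = None,
    C: Optional[int] = None,
    rescaled: bool = False,
) -> SpectralTheory:
    """Bundle outlier and bulk-radius predictions for one parameter point."""
    outlier = theory_rank_one_outlier(sigma_mn, s=s, C=C, N=N, rescaled=rescaled)
    radius = theory_rank_one_bulk_radius(sigma2, s=s, N=N, C=C, rescaled=rescaled)
    return SpectralTheory(
        outlier=float(outlier),
        bulk_radius=float(radius),
        regime_inputs={
            "sigma2": sigma2,
            "sigma_mn": sigma_mn,
            "N": N,
            "s": s,
            "C": C,
            "branch": "rescaled" if rescaled else "scaled",
        },
    )


def compute_spectrum(W: WeightMatrix | np.ndarray) -> np.ndarray:
    """All N eigenvalues of a coupling matrix (dense eigendecomposition)."""
    A = W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("matrix contains non-finite entries")
    return scipy.linalg.eigvals(A)


def estimate_outlier_and_bulk(
    spectrum: np.ndarray,
    theory: Optional[SpectralTheory] = None,
    margin: float = 0.0,
) -> SpectralReport:
    """Split a spectrum into a measurable outlier and the bulk.

    The eigenvalue with largest real part is declared a measurable outlier
    iff its real part exceeds the largest modulus of the remaining
    eigenvalues by the relative ``margin`` (default: strictly greater).
    When nothing separates, all eigenvalues count as bulk and no outlier is
    reported — the regime in which the outlier's location cannot be
    measured empirically.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.size == 0:
        raise ValueError("empty spectrum")
    idx = int(np.argmax(spectrum.real))
    candidate = spectrum[idx]
    rest = np.delete(spectrum, idx)
    rest_radius = float(np.abs(rest).max()) if rest.size else 0.0
    measurable = bool(candidate.real > rest_radius * (1.0 + margin)) and candidate.real > 0
    if measurable:
        return SpectralReport(
            eigenvalues=spectrum,
            outlier_hat=float(candidate.real),
            bulk_radius_hat=rest_radius,
            outlier_measurable=True,
            theory=theory,
        )
    return SpectralReport(
        eigenvalues=spectrum,
        outlier_hat=None,
        bulk_radius_hat=float(np.abs(spectrum).max()),
        outlier_measurable=False,
        theory=theory,
    )


def deflate_outlier(
    P_sparse: WeightMatrix, P_dense: WeightMatrix, s: float
) -> WeightMatrix:
    """Remove the structural outlier: ``P* = P_sparse - (1 - s) P_dense``.

    m remains an eigenvector of the result but with eigenvalue ≈ 0, while
    the bulk eigenvalues are unchanged; the entrywise variance of P* is
    ``σ⁴ s (1 - s) / N²`` (scaled branch), which feeds the circular law for
    the bulk radius.
    """
    if P_sparse.N != P_dense.N:
        raise ValueError("matrix dimensions do not match")
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    return WeightMatrix(
        W=P_sparse.W - (1.0 - s) * P_dense.W,
        provenance="deflated",
        vectors=P_sparse.vectors,
        mask=P_sparse.mask,
    )
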