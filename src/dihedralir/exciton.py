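"""One- and two-exciton amide I Hamiltonians and transition dipoles.

The one-exciton Hamiltonian H1 carries the local (site) frequencies on its
diagonal and the inter-site couplings off-diagonal.  The two-exciton
Hamiltonian H2, in the basis {|ii>, |ij> (i<j)}, carries overtone energies
2*w_i - Delta (Delta = diagonal anharmonicity, default 16 cm^-1), combination
energies w_i + w_j, and the harmonic off-diagonal completion
<ii|H|ij> = sqrt(2) beta_ij, <ij|H|ik> = beta_jk.  Transition dipoles follow
the harmonic ladder rules <0|mu|i> = mu_i, <i|mu|ii> = sqrt(2) mu_i,
<i|mu|ij> = mu_j, rotated into the eigenbases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import PeptideModel

__all__ = [
    "ExcitonParams",
    "ExcitonSystem",
    "build_one_exciton",
    "two_exciton_basis",
    "build_two_exciton",
    "manifold_dipoles",
    "solve",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ExcitonParams:
    """Exciton-model parameters: diagonal anharmonicity Delta (cm^-1)."""

    anharmonicity: float = 16.0

    def __post_init__(self):
        if self.anharmonicity < 0:
            raise ValueError("anharmonicity must be >= 0")


def _sorted_eigh(H: np.ndarray):
    """Symmetric eigendecomposition with a fixed sign convention: ascending
    eigenvalues, first nonzero eigenvector component positive."""
    evals, evecs = np.linalg.eigh(H)
    for k in range(evecs.shape[1]):
        v = evecs[:, k]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            evecs[:, k] = -v
    return evals, evecs


def build_one_exciton(model: PeptideModel, couplings: np.ndarray) -> np.ndarray:
    """H1: site frequencies on the diagonal, couplings off-diagonal."""
    couplings = np.asarray(couplings, float)
    n = model.n_sites
    if couplings.shape != (n, n):
        raise ValueError(
            f"coupling matrix shape {couplings.shape} does not match "
            f"{n} sites")
    H1 = couplings.copy()
    np.fill_diagonal(H1, model.site_frequencies)
    return H1


def two_exciton_basis(n: int) -> list:
    """Basis ordering: all overtones |ii> (ascending i), then combinations
    |ij> with i < j in lexicographic order."""
    return [(i, i) for i in range(n)] + [(i, j) for i in range(n)
                                         for j in range(i + 1, n)]


def build_two_exciton(H1: np.ndarray, params: ExcitonParams = ExcitonParams()) -> np.ndarray:
    """Two-exciton Hamiltonian with anharmonically shifted overtones."""
    H1 = np.asarray(H1, float)
    n = H1.shape[0]
    w = np.diag(H1)
    basis = two_exciton_basis(n)
    dim = len(basis)
    H2 = np.zeros((dim, dim))
    index = {b: k for k, b in enumerate(basis)}
    for k, (i, j) in enumerate(basis):
        if i == j:
            H2[k, k] = 2.0 * w[i] - params.anharmonicity
        else:
            H2[k, k] = w[i] + w[j]
    for a, (i, j) in enumerate(basis):
        for b in range(a + 1, dim):
            p, q = basis[b]
            if i == j:
                # overtone |ii> couples to combinations containing i
                if p == i and q != i:
                    H2[a, b] = _SQRT2 * H1[i, q]
                elif q == i and p != i:
                    H2[a, b] = _SQRT2 * H1[i, p]
                elif p == q:  # |ii> -- |jj|: no direct bilinear coupling
                    H2[a, b] = 0.0
            elif p == q:
                if i == p:
                    H2[a, b] = _SQRT2 * H1[p, j]
                elif j == p:
                    H2[a, b] = _SQRT2 * H1[p, i]
            else:
                shared = {i, j} & {p, q}
                if len(shared) == 1:
                    s = shared.pop()
                    r1 = (({i, j} - {s}).pop(), ({p, q} - {s}).pop())
                    H2[a, b] = H1[r1[0], r1[1]]
            H2[b, a] = H2[a, b]
    return H2


@dataclass
class ExcitonSystem:
    """Solved exciton system: Hamiltonians, eigenstates, manifold dipoles."""

    H1: np.ndarray
    H2: np.ndarray
    e1: np.ndarray
    v1: np.ndarray
    e2: np.ndarray
    v2: np.ndarray
    mu01: np.ndarray  # (n, 3): ground -> one-exciton eigenstate dipoles
    mu12: np.ndarray  # (n, N2, 3): one-exciton -> two-exciton dipoles
    params: ExcitonParams = field(default_factory=ExcitonParams)

    @property
    def n_sites(self) -> int:
        return self.H1.shape[0]

    def mu01_sq(self) -> np.ndarray:
        """|mu_0->k|^2 per one-exciton eigenstate."""
        return np.einsum("kd,kd->k", self.mu01, self.mu01)

    def mu12_sq(self) -> np.ndarray:
        """|mu_k->m|^2, shape (n one-exciton, N2 two-exciton)."""
        return np.einsum("kmd,kmd->km", self.mu12, self.mu12)


def manifold_dipoles(model: PeptideModel, v1: np.ndarray, v2: np.ndarray):
    """Rotate site-basis harmonic dipole rules into the eigenbases.

    Site basis: <0|mu|i> = mu_i, <i|mu|ii> = sqrt(2) mu_i, <i|mu|ij> = mu_j
    for j != i, and zero for pair states not containing i.
    """
    n = model.n_sites
    mu_site = np.array([d.vector() for d in model.dipoles])  # (n, 3)
    basis = two_exciton_basis(n)
    N2 = len(basis)
    M = np.zeros((n, N2, 3))  # <site i | mu | pair q>
    for q, (p, r) in enumerate(basis):
        if p == r:
            M[p, q] = _SQRT2 * mu_site[p]
        else:
            M[p, q] = mu_site[r]
            M[r, q] = mu_site[p]
    mu01 = v1.T @ mu_site  # (n, 3)
    # mu12[k, m] = sum_iq v1[i,k] v2[q,m] M[i,q]
    mu12 = np.einsum("ik,qm,iqd->kmd", v1, v2, M)
    return mu01, mu12


def solve(model: PeptideModel, couplings: np.ndarray,
          params: ExcitonParams = ExcitonParams(),
          two_exciton: bool = True) -> ExcitonSystem:
    """Build and diagonalize both manifolds for a model + coupling matrix."""
    H1 = build_one_exciton(model, couplings)
    e1, v1 = _sorted_eigh(H1)
    if two_exciton:
        H2 = build_two_exciton(H1, params)
        e2, v2 = _sorted_eigh(H2)
    else:
        H2 = np.zeros((0, 0))
        e2, v2 = np.zeros(0), np.zeros((0, 0))
    mu01, mu12 = manifold_dipoles(model, v1, v2) if two_exciton else (
        v1.T @ np.array([d.vector() for d in model.dipoles]),
        np.zeros((model.n_sites, 0, 3)))
    return ExcitonSystem(H1=H1, H2=H2, e1=e1, v1=v1, e2=e2, v2=v2,
                         mu01=mu01, mu12=mu12, params=params)
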