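"""DKI forward signal model.

The log-signal is the cumulant expansion truncated at the kurtosis term,

    ln S(n, b) = ln S0 - b * n'Dn + (1/6) b^2 MD^2 * sum_ijkl n_i n_j n_k n_l W_ijkl

with D the symmetric 3x3 diffusion tensor (mm^2/s) and W the fully symmetric
rank-4 kurtosis tensor (dimensionless, 15 independent elements).  Along a
single axis this reduces to

    ln S(b) = ln S0 - b Dapp + (1/6) b^2 Dapp^2 Kapp,

with Dapp = n'Dn and Kapp = (MD^2 / Dapp^2) * (W contracted four times with n);
the MD^2-scaled and Dapp^2-scaled quadratic terms are algebraically identical.

Units: b in s/mm^2 and D in mm^2/s everywhere; reporting layers convert MD to
x1e-3 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement, permutations

import numpy as np

from .acquisition import AcquisitionScheme

__all__ = [
    "W_INDEX", "W_MULTIPLICITY", "D_INDEX", "D_MULTIPLICITY",
    "DiffusionTensor", "KurtosisTensor", "VoxelSignalModel",
    "w15_to_full", "full_to_w15", "rotate_w15",
    "dapp", "kapp", "mean_diffusivity", "predict_signal", "design_matrix",
]

#: Fixed ordering of the 15 independent kurtosis-tensor elements.
W_INDEX: tuple[tuple[int, int, int, int], ...] = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)

def _n_permutations(idx: tuple[int, ...]) -> int:
    return len(set(permutations(idx)))

#: Number of distinct index permutations of each unique element (1, 4, 6 or 12).
W_MULTIPLICITY = np.array([_n_permutations(i) for i in W_INDEX], dtype=float)

#: Unique diffusion-tensor elements (11, 22, 33, 12, 13, 23) and multiplicities.
D_INDEX: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
D_MULTIPLICITY = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor, stored as the full matrix (mm^2/s)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("diffusion tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("diffusion tensor must be symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))

    @classmethod
    def from_elements(cls, d11, d22, d33, d12, d13, d23) -> "DiffusionTensor":
        return cls(np.array([[d11, d12, d13],
                             [d12, d22, d23],
                             [d13, d23, d33]], dtype=float))

    @property
    def elements(self) -> np.ndarray:
        """(D11, D22, D33, D12, D13, D23)."""
        m = self.matrix
        return np.array([m[i, j] for i, j in D_INDEX])


@dataclass(frozen=True)
class KurtosisTensor:
    """Fully symmetric rank-4 kurtosis tensor via its 15 unique elements,
    ordered as in :data:`W_INDEX` (dimensionless)."""

    w15: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w15, dtype=float)
        if w.shape != (15,):
            raise ValueError("kurtosis tensor needs exactly 15 elements")
        object.__setattr__(self, "w15", w)

    @property
    def full(self) -> np.ndarray:
        return w15_to_full(self.w15)


@dataclass(frozen=True)
class VoxelSignalModel:
    """Ground-truth signal model of one voxel: S0 > 0, D, W."""

    s0: float
    D: DiffusionTensor
    W: KurtosisTensor

    def __post_init__(self):
        if not self.s0 > 0:
            raise ValueError("S0 must be positive")


def w15_to_full(w15: np.ndarray) -> np.ndarray:
    """Expand 15 unique elements into the full symmetric (..., 3,3,3,3) tensor."""
    w15 = np.asarray(w15, dtype=float)
    full = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for k, idx in enumerate(W_INDEX):
        for perm in set(permutations(idx)):
            full[..., perm[0], perm[1], perm[2], perm[3]] = w15[..., k]
    return full

def full_to_w15(full: np.ndarray) -> np.ndarray:
    """Reduce a full (..., 3,3,3,3) symmetric tensor to the 15 unique elements."""
    full = np.asarray(full, dtype=float)
    out = np.empty(full.shape[:-4] + (15,))
    for k, (i, j, l, m) in enumerate(W_INDEX):
        out[..., k] = full[..., i, j, l, m]
    return out

def rotate_w15(w15: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate kurtosis tensor(s): W'_ijkl = R_ia R_jb R_kc R_ld W_abcd.

    ``w15`` may be (..., 15); ``R`` is a single 3x3 rotation or (..., 3, 3).
    """
    full = w15_to_full(w15)
    rotated = np.einsum("...ia,...jb,...kc,...ld,...abcd->...ijkl",
                        R, R, R, R, full)
    return full_to_w15(rotated)


def _as_matrix(D) -> np.ndarray:
    return D.matrix if isinstance(D, DiffusionTensor) else np.asarray(D, float)

def _as_w15(W) -> np.ndarray:
    return W.w15 if isinstance(W, KurtosisTensor) else np.asarray(W, float)


def _check_unit(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(np.linalg.norm(n, axis=-1) - 1.0) > 1e-6):
        raise ValueError("encoding direction must be a unit vector")
    return n


def dapp(D, n) -> float | np.ndarray:
    """Apparent diffusion coefficient n'Dn along unit direction(s) n (mm^2/s)."""
    Dm = _as_matrix(D)
    n = _check_unit(n)
    return np.einsum("...i,...ij,...j->...", n, Dm, n)


def mean_diffusivity(D) -> float | np.ndarray:
    """MD = trace(D) / 3."""
    Dm = _as_matrix(D)
    return np.trace(Dm, axis1=-2, axis2=-1) / 3.0


def _w_contract(w15: np.ndarray, n: np.ndarray) -> np.ndarray:
    """sum_ijkl n_i n_j n_k n_l W_ijkl using the 15 unique elements and their
    permutation multiplicities (equals the naive 81-term sum)."""
    n = np.asarray(n, dtype=float)
    mono = np.stack([n[..., i] * n[..., j] * n[..., k] * n[..., l]
                     for (i, j, k, l) in W_INDEX], axis=-1)
    return np.einsum("...k,k,...k->...", mono,
                     W_MULTIPLICITY, np.broadcast_to(w15, mono.shape))


def kapp(D, W, n) -> float | np.ndarray:
    """Apparent kurtosis along n: (MD^2 / Dapp^2) * (n^4 : W).

    Where Dapp <= 0 the kurtosis is undefined and NaN is returned (flagged,
    never silently zeroed).
    """
    Dm = _as_matrix(D)
    w15 = _as_w15(W)
    n = _check_unit(n)
    da = np.einsum("...i,...ij,...j->...", n, Dm, n)
    md = np.trace(Dm, axis1=-2, axis2=-1) / 3.0
    contraction = _w_contract(w15, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(da > 0, (md / da) ** 2 * contraction, np.nan)
    return out if out.ndim else float(out)


def predict_signal(model: VoxelSignalModel, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signal for every measurement of *scheme*."""
    beta = np.concatenate((
        [np.log(model.s0)],
        model.D.elements,
        mean_diffusivity(model.D) ** 2 * model.W.w15,
    ))
    return np.exp(design_matrix(scheme, check=False) @ beta)


def design_matrix(scheme: AcquisitionScheme, check: bool = True) -> np.ndarray:
    """(N, 22) linear design for the log-signal.

    Column order and meaning (coefficient vector beta):

    - column 0: constant 1                      -> beta[0]  = ln S0
    - columns 1-6: -b * mult2 * n_i n_j         -> beta[1:7] = (D11, D22, D33,
      D12, D13, D23), with mult2 = (1,1,1,2,2,2)
    - columns 7-21: (b^2/6) * mult4 * n_i n_j n_k n_l  -> beta[7:22] =
      MD^2 * (W1111 ... W1233) in :data:`W_INDEX` order, with mult4 the
      permutation multiplicities.

    The kurtosis coefficients are the MD^2-scaled elements, which keeps the
    model linear; W itself is recovered downstream by dividing by the fitted
    MD^2.
    """
    b = scheme.bvals
    n = scheme.bvecs
    if check:
        nonzero = np.unique(np.round(b[b > 0], 3))
        if len(nonzero) < 2:
            raise ValueError(
                "DKI design requires >= 2 distinct nonzero b-values "
                f"(got {nonzero.tolist()}): the b and b^2 columns are "
                "collinear, the system is rank-deficient")
    cols = [np.ones_like(b)]
    for m2, (i, j) in zip(D_MULTIPLICITY, D_INDEX):
        cols.append(-b * m2 * n[:, i] * n[:, j])
    for m4, (i, j, k, l) in zip(W_MULTIPLICITY, W_INDEX):
        cols.append(b ** 2 / 6.0 * m4 * n[:, i] * n[:, j] * n[:, k] * n[:, l])
    return np.stack(cols, axis=1)
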