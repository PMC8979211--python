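"""Physical and RBE-weighted (biological) dose from particle numbers.

The physical dose is linear in the particle-number vector N through the
sparse dose-influence matrix, ``D_i = sum_j d_ij N_j``. The biological dose
multiplies it by the relative biological effectiveness, computed here with
the analytic low-dose mixed-field approximation: per-voxel mixed-field
coefficients are dose-weighted means over the contributing spots
(Zaider-Rossi weighting of alpha and sqrt(beta)), the biological effect
``-ln S`` follows the linear-quadratic curve up to the threshold dose D_t
and a straight line of slope s_max above it, and the biological dose is
obtained by inverting the photon response at that effect.

With the per-spot tables the effect has the closed form

    -ln S_i = (sum_j d_ij N_j sqrt(beta_ij))^2 + sum_j d_ij N_j alpha_ij

for D_i^phys <= D_t, which makes the gradient of the biological dose with
respect to every N_j analytic (the full chain rule, i.e. including the
variation of RBE with N, not only RBE * grad D_phys).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DoseCorrelationMatrix",
    "PhotonResponse",
    "MixedFieldTable",
    "MixedFieldCoefficients",
    "physical_dose",
    "mixed_field_coefficients",
    "biological_effect",
    "biological_dose",
    "biological_dose_from_particles",
    "rbe",
    "biological_dose_gradient",
]


class DimensionError(ValueError):
    pass


@dataclass(frozen=True)
class DoseCorrelationMatrix:
    """Sparse voxel x rasterpoint matrix of d_ij (Gy per particle).

    ``peak_offset_mm`` (optional, same sparsity) is the signed depth offset
    of voxel i from spot j's Bragg peak, used to synthesize
    radiosensitivity tables.
    """

    d: sp.csr_matrix
    peak_offset_mm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        d = sp.csr_matrix(self.d)
        if (d.data < 0).any():
            raise ValueError("dose-influence entries must be nonnegative")
        object.__setattr__(self, "d", d)

    @property
    def n_voxels(self) -> int:
        return self.d.shape[0]

    @property
    def n_spots(self) -> int:
        return self.d.shape[1]


@dataclass(frozen=True)
class PhotonResponse:
    """Photon LQ curve with the high-dose linear continuation of the LEM.

    s_max defaults to the LQ slope at D_t (alpha_x + 2 beta_x D_t) so the
    effect curve is C1 at the threshold; S_t_effect is -ln S at D_t.
    """

    alpha_x: float
    beta_x: float
    D_t: float
    s_max: float | None = None

    def __post_init__(self) -> None:
        if self.beta_x <= 0:
            raise ValueError("beta_x must be positive (the LQ inversion is undefined at 0)")
        if self.alpha_x <= 0 or self.D_t <= 0:
            raise ValueError("alpha_x and D_t must be positive")
        if self.s_max is None:
            object.__setattr__(self, "s_max", self.alpha_x + 2.0 * self.beta_x * self.D_t)
        if self.s_max < self.alpha_x:
            raise ValueError("s_max must be >= alpha_x")

    @property
    def S_t_effect(self) -> float:
        return (self.beta_x * self.D_t + self.alpha_x) * self.D_t

    def effect(self, dose) -> np.ndarray:
        """Photon effect -ln S at the given dose (both branches)."""
        dose = np.asarray(dose, dtype=float)
        low = (self.beta_x * dose + self.alpha_x) * dose
        high = self.S_t_effect + (dose - self.D_t) * self.s_max
        return np.where(dose <= self.D_t, low, high)


def _check_aligned(a: sp.csr_matrix, b: sp.csr_matrix) -> None:
    if a.shape != b.shape or not (
        np.array_equal(a.indptr, b.indptr) and np.array_equal(a.indices, b.indices)
    ):
        raise ValueError("radiosensitivity tables are not aligned with the dose matrix sparsity")


@dataclass(frozen=True)
class MixedFieldTable:
    """Per-entry alpha_ij and sqrt(beta_ij), aligned with d_ij, plus the
    photon response parameters."""

    alpha: sp.csr_matrix
    sqrt_beta: sp.csr_matrix
    photon: PhotonResponse

    def __post_init__(self) -> None:
        if (self.alpha.data <= 0).any():
            raise ValueError("alpha_ij must be positive wherever d_ij is nonzero")
        _check_aligned(self.alpha, self.sqrt_beta)


@dataclass(frozen=True)
class MixedFieldCoefficients:
    """Voxel-wise mixed-field LQ coefficients (0 where the dose is 0)."""

    alpha_bar: np.ndarray  # 1/Gy
    beta_bar: np.ndarray  # 1/Gy^2


def _as_particles(N, n_spots: int) -> np.ndarray:
    N = np.asarray(N, dtype=float).ravel()
    if N.size != n_spots:
        raise DimensionError(f"particle vector has length {N.size}, expected {n_spots}")
    if (N < 0).any():
        raise ValueError("particle numbers must be nonnegative")
    return N


def physical_dose(matrix: DoseCorrelationMatrix, N) -> np.ndarray:
    """Physical dose per voxel, D_i = sum_j d_ij N_j (Gy per fraction)."""
    N = _as_particles(N, matrix.n_spots)
    return matrix.d @ N


def _weighted_sums(matrix: DoseCorrelationMatrix, table: MixedFieldTable, N):
    """A_i = sum d a N, B_i = sum d sqrt(beta) N, P_i = sum d N."""
    d = matrix.d
    _check_aligned(d, table.alpha)
    N = _as_particles(N, matrix.n_spots)
    da = d.copy()
    da.data = d.data * table.alpha.data
    db = d.copy()
    db.data = d.data * table.sqrt_beta.data
    return da @ N, db @ N, d @ N


def mixed_field_coefficients(
    matrix: DoseCorrelationMatrix, table: MixedFieldTable, N
) -> MixedFieldCoefficients:
    """Dose-weighted mean alpha and (mean sqrt(beta))^2 per voxel."""
    A, B, P = _weighted_sums(matrix, table, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_bar = np.where(P > 0, A / np.where(P > 0, P, 1.0), 0.0)
        sqrt_beta_bar = np.where(P > 0, B / np.where(P > 0, P, 1.0), 0.0)
    return MixedFieldCoefficients(alpha_bar=alpha_bar, beta_bar=sqrt_beta_bar**2)


def biological_effect(Dphys, coeffs: MixedFieldCoefficients, photon: PhotonResponse) -> np.ndarray:
    """Mixed-field effect -ln S per voxel (LQ up to D_t, linear above)."""
    Dphys = np.asarray(Dphys, dtype=float)
    if (Dphys < 0).any():
        raise ValueError("physical dose must be nonnegative")
    low = (coeffs.beta_bar * Dphys + coeffs.alpha_bar) * Dphys
    at_t = (coeffs.beta_bar * photon.D_t + coeffs.alpha_bar) * photon.D_t
    high = at_t + (Dphys - photon.D_t) * photon.s_max
    return np.where(Dphys <= photon.D_t, low, high)


def biological_dose(effect, photon: PhotonResponse) -> np.ndarray:
    """Invert the photon response at the given effect (both branches)."""
    effect = np.asarray(effect, dtype=float)
    if (effect < 0).any():
        raise ValueError("effect must be nonnegative")
    k = photon.alpha_x / (2.0 * photon.beta_x)
    low = np.sqrt(effect / photon.beta_x + k * k) - k
    high = (effect - photon.S_t_effect) / photon.s_max + photon.D_t
    return np.where(effect <= photon.S_t_effect, low, high)


def biological_dose_from_particles(
    matrix: DoseCorrelationMatrix, table: MixedFieldTable, N
) -> np.ndarray:
    """Full pipeline N -> Dphys -> coefficients -> effect -> Dbio."""
    Dphys = physical_dose(matrix, N)
    coeffs = mixed_field_coefficients(matrix, table, N)
    eff = biological_effect(Dphys, coeffs, table.photon)
    return biological_dose(eff, table.photon)


def rbe(Dbio, Dphys) -> np.ndarray:
    """Per-voxel RBE = Dbio / Dphys, 1 by convention where Dphys = 0."""
    Dbio = np.asarray(Dbio, dtype=float)
    Dphys = np.asarray(Dphys, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(Dphys > 0, Dbio / np.where(Dphys > 0, Dphys, 1.0), 1.0)


def biological_dose_gradient(
    matrix: DoseCorrelationMatrix, table: MixedFieldTable, N
) -> sp.csr_matrix:
    """Sparse gradient dDbio_i/dN_j with the same sparsity as d_ij.

    Chain rule through effect and inversion. With
    A = sum d a N, B = sum d sb N, P = sum d N and per-entry shorthands
    a_e = d alpha, b_e = d sqrt(beta):

    - P <= D_t: effect = B^2 + A, so d(effect)/dN_j = 2 B b_e + a_e;
    - P > D_t: effect = (D_t^2) B^2/P^2 + D_t A/P + (P - D_t) s_max, the
      quotient rule gives the entry values.

    Then multiply by d(Dbio)/d(effect): 1 / (2 beta_x (Dbio + alpha_x /
    (2 beta_x))) on the LQ branch, 1 / s_max on the linear branch.
    """
    A, B, P = _weighted_sums(matrix, table, N)
    photon = table.photon
    d = matrix.d
    coo = d.tocoo()
    i = coo.row
    d_e = coo.data
    a_e = d_e * table.alpha.tocoo().data
    b_e = d_e * table.sqrt_beta.tocoo().data

    low_mask = P[i] <= photon.D_t
    dE = np.empty_like(d_e)
    dE[low_mask] = 2.0 * B[i][low_mask] * b_e[low_mask] + a_e[low_mask]
    if (~low_mask).any():
        hi = ~low_mask
        ih = i[hi]
        Ph, Ah, Bh = P[ih], A[ih], B[ih]
        Dt, sm = photon.D_t, photon.s_max
        dE[hi] = (
            (Dt * Dt / (Ph * Ph)) * (2.0 * Bh * b_e[hi] - 2.0 * Bh * Bh * d_e[hi] / Ph)
            + (Dt / Ph) * (a_e[hi] - (Ah / Ph) * d_e[hi])
            + sm * d_e[hi]
        )

    coeffs = MixedFieldCoefficients(
        alpha_bar=np.where(P > 0, A / np.where(P > 0, P, 1.0), 0.0),
        beta_bar=np.where(P > 0, (B / np.where(P > 0, P, 1.0)) ** 2, 0.0),
    )
    eff = biological_effect(P, coeffs, photon)
    Dbio = biological_dose(eff, photon)
    k = photon.alpha_x / (2.0 * photon.beta_x)
    dDdE = np.where(
        eff <= photon.S_t_effect,
        1.0 / (2.0 * photon.beta_x * (Dbio + k)),
        1.0 / photon.s_max,
    )
    grad = sp.coo_matrix((dE * dDdE[i], (i, coo.col)), shape=d.shape)
    return grad.tocsr()
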