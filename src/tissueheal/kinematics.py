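"""Finite-strain kinematics of the multiplicative split for fibrous soft tissue.

The total deformation gradient of the mixture is decomposed as

    F = F_e^c . F_r^c . F_p^c        (collagen)
    F = F_e^m                        (non-collagenous matrix)

where ``F_p`` carries the permanent (plastic) stretch caused by collagen
interstrand delamination, ``F_r`` the remodeling stretch exchanging stretched
collagen for collagen deposited at its pre-stretch, and the elastic remainder
carries both the recoverable response and the volumetric growth swelling.
Both inelastic gradients are rank-one updates of the identity along the fiber
direction and are exactly unimodular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FiberFrame",
    "DecomposedDeformation",
    "ElasticInvariants",
    "inelastic_stretch_tensor",
    "inelastic_stretch_tensor_inverse",
    "fiber_frames",
    "elastic_invariants",
]

_UNIT_TOL = 1e-12
_EYE = np.eye(3)


class DegenerateDeformationError(ValueError):
    """Raised when a deformation maps a fiber to (numerically) zero length
    or has a non-positive determinant."""


def _as_unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _UNIT_TOL:
        raise DegenerateDeformationError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class FiberFrame:
    """Collagen fiber directions in the reference and intermediate
    configurations, with their structural (self outer-product) tensors."""

    a_0: np.ndarray
    a_p: np.ndarray
    a_r: np.ndarray

    def __post_init__(self):
        for name in ("a_0", "a_p", "a_r"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
            object.__setattr__(self, name, v)

    @property
    def M_0(self) -> np.ndarray:
        return np.outer(self.a_0, self.a_0)

    @property
    def M_p(self) -> np.ndarray:
        return np.outer(self.a_p, self.a_p)

    @property
    def M_r(self) -> np.ndarray:
        return np.outer(self.a_r, self.a_r)


@dataclass(frozen=True)
class DecomposedDeformation:
    """Total deformation gradient together with the inelastic collagen parts.

    ``F_e_c = F F_p^-1 F_r^-1`` is the elastic collagen gradient;
    the matrix deforms purely elastically, ``F_e_m = F``.
    """

    F: np.ndarray
    F_p: np.ndarray
    F_r: np.ndarray

    @property
    def F_e_c(self) -> np.ndarray:
        return self.F @ np.linalg.inv(self.F_p) @ np.linalg.inv(self.F_r)

    @property
    def F_e_m(self) -> np.ndarray:
        return self.F

    def validate(self, tol: float = 1e-10) -> None:
        if np.linalg.det(self.F) <= 0:
            raise DegenerateDeformationError("det(F) <= 0")
        for name in ("F_p", "F_r"):
            if abs(np.linalg.det(getattr(self, name)) - 1.0) > tol:
                raise ValueError(f"{name} is not unimodular")
        recon = self.F_e_c @ self.F_r @ self.F_p
        if not np.allclose(recon, self.F, atol=tol, rtol=0):
            raise ValueError("F != F_e_c F_r F_p")


@dataclass(frozen=True)
class ElasticInvariants:
    """Scalar deformation measures entering the mixture free energy.

    ``I1_bar`` is the isochoric first invariant of the matrix,
    ``Ie_c`` the squared elastic collagen stretch along the fiber, and the
    ``lambda_*`` fields the fiber-direction stretches of the multiplicative
    chain (lambda_total = lambda_e * lambda_r * lambda_p).
    """

    J: float
    I1_bar: float
    Ie_c: float
    lambda_total: float
    lambda_p: float
    lambda_r: float
    lambda_e: float


def inelastic_stretch_tensor(lam: float, M: np.ndarray) -> np.ndarray:
    """Unimodular stretch ``lam`` along a fiber: ``lam M + lam^(-1/2)(I - M)``.

    Eigenvalue ``lam`` along the fiber direction and ``lam^(-1/2)``
    transversely, so the determinant is exactly one.
    """
    if not lam > 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("M must be a symmetric 3x3 tensor")
    if abs(np.trace(M) - 1.0) > 1e-8 or abs(np.trace(M @ M) - 1.0) > 1e-8:
        raise ValueError("M must be rank one with unit trace")
    return lam * M + lam ** (-0.5) * (_EYE - M)


def inelastic_stretch_tensor_inverse(lam: float, M: np.ndarray) -> np.ndarray:
    """Closed-form inverse of :func:`inelastic_stretch_tensor`.

    Computed as the rank-one update ``lam^-1 M + lam^(1/2)(I - M)`` rather
    than by general matrix inversion, preserving exact unimodularity.
    """
    return inelastic_stretch_tensor(1.0 / lam, np.asarray(M, dtype=float))


def fiber_frames(F_p: np.ndarray, F_r: np.ndarray, a_0: np.ndarray) -> FiberFrame:
    """Map the reference fiber direction through the inelastic gradients and
    renormalize, so that stretches multiply along the chain."""
    F_p = np.asarray(F_p, dtype=float)
    F_r = np.asarray(F_r, dtype=float)
    if np.linalg.det(F_p) <= 0 or np.linalg.det(F_r) <= 0:
        raise DegenerateDeformationError("inelastic gradient with det <= 0")
    a_0 = _as_unit(a_0, "a_0")
    a_p = _as_unit(F_p @ a_0, "F_p a_0")
    a_r = _as_unit(F_r @ a_p, "F_r a_p")
    return FiberFrame(a_0=a_0, a_p=a_p, a_r=a_r)


def elastic_invariants(
    F: np.ndarray, F_p: np.ndarray, F_r: np.ndarray, frame: FiberFrame
) -> ElasticInvariants:
    """Invariants of the elastic collagen and matrix deformation.

    ``Ie_c = C_e^c : M_r`` with ``C_e^c`` the elastic collagen right
    Cauchy-Green tensor; ``I1_bar = det(C)^(-1/3) tr(C)`` for the matrix,
    which deforms with the total gradient.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise DegenerateDeformationError("det(F) <= 0 (inverted element)")
    C = F.T @ F
    I1_bar = float(J ** (-2.0 / 3.0) * np.trace(C))

    Fp_inv = np.linalg.inv(np.asarray(F_p, dtype=float))
    Fr_inv = np.linalg.inv(np.asarray(F_r, dtype=float))
    F_e = F @ Fp_inv @ Fr_inv
    C_e = F_e.T @ F_e
    Ie_c = float(frame.a_r @ C_e @ frame.a_r)

    lam_total = float(np.linalg.norm(F @ frame.a_0))
    lam_p = float(np.linalg.norm(F_p @ frame.a_0))
    lam_r = float(np.linalg.norm(F_r @ frame.a_p))
    lam_e = float(np.linalg.norm(F_e @ frame.a_r))
    return ElasticInvariants(
        J=J,
        I1_bar=I1_bar,
        Ie_c=Ie_c,
        lambda_total=lam_total,
        lambda_p=lam_p,
        lambda_r=lam_r,
        lambda_e=lam_e,
    )
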