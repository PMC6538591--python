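"""Reparameterization separating equality-constrained from free directions.

For a hypothesis ``R_E beta = r_E & R_I beta > r_I`` the coefficients are
transformed to ``xi = T beta`` with ``T = [R_E; D]``, where ``D`` holds
``k - q_E`` linearly independent rows of the projector onto the orthogonal
complement of the equality rows.  In the new coordinates the hypothesis
reads ``xi_E = r_E & Rtilde_I xi_I > rtilde_I`` with

    Rtilde_I = R_I D^-      and      rtilde_I = r_I - R_I R_E^- r_E,

``^-`` denoting Moore-Penrose pseudo-inverses.  The default prior centre
``mu0 = T R^- r`` (stacked ``R = [R_E; R_I]``, ``r = (r_E, r_I)``) sits on
the boundary of the constrained space; with the all-zero right-hand sides
of typical applications it is simply the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypotheses import ConstraintSystem, HypothesisError

__all__ = ["TransformedSystem", "build_complement_basis", "transform_system",
           "SaturatedSystemError"]

_SVD_CUT = None  # default numpy pinv cutoff: max(dim) * eps * sigma_max


class SaturatedSystemError(ValueError):
    """Equalities determine all k coefficients; no free directions remain."""


@dataclass(frozen=True)
class TransformedSystem:
    """The xi-coordinates version of one constraint system."""

    T: np.ndarray            # (k, k), rows R_E then D
    D: np.ndarray            # (k - q_E, k)
    Rtilde_I: np.ndarray     # (q_I, k - q_E)
    rtilde_I: np.ndarray     # (q_I,)
    mu0: np.ndarray          # (k,) prior centre for xi; leading block == r_E
    rank_RtildeI: int

    @property
    def q_E(self) -> int:
        return self.T.shape[0] - self.D.shape[0]

    @property
    def full_rank(self) -> bool:
        return self.rank_RtildeI == self.Rtilde_I.shape[0]


def build_complement_basis(R_E: np.ndarray) -> np.ndarray:
    """Rows spanning the orthogonal complement of the equality rows.

    Taken as linearly independent rows of the projector
    ``P = I - R_E'(R_E R_E')^{-1} R_E``, selected greedily in row order so
    the choice is deterministic.  (Any full-rank selection produces the
    same Bayes factors; the choice only relabels the free coordinates.)
    """
    R_E = np.atleast_2d(np.asarray(R_E, dtype=float))
    q_E, k = R_E.shape
    if q_E == 0:
        return np.eye(k)
    if np.linalg.matrix_rank(R_E) < q_E:
        raise HypothesisError("equality rows are not linearly independent")
    if q_E >= k:
        raise SaturatedSystemError(
            "equalities fix all coefficients; no complement basis exists"
        )
    P = np.eye(k) - R_E.T @ np.linalg.solve(R_E @ R_E.T, R_E)
    rows, basis = [], np.empty((0, k))
    for i in range(k):
        cand = P[i]
        resid = cand - basis.T @ (basis @ cand)
        norm = np.linalg.norm(resid)
        if norm > 1e-10:
            rows.append(cand)
            basis = np.vstack([basis, resid / norm])
        if len(rows) == k - q_E:
            break
    if len(rows) < k - q_E:
        raise HypothesisError("failed to span the complement of the equality rows")
    return np.array(rows)


def transform_system(sys: ConstraintSystem) -> TransformedSystem:
    """Build ``T``, the reduced inequality system, and the prior centre."""
    k = sys.k
    if sys.q_E >= k and sys.q_E > 0:
        raise SaturatedSystemError(
            "all coefficients are equality-determined; handle via the "
            "equality-only Bayes factor"
        )
    D = build_complement_basis(sys.R_E) if sys.q_E else np.eye(k)
    T = np.vstack([sys.R_E, D]) if sys.q_E else D
    if np.linalg.matrix_rank(T) < k:
        raise HypothesisError("transformation matrix T is singular")
    if sys.q_E:
        Rtilde = sys.R_I @ np.linalg.pinv(D)
        rtilde = sys.r_I - sys.R_I @ (np.linalg.pinv(sys.R_E) @ sys.r_E)
    else:
        Rtilde = sys.R_I.copy()
        rtilde = sys.r_I.copy()
    R = np.vstack([sys.R_E, sys.R_I])
    r = np.concatenate([sys.r_E, sys.r_I])
    # minimum-norm (least-squares when inconsistent) boundary point
    mu0 = T @ (np.linalg.pinv(R) @ r)
    rank = (
        int(np.linalg.matrix_rank(Rtilde)) if Rtilde.size else 0
    )
    return TransformedSystem(
        T=T, D=D, Rtilde_I=Rtilde, rtilde_I=rtilde, mu0=mu0, rank_RtildeI=rank
    )
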