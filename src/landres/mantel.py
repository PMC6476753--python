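"""Simple and partial Mantel permutation tests, written from scratch.

The Mantel statistic is the Pearson correlation of the vectorized strict
upper triangles of two symmetric pairwise matrices.  Significance comes from
jointly permuting the rows and columns of one matrix — i.e. relabelling
individuals — and the permutation p-value is

    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)

for the one-tailed "greater" alternative, so 999 permutations floor p at
0.001.  Ties (a permuted r exactly equal to the observed one) count toward
p, which is the conservative convention.

The partial Mantel statistic is the first-order partial correlation

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))

and its null distribution is obtained by permuting the first matrix raw and
recomputing the partial statistic each time (the scheme of the classic
ecology packages); a residual-permutation variant is available via
``method="residual"``.

For n <= 8 individuals :func:`exhaustive_mantel` enumerates all n! joint
permutations and returns the exact p, which doubles as the built-in oracle
for the Monte-Carlo engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np

from .errors import CollinearityError, ConfigurationError, DegenerateMatrixError
from .pairwise import PairwiseMatrix

TAILS = ("greater", "less", "two-sided")


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, PairwiseMatrix):
        return m.values
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError("expected a square matrix")
    if not np.allclose(m, m.T):
        raise ConfigurationError("matrix must be symmetric")
    return m


def _check_conformable(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for m in mats[1:]:
        if m.shape[0] != n:
            raise ConfigurationError("matrices must share the same individuals")
    if n < 3:
        raise ConfigurationError("Mantel statistics need at least 3 individuals")
    return n


def _centred_unit(vec: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """Centred vector and its norm; zero variance is a degenerate matrix."""
    c = vec - vec.mean()
    norm = float(np.linalg.norm(c))
    if norm == 0.0:
        raise DegenerateMatrixError(f"matrix {what} has zero off-diagonal variance")
    return c, norm


@dataclass
class MantelResult:
    """Outcome of a (partial) Mantel permutation test."""

    r: float
    p: float
    n_perm: int
    tail: str
    kind: str  # "simple" or "partial"
    conditioning: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise DegenerateMatrixError("Mantel r is not finite")


def _tail_count(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    # exact ties count as extreme (conservative)
    if tail == "greater":
        return int(np.count_nonzero(r_perm >= r_obs - 1e-15))
    if tail == "less":
        return int(np.count_nonzero(r_perm <= r_obs + 1e-15))
    if tail == "two-sided":
        return int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    raise ConfigurationError(f"tail must be one of {TAILS}, got {tail!r}")


def mantel_r(A, B) -> float:
    """Pearson correlation of the strict upper triangles of A and B."""
    a_m, b_m = _as_matrix(A), _as_matrix(B)
    n = _check_conformable(a_m, b_m)
    iu = np.triu_indices(n, k=1)
    a_c, na = _centred_unit(a_m[iu], "A")
    b_c, nb = _centred_unit(b_m[iu], "B")
    return float(a_c @ b_c / (na * nb))


def mantel_test(A, B, n_perm: int = 999, seed=None, tail: str = "greater"
                ) -> MantelResult:
    """Simple Mantel test, permuting the rows/columns of B jointly.

    Deterministic given ``seed``; with ``n_perm`` permutations the smallest
    attainable p is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if tail not in TAILS:
        raise ConfigurationError(f"tail must be one of {TAILS}, got {tail!r}")
    a_m, b_m = _as_matrix(A), _as_matrix(B)
    n = _check_conformable(a_m, b_m)
    iu = np.triu_indices(n, k=1)
    a_c, na = _centred_unit(a_m[iu], "A")
    b_c, nb = _centred_unit(b_m[iu], "B")
    r_obs = float(a_c @ b_c / (na * nb))
    # Joint row/column permutation leaves the off-diagonal multiset of B
    # intact, so mean and norm are permutation-invariant: only the dot
    # product needs recomputing.
    ua = a_c / (na * nb)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    b_mean = b_m[iu].mean()
    for k in range(n_perm):
        p = rng.permutation(n)
        bp = b_m[p[iu[0]], p[iu[1]]]
        r_perm[k] = ua @ (bp - b_mean)
    p_val = (1 + _tail_count(r_perm, r_obs, tail)) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm, tail=tail, kind="simple")


def exhaustive_mantel(A, B, tail: str = "greater") -> float:
    """Exact Mantel p by enumerating all n! joint permutations (n <= 8).

    The identity permutation is included in the reference set, so the
    observed configuration counts toward its own p.
    """
    a_m, b_m = _as_matrix(A), _as_matrix(B)
    n = _check_conformable(a_m, b_m)
    if n > 8:
        raise ConfigurationError(
            f"exhaustive enumeration is limited to n <= 8 (got n = {n})"
        )
    iu = np.triu_indices(n, k=1)
    a_c, na = _centred_unit(a_m[iu], "A")
    b_c, nb = _centred_unit(b_m[iu], "B")
    r_obs = float(a_c @ b_c / (na * nb))
    ua = a_c / (na * nb)
    b_mean = b_m[iu].mean()
    r_all = np.array([
        ua @ (b_m[np.array(p)[iu[0]], np.array(p)[iu[1]]] - b_mean)
        for p in _permutations(range(n))
    ])
    return _tail_count(r_all, r_obs, tail) / len(r_all)


def partial_mantel_r(A, B, C) -> float:
    """First-order partial correlation r_AB.C on upper-triangle vectors."""
    a_m, b_m, c_m = _as_matrix(A), _as_matrix(B), _as_matrix(C)
    n = _check_conformable(a_m, b_m, c_m)
    iu = np.triu_indices(n, k=1)
    a_c, na = _centred_unit(a_m[iu], "A")
    b_c, nb = _centred_unit(b_m[iu], "B")
    c_c, nc = _centred_unit(c_m[iu], "C")
    r_ab = float(a_c @ b_c / (na * nb))
    r_ac = float(a_c @ c_c / (na * nc))
    r_bc = float(b_c @ c_c / (nb * nc))
    return _partial_from_pairwise(r_ab, r_ac, r_bc)


def _partial_from_pairwise(r_ab: float, r_ac: float, r_bc: float) -> float:
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise CollinearityError(
            "conditioning matrix is perfectly correlated with a test matrix"
        )
    return (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac ** 2) * (1 - r_bc ** 2))


def partial_mantel_test(A, B, C, n_perm: int = 999, seed=None,
                        tail: str = "greater", method: str = "raw"
                        ) -> MantelResult:
    """Partial Mantel test of A ~ B conditioning on C.

    ``method="raw"`` (default) permutes A jointly and recomputes the partial
    statistic; ``method="residual"`` permutes the residuals of A's
    upper-triangle vector after regressing out C.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if tail not in TAILS:
        raise ConfigurationError(f"tail must be one of {TAILS}, got {tail!r}")
    if method not in ("raw", "residual"):
        raise ConfigurationError(f"unknown permutation method {method!r}")
    a_m, b_m, c_m = _as_matrix(A), _as_matrix(B), _as_matrix(C)
    n = _check_conformable(a_m, b_m, c_m)
    iu = np.triu_indices(n, k=1)
    a_c, na = _centred_unit(a_m[iu], "A")
    b_c, nb = _centred_unit(b_m[iu], "B")
    c_c, nc = _centred_unit(c_m[iu], "C")
    r_bc = float(b_c @ c_c / (nb * nc))
    r_ab = float(a_c @ b_c / (na * nb))
    r_ac = float(a_c @ c_c / (na * nc))
    r_obs = _partial_from_pairwise(r_ab, r_ac, r_bc)

    rng = np.random.default_rng(seed)
    ub = b_c / nb
    uc = c_c / nc
    r_perm = np.empty(n_perm)
    if method == "raw":
        a_mean = a_m[iu].mean()
        for k in range(n_perm):
            p = rng.permutation(n)
            ap = a_m[p[iu[0]], p[iu[1]]] - a_mean
            r1 = float(ap @ ub) / na
            r2 = float(ap @ uc) / na
            r_perm[k] = _partial_from_pairwise(r1, r2, r_bc)
    else:
        # residuals of A on C, permuted as a symmetric matrix
        resid_vec = a_c - (a_c @ uc) * uc
        res_m = np.zeros_like(a_m)
        res_m[iu] = resid_vec
        res_m = res_m + res_m.T
        rc, rn = _centred_unit(res_m[iu], "residual(A|C)")
        res_mean = res_m[iu].mean()
        for k in range(n_perm):
            p = rng.permutation(n)
            rp = res_m[p[iu[0]], p[iu[1]]] - res_mean
            r1 = float(rp @ ub) / rn
            r2 = float(rp @ uc) / rn
            r_perm[k] = _partial_from_pairwise(r1, r2, r_bc)
    p_val = (1 + _tail_count(r_perm, r_obs, tail)) / (n_perm + 1)
    role_c = C.role if isinstance(C, PairwiseMatrix) and C.role else "C"
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm, tail=tail,
                        kind="partial", conditioning=role_c)
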