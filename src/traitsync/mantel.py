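"""Simple and partial Mantel permutation tests on distance matrices.

The Mantel statistic is the Pearson correlation r between the vectorized
lower triangles of two aligned distance matrices.  Significance cannot come
from the usual t distribution because the n(n-1)/2 pairwise entries are not
independent; instead, the rows and columns of one matrix are permuted
*jointly* (preserving its internal structure) to build the null
distribution.  The one-tailed p-value against H0: r <= 0 uses the
add-one convention p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), which never
reports zero.

The partial Mantel test controls a third matrix C (here: phylogenetic
distance) through the first-order partial correlation

    r_AB.C = (r_AB - r_AC * r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)),

permuting B and recomputing r_AB and r_BC each time (raw-matrix
permutation in the Smouse-Long-Sokal style; a residual-permutation variant
is available via ``method="residual"``).

Confidence intervals come from subsampling species without replacement
(default 90% of species per repeat) and recomputing r on the induced
submatrices; resampling *with* replacement would duplicate species and
create artificial zero distances.

Undefined (NaN) entries in any matrix are excluded pairwise, consistently
across all matrices involved, before correlations are computed.

``exact_mantel`` enumerates all n! joint permutations (n <= 8) and serves
as a ground-truth oracle for the Monte-Carlo p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from itertools import permutations as _all_permutations

import numpy as np

from .errors import (
    AlignmentError,
    CollinearMatricesError,
    DegenerateMatrixError,
    InvalidArgumentError,
)
from .matrices import DistanceMatrix

logger = logging.getLogger("traitsync.mantel")

__all__ = [
    "MantelResult",
    "vectorize_pair",
    "mantel",
    "exact_mantel",
    "partial_mantel",
    "bootstrap_ci",
]

_PERM_CHUNK = 2000  # permutations per vectorized block (bounds memory)


@dataclass
class MantelResult:
    """Observed statistic, permutation p-value and bootstrap CI."""

    r_obs: float
    p_one_tailed: float
    ci_low: float
    ci_high: float
    n_species: int
    n_perm: int
    n_boot: int
    seed: int
    partial: bool = field(default=False)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_aligned(*mats: DistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            extra = sorted(set(m.labels) - set(ref))
            missing = sorted(set(ref) - set(m.labels))
            if extra or missing:
                raise AlignmentError(
                    f"matrices are not aligned: only in {m.name or 'second'}: {extra}; "
                    f"missing from it: {missing}"
                )
            raise AlignmentError(
                "matrices share a species set but in different order; reindex first"
            )


def vectorize_pair(A: DistanceMatrix, B: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Paired lower-triangle vectors, entries undefined in either excluded."""
    _check_aligned(A, B)
    a, b = A.triangle(), B.triangle()
    ok = ~np.isnan(a) & ~np.isnan(b)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("vectorize: excluded %d undefined pair(s)", n_dropped)
    if ok.sum() < 3:
        raise InvalidArgumentError("fewer than 3 usable species pairs")
    return a[ok], b[ok]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise DegenerateMatrixError("degenerate distance matrix: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _masked_pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise pairwise-complete Pearson r between each row of X and y.

    NaN in a row of X or in y drops that entry for that row.  Rows with a
    degenerate (zero-variance) overlap yield NaN.
    """
    valid = ~np.isnan(X) & ~np.isnan(y)[None, :]
    Xz = np.where(valid, X, 0.0)
    Yz = np.where(valid, y[None, :], 0.0)
    n = valid.sum(axis=1).astype(float)
    sx = Xz.sum(axis=1)
    sy = Yz.sum(axis=1)
    sxx = (Xz * Xz).sum(axis=1)
    syy = (Yz * Yz).sum(axis=1)
    sxy = (Xz * Yz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        return np.where((n >= 3) & (den > 0), num / den, np.nan)


def _permuted_triangles(
    values: np.ndarray, perms: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Lower-triangle vectors of ``values`` under each joint permutation."""
    return values[perms[:, iu[0]], perms[:, iu[1]]]


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    n_boot: int = 10000,
    boot_frac: float = 0.9,
) -> MantelResult:
    """Simple Mantel test of A against B with joint row/column permutation of B.

    Set ``n_boot=0`` to skip the bootstrap CI (bounds reported as NaN).
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    _check_aligned(A, B)
    a_vec, b_vec = vectorize_pair(A, B)
    r_obs = _pearson(a_vec, b_vec)

    rng = np.random.default_rng(seed)
    n = A.n
    iu = np.triu_indices(n, k=1)
    a_tri = A.triangle()
    n_exceed = 0
    n_degenerate = 0
    for start in range(0, n_perm, _PERM_CHUNK):
        m = min(_PERM_CHUNK, n_perm - start)
        perms = np.argsort(rng.random((m, n)), axis=1)
        b_perm = _permuted_triangles(B.values, perms, iu)
        r_perm = _masked_pearson_rows(b_perm, a_tri)
        n_degenerate += int(np.isnan(r_perm).sum())
        n_exceed += int(np.sum(r_perm >= r_obs - 1e-12))
    if n_degenerate:
        logger.info("mantel: %d degenerate permutation(s) excluded", n_degenerate)
    p = (1 + n_exceed) / (n_perm + 1)

    if n_boot > 0:
        ci_low, ci_high = bootstrap_ci(
            A, B, n_boot=n_boot, frac=boot_frac, seed=_spawn_seed(rng)
        )
    else:
        ci_low = ci_high = float("nan")
    return MantelResult(
        r_obs=r_obs,
        p_one_tailed=float(p),
        ci_low=ci_low,
        ci_high=ci_high,
        n_species=n,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=-1 if seed is None else int(seed),
    )


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def exact_mantel(A: DistanceMatrix, B: DistanceMatrix) -> float:
    """Exact one-tailed p by full enumeration of all n! joint permutations.

    p = #{pi : r_pi >= r_obs} / n!, the identity included.  Refuses n > 8
    (the enumeration grows factorially).
    """
    _check_aligned(A, B)
    n = A.n
    if n > 8:
        raise InvalidArgumentError(f"exact enumeration refused for n={n} > 8")
    a_vec, b_vec = vectorize_pair(A, B)
    r_obs = _pearson(a_vec, b_vec)
    iu = np.triu_indices(n, k=1)
    a_tri = A.triangle()
    perms = np.array(list(_all_permutations(range(n))))
    count = 0
    for start in range(0, len(perms), _PERM_CHUNK):
        block = perms[start : start + _PERM_CHUNK]
        r_perm = _masked_pearson_rows(_permuted_triangles(B.values, block, iu), a_tri)
        count += int(np.sum(r_perm >= r_obs - 1e-12))
    return count / math.factorial(n)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    den = (1 - r_ac**2) * (1 - r_bc**2)
    if den <= 0:
        raise CollinearMatricesError("collinear matrices: |r| = 1 with the covariate")
    return (r_ab - r_ac * r_bc) / math.sqrt(den)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    n_boot: int = 10000,
    boot_frac: float = 0.9,
    method: str = "raw",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    ``method="raw"`` permutes B and recomputes r_AB and r_BC each time
    (r_AC is fixed); ``method="residual"`` regresses the A and B triangles
    on C's first and permutes B's residual vector entries.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if method not in {"raw", "residual"}:
        raise InvalidArgumentError(f"unknown partial-permutation method {method!r}")
    _check_aligned(A, B, C)
    n = A.n
    tri = np.column_stack([A.triangle(), B.triangle(), C.triangle()])
    ok = ~np.isnan(tri).any(axis=1)
    if ok.sum() < 3:
        raise InvalidArgumentError("fewer than 3 usable species pairs")
    a_vec, b_vec, c_vec = tri[ok].T
    r_ab = _pearson(a_vec, b_vec)
    r_ac = _pearson(a_vec, c_vec)
    r_bc = _pearson(b_vec, c_vec)
    r_obs = _partial_r(r_ab, r_ac, r_bc)

    rng = np.random.default_rng(seed)
    n_exceed = 0
    if method == "raw":
        iu = np.triu_indices(n, k=1)
        # A/C entries are fixed under the null; mask B's permuted triangle
        # against the joint validity of A and C.
        a_tri = np.where(ok_full := _joint_mask(A, C), A.triangle(), np.nan)
        c_tri = np.where(ok_full, C.triangle(), np.nan)
        for start in range(0, n_perm, _PERM_CHUNK):
            m = min(_PERM_CHUNK, n_perm - start)
            perms = np.argsort(rng.random((m, n)), axis=1)
            b_perm = _permuted_triangles(B.values, perms, iu)
            r_ab_p = _masked_pearson_rows(b_perm, a_tri)
            r_bc_p = _masked_pearson_rows(b_perm, c_tri)
            with np.errstate(invalid="ignore", divide="ignore"):
                den = (1 - r_ac**2) * (1 - r_bc_p**2)
                r_p = np.where(den > 0, (r_ab_p - r_ac * r_bc_p) / np.sqrt(den), np.nan)
            n_exceed += int(np.sum(r_p >= r_obs - 1e-12))
    else:  # residual permutation (Legendre method 1 style)
        resid_a = a_vec - np.polyval(np.polyfit(c_vec, a_vec, 1), c_vec)
        resid_b = b_vec - np.polyval(np.polyfit(c_vec, b_vec, 1), c_vec)
        r_obs_res = _pearson(resid_a, resid_b)
        for _ in range(n_perm):
            rb = rng.permutation(resid_b)
            if np.corrcoef(resid_a, rb)[0, 1] >= r_obs_res - 1e-12:
                n_exceed += 1
    p = (1 + n_exceed) / (n_perm + 1)

    if n_boot > 0:
        ci_low, ci_high = bootstrap_ci(
            A, B, C=C, n_boot=n_boot, frac=boot_frac, seed=_spawn_seed(rng)
        )
    else:
        ci_low = ci_high = float("nan")
    return MantelResult(
        r_obs=float(r_obs),
        p_one_tailed=float(p),
        ci_low=ci_low,
        ci_high=ci_high,
        n_species=n,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=-1 if seed is None else int(seed),
        partial=True,
    )


def _joint_mask(A: DistanceMatrix, C: DistanceMatrix) -> np.ndarray:
    return ~np.isnan(A.triangle()) & ~np.isnan(C.triangle())


def bootstrap_ci(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix | None = None,
    n_boot: int = 10000,
    frac: float = 0.9,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% CI for (partial) Mantel r by species subsampling without replacement.

    Each repeat draws ``ceil(frac * n)`` species, recomputes r on the induced
    submatrices, and the 2.5th/97.5th percentiles of the replicate
    distribution are returned.  Degenerate repeats are discarded and logged;
    more than 50% discarded raises.
    """
    if not (0 < frac <= 1):
        raise InvalidArgumentError("frac must be in (0, 1]")
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    mats = (A, B) if C is None else (A, B, C)
    _check_aligned(*mats)
    n = A.n
    m = math.ceil(frac * n)
    if m < 3:
        raise InvalidArgumentError("subsample too small: fewer than 3 species")
    rng = np.random.default_rng(seed)
    sub_iu = np.triu_indices(m, k=1)
    reps = []
    n_bad = 0
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        tri = [mat.values[np.ix_(idx, idx)][sub_iu] for mat in mats]
        ok = ~np.isnan(np.column_stack(tri)).any(axis=1)
        if ok.sum() < 3:
            n_bad += 1
            continue
        vecs = [t[ok] for t in tri]
        try:
            if C is None:
                reps.append(_pearson(vecs[0], vecs[1]))
            else:
                reps.append(
                    _partial_r(
                        _pearson(vecs[0], vecs[1]),
                        _pearson(vecs[0], vecs[2]),
                        _pearson(vecs[1], vecs[2]),
                    )
                )
        except (DegenerateMatrixError, CollinearMatricesError):
            n_bad += 1
    if n_bad:
        logger.info("bootstrap: discarded %d degenerate repeat(s)", n_bad)
    if n_bad > n_boot / 2:
        raise DegenerateMatrixError(
            f"bootstrap unusable: {n_bad}/{n_boot} degenerate repeats"
        )
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)
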