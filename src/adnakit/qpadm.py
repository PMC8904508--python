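"""qpWave rank tests and qpAdm admixture-weight estimation.

Both operate on the matrix X of f4 statistics X_ij = f4(l0, l_i; r0, r_j)
for "left" populations L = [target, sources...] against "right" outgroups
R = [reference, others...], with a block-jackknife covariance Q of vec(X).
qpWave asks what rank X has (how many independent ancestry streams relate
L to R); qpAdm finds mixture weights w (summing to 1) that drive the
target's f4 vector to a combination of the sources', by generalized least
squares, and reports a tail probability from the rank test of the full
left set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import stream
from .fstats import AlleleCounts, BlockPartition, f4_per_snp

__all__ = [
    "LeftRightConfig",
    "F4Matrix",
    "QpWaveResult",
    "QpAdmResult",
    "build_f4_matrix",
    "qpwave_rank_test",
    "qpadm_weights",
    "CollinearSourcesError",
    "SingularCovarianceError",
]


class CollinearSourcesError(ValueError):
    pass


class SingularCovarianceError(ValueError):
    pass


@dataclass
class LeftRightConfig:
    """Left (target first, then sources) and right (outgroups, reference
    first) population lists; ``allsnps`` computes each f4 entry on its own
    maximal SNP set instead of the global intersection."""

    left: list[str]
    right: list[str]
    allsnps: bool = True

    def __post_init__(self):
        if set(self.left) & set(self.right):
            raise ValueError("left and right population lists overlap")
        if len(self.right) < 3:
            raise ValueError("need >= 2 right populations beyond the reference")
        if len(self.left) < 2:
            raise ValueError("need >= 2 left populations")


@dataclass
class F4Matrix:
    """f4 matrix with jackknife machinery attached."""

    X: np.ndarray  # (m, k) = (|L|-1, |R|-1)
    Q: np.ndarray  # (m*k, m*k) covariance of vec(X), row-major
    loo: np.ndarray  # (g, m, k) leave-one-block-out matrices
    n_snps: np.ndarray  # (m, k) SNPs used per entry
    left: list[str] = field(default_factory=list)
    right: list[str] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return self.loo.shape[0]


def build_f4_matrix(
    counts: AlleleCounts, config: LeftRightConfig, partition: BlockPartition
) -> F4Matrix:
    """X_ij = f4(l0, l_i; r0, r_j) with delete-one-block jackknife covariance."""
    L, R = config.left, config.right
    m, k = len(L) - 1, len(R) - 1
    ids = partition.block_ids
    g = partition.n_blocks
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")

    if not config.allsnps:
        shared = np.ones(counts.n_snps, dtype=bool)
        for p in L + R:
            shared &= counts.size(p) >= 1
        if not shared.any():
            raise ValueError("no globally shared SNPs (try allsnps=True)")

    sums = np.zeros((g, m, k))
    nums = np.zeros((g, m, k))
    for i in range(m):
        for j in range(k):
            v, valid = f4_per_snp(counts, L[0], L[i + 1], R[0], R[j + 1])
            if not config.allsnps:
                valid = valid & shared
            if not valid.any():
                raise ValueError(
                    f"no SNPs for f4({L[0]},{L[i+1]};{R[0]},{R[j+1]})"
                )
            wv = np.where(valid, v, 0.0)
            sums[:, i, j] = np.bincount(ids, weights=wv, minlength=g)
            nums[:, i, j] = np.bincount(
                ids, weights=valid.astype(float), minlength=g
            )
    tot_s, tot_n = sums.sum(axis=0), nums.sum(axis=0)
    X = tot_s / tot_n
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_s - sums) / (tot_n - nums)
    # blocks empty for an entry contribute its full-data value (no-op)
    loo = np.where(np.isfinite(loo), loo, X)
    vecs = loo.reshape(g, m * k)
    center = vecs.mean(axis=0)
    dev = vecs - center
    Q = (g - 1) / g * (dev.T @ dev)
    return F4Matrix(X, Q, loo, tot_n, list(L), list(R))


def _regularized_inverse(Q: np.ndarray, max_ridge: float = 1e-3):
    """Inverse of Q with an escalating ridge (1e-6 .. 1e-3 of mean diag)."""
    scale = float(np.mean(np.diag(Q)))
    eps = 1e-6
    while eps <= max_ridge:
        Qr = Q + eps * scale * np.eye(Q.shape[0])
        cond = np.linalg.cond(Qr)
        if cond < 1e10:
            return np.linalg.inv(Qr), cond
        eps *= 10
    raise SingularCovarianceError(
        f"covariance singular even at ridge {max_ridge} "
        f"(condition number {cond:.3g})"
    )


@dataclass
class QpWaveResult:
    rank: int
    statistic: float
    df: int
    p_value: float


def _rank_r_fit(X, Qinv, r, seed, n_restarts=10, n_iter=200, tol=1e-10):
    """min over rank-r Xhat of vec(X-Xhat)' Qinv vec(X-Xhat), by alternating
    generalized least squares on the factors (10 seeded restarts)."""
    m, k = X.shape
    v = X.reshape(-1)
    if r == 0:
        return float(v @ Qinv @ v)
    best = np.inf
    rng = stream(seed, "qpwave-als")
    chol = np.linalg.cholesky(Qinv)
    W = chol.T  # whitening: ||W (v - vec(Xhat))||^2
    for _ in range(n_restarts):
        B = rng.standard_normal((k, r))
        prev = np.inf
        for _ in range(n_iter):
            # vec(A B') = (B kron I_m)... using row-major: vec(Xhat)[i*k+j]
            MA = np.zeros((m * k, m * r))
            for i in range(m):
                MA[i * k : (i + 1) * k, i * r : (i + 1) * r] = B
            a, *_ = np.linalg.lstsq(W @ MA, W @ v, rcond=None)
            A = a.reshape(m, r)
            MB = np.zeros((m * k, k * r))
            for i in range(m):
                for j in range(k):
                    MB[i * k + j, j * r : (j + 1) * r] = A[i]
            b, *_ = np.linalg.lstsq(W @ MB, W @ v, rcond=None)
            B = b.reshape(k, r)
            resid = v - (A @ B.T).reshape(-1)
            obj = float(resid @ Qinv @ resid)
            if prev - obj < tol * max(prev, 1e-30):
                break
            prev = obj
        best = min(best, obj)
    return best


def qpwave_rank_test(
    f4m: F4Matrix, rank: int, seed: int = 0
) -> QpWaveResult:
    """Chi-square test of 'X has rank <= r'.

    df = (m - r)(k - r); the statistic is the Q-weighted distance from X to
    the nearest rank-r matrix.
    """
    m, k = f4m.X.shape
    if not 0 <= rank < min(m, k):
        raise ValueError(f"rank must lie in [0, {min(m, k) - 1}]")
    Qinv, _ = _regularized_inverse(f4m.Q)
    statistic = _rank_r_fit(f4m.X, Qinv, rank, seed)
    df = (m - rank) * (k - rank)
    p = float(stats.chi2.sf(statistic, df))
    return QpWaveResult(rank, statistic, df, p)


@dataclass
class QpAdmResult:
    weights: np.ndarray  # sums to 1 exactly
    se: np.ndarray
    p_value: float  # tail p of the rank-(k-1) test with target included
    feasible: bool  # all weights in [0, 1]
    sources: list[str] = field(default_factory=list)
    precision: float = np.nan  # min eigenvalue of the GLS normal matrix;
    # ~0 flags rights that do not differentiate the sources
    rank_result: QpWaveResult | None = None


def _solve_weights(X, Q, n_iter=30, tol=1e-12):
    """Fixed-point GLS for w: min_w d' Q_d(w)^{-1} d with d = X' w, sum w = 1.

    Q_d(w) = (w kron I)' Q (w kron I) under row-major vec ordering.
    Returns (w, precision) where precision is the smallest eigenvalue of
    the GLS normal matrix M = X Q_d^{-1} X' — near-zero when the rights do
    not differentiate the sources (weights then have huge variance).
    """
    m, k = X.shape
    w = np.full(m, 1.0 / m)
    Qt = Q.reshape(m, k, m, k)
    M = np.eye(m)
    for _ in range(n_iter):
        Qd = np.einsum("i,ikjl,j->kl", w, Qt, w)
        Qd_inv, _ = _regularized_inverse(Qd)
        M = X @ Qd_inv @ X.T
        try:
            Minv = np.linalg.inv(M + 1e-12 * np.mean(np.diag(M)) * np.eye(m))
        except np.linalg.LinAlgError as e:
            raise CollinearSourcesError(str(e)) from e
        ones = np.ones(m)
        w_new = Minv @ ones / (ones @ Minv @ ones)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return w, float(np.linalg.eigvalsh(M).min())


def qpadm_weights(
    counts: AlleleCounts,
    config: LeftRightConfig,
    partition: BlockPartition,
    seed: int = 0,
) -> QpAdmResult:
    """Mixture weights of left[0] as a combination of left[1:].

    Weights solve the generalized least squares problem sum_i w_i
    f4(target, s_i; r0, r_j) ~ 0 for all j, subject to sum w = 1 (the
    target-minus-mixture lineage shares no drift with any right). SEs come
    from leave-one-block-out re-solves; the tail p-value is the qpWave test
    of rank |sources| - 1 on the same matrix. Weights outside [0, 1] are
    reported (feasible=False), never clamped.
    """
    if len(config.left) < 3:
        raise ValueError("need a target and at least 2 sources")
    sources = config.left[1:]
    f4m = build_f4_matrix(counts, config, partition)
    X, Q = f4m.X, f4m.Q
    m = X.shape[0]

    # collinearity diagnostic: near-proportional source rows (a zero row is
    # fine — the target itself matches that source and takes weight ~ 1)
    norms = np.maximum(np.linalg.norm(X, axis=1), 1e-300)
    G = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.fill_diagonal(G, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(G)), G.shape)
    if abs(G[i, j]) > 1 - 1e-10:
        raise CollinearSourcesError(
            f"sources {sources[i]!r} and {sources[j]!r} are collinear "
            "on these rights"
        )

    w, precision = _solve_weights(X, Q)

    # jackknife SEs: re-solve on each leave-one-block-out matrix
    g = f4m.n_blocks
    w_loo = np.empty((g, m))
    for b in range(g):
        w_loo[b], _ = _solve_weights(f4m.loo[b], Q)
    se = np.sqrt((g - 1) / g * ((w_loo - w_loo.mean(axis=0)) ** 2).sum(axis=0))

    rank_res = qpwave_rank_test(f4m, m - 1, seed=seed)
    feasible = bool(np.all((w >= 0) & (w <= 1)))
    return QpAdmResult(
        w, se, rank_res.p_value, feasible, list(sources), precision, rank_res
    )
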