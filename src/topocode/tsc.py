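"""Topographic sparse coding: grouped smoothed-L1 dictionary learning.

Samples ``x`` (d x N, columns are feature vectors) are decomposed over a
dictionary ``A`` (d x k) with codes ``s`` (k x N) so that ``x = A s + r``.
The objective penalizes reconstruction error, a *topographic* group
sparsity term, and dictionary energy:

    J(A, s) = ||A s - x||_2^2
              + lambda * sum_{g,n} sqrt( (V (s o s))_{g,n} + eps )
              + gamma * ||A||_2^2            s.t.  ||s_n||_2^2 <= C

where ``V`` is a binary grouping matrix whose rows are overlapping
neighborhoods of dictionary atoms arranged on a 2-D grid, ``o`` is the
elementwise square, and ``eps > 0`` smooths the group-L1 term so plain
gradient methods apply. With singleton groups and ``eps -> 0`` the
penalty reduces to the entrywise L1 norm of ``s``. Because co-active
atoms pay less when they share a group, neighboring atoms on the grid
learn similar features — the topographic-map property the method models.

Optimization alternates mini-batch code updates (projected gradient
descent with backtracking line search; ``A`` fixed) and dictionary
gradient steps (codes fixed) followed by column renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GroupingMatrix",
    "TscConfig",
    "ReconstructionResult",
    "ObjectiveTerms",
    "OptimizationTrace",
    "TraceRecord",
    "DivergenceError",
    "build_grouping_matrix",
    "smoothed_group_penalty",
    "objective",
    "grad_codes",
    "grad_dictionary",
    "init_codes",
    "project_codes",
    "encode",
    "learn",
    "match_atoms",
]


class DivergenceError(RuntimeError):
    """Raised when the optimizer produces a non-finite objective."""


@dataclass(frozen=True)
class GroupingMatrix:
    """Binary G x k matrix assigning dictionary atoms to grid neighborhoods.

    Atoms are indexed row-major on a ``grid_rows x grid_cols`` grid. Each
    row of ``values`` is one group: the ``group_size x group_size`` window
    anchored at one grid position (toroidal when ``wraparound``). With
    wraparound there is one group per atom, so G = k.
    """

    values: np.ndarray
    grid_rows: int
    grid_cols: int
    group_size: int
    wraparound: bool

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TscConfig:
    """Hyperparameters of the topographic sparse coding objective and solver.

    lambda_ : weight of the group-sparsity penalty.
    gamma : weight-decay coefficient on ||A||^2.
    epsilon : smoothing constant inside the group square roots; must be > 0
        for the gradients to exist everywhere.
    C : per-column bound on ||s_n||^2, enforced by projection
        (``math.inf`` disables the constraint).
    k : number of dictionary atoms; must equal grid_rows * grid_cols.
    group_size : side length of the square topographic neighborhood.
    """

    lambda_: float = 0.1
    gamma: float = 0.1
    epsilon: float = 1e-2
    C: float = 1.0
    k: int = 121
    group_size: int = 3
    grid_rows: int | None = None
    grid_cols: int | None = None
    wraparound: bool = True
    batch_size: int = 256
    max_outer_iters: int = 100
    max_inner_iters: int = 200
    tol_rel: float = 1e-6
    step_init: float = 1.0
    dict_steps: int = 1
    init: str = "data"  # "data": atoms seeded from sample columns; "gaussian"
    atom_refresh_every: int = 40  # 0 disables the refresh heuristic
    refresh_coherence: float = 0.9
    refresh_usage_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.gamma < 0:
            raise ValueError("lambda_ and gamma must be nonnegative")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if not (self.C > 0):
            raise ValueError("C must be positive (use math.inf to disable)")
        if self.k <= 0 or self.group_size <= 0:
            raise ValueError("k and group_size must be positive")
        if self.batch_size <= 0 or self.max_outer_iters <= 0 or self.max_inner_iters <= 0:
            raise ValueError("iteration counts and batch_size must be positive")
        if self.step_init <= 0 or self.tol_rel <= 0:
            raise ValueError("step_init and tol_rel must be positive")
        if self.init not in ("data", "gaussian"):
            raise ValueError("init must be 'data' or 'gaussian'")
        if self.atom_refresh_every < 0:
            raise ValueError("atom_refresh_every must be nonnegative")
        r, c = self.grid_shape()
        if r * c != self.k:
            raise ValueError(f"k={self.k} is not grid_rows*grid_cols={r}*{c}")

    def grid_shape(self) -> tuple[int, int]:
        """Atom-grid dimensions; defaults to a square sqrt(k) x sqrt(k) grid."""
        if self.grid_rows is not None and self.grid_cols is not None:
            return self.grid_rows, self.grid_cols
        root = math.isqrt(self.k)
        if root * root != self.k:
            raise ValueError(
                f"k={self.k} is not a perfect square; set grid_rows/grid_cols explicitly"
            )
        return root, root


@dataclass(frozen=True)
class ReconstructionResult:
    """A·s, the residual r = x − A·s, and the squared reconstruction error."""

    reconstruction: np.ndarray
    residual: np.ndarray
    sse: float


@dataclass(frozen=True)
class ObjectiveTerms:
    """Value of J and its additive decomposition."""

    J: float
    sse: float
    penalty: float
    decay: float
    recon: ReconstructionResult


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    J: float
    sse: float
    penalty: float
    decay: float
    step: float
    batch: tuple[int, ...] | None = None


@dataclass
class OptimizationTrace:
    """Per-iteration objective decomposition; terms sum to J at every record."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, rec: TraceRecord) -> None:
        self.records.append(rec)

    @property
    def objectives(self) -> np.ndarray:
        return np.array([r.J for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def build_grouping_matrix(
    grid_rows: int,
    grid_cols: int,
    group_size: int,
    wraparound: bool = True,
) -> GroupingMatrix:
    """Construct the binary grouping matrix V over a 2-D atom grid.

    One group per anchor position; the group covers the
    ``group_size x group_size`` window whose top-left corner is the
    anchor. With ``wraparound`` the window wraps toroidally and every
    grid position anchors a group (G = k); without it only windows that
    fit inside the grid are kept.
    """
    if group_size > min(grid_rows, grid_cols):
        raise ValueError(
            f"group_size={group_size} exceeds grid {grid_rows}x{grid_cols}"
        )
    k = grid_rows * grid_cols
    if wraparound:
        anchors = [(r, c) for r in range(grid_rows) for c in range(grid_cols)]
    else:
        anchors = [
            (r, c)
            for r in range(grid_rows - group_size + 1)
            for c in range(grid_cols - group_size + 1)
        ]
    V = np.zeros((len(anchors), k), dtype=np.float64)
    for g, (r0, c0) in enumerate(anchors):
        for dr in range(group_size):
            for dc in range(group_size):
                r = (r0 + dr) % grid_rows
                c = (c0 + dc) % grid_cols
                V[g, r * grid_cols + c] = 1.0
    return GroupingMatrix(V, grid_rows, grid_cols, group_size, wraparound)


def _as_V(V: GroupingMatrix | np.ndarray) -> np.ndarray:
    return V.values if isinstance(V, GroupingMatrix) else np.asarray(V, dtype=np.float64)


def smoothed_group_penalty(
    codes: np.ndarray, V: GroupingMatrix | np.ndarray, epsilon: float
) -> float:
    """sum over groups g and samples n of sqrt( sum_{j in g} s_{j,n}^2 + eps )."""
    Vm = _as_V(V)
    s = np.asarray(codes, dtype=np.float64)
    if Vm.shape[1] != s.shape[0]:
        raise ValueError(
            f"grouping matrix has {Vm.shape[1]} atom columns but codes have {s.shape[0]} rows"
        )
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    energy = Vm @ (s * s)
    return float(np.sum(np.sqrt(energy + epsilon)))


def objective(
    A: np.ndarray,
    s: np.ndarray,
    x: np.ndarray,
    V: GroupingMatrix | np.ndarray,
    cfg: TscConfig,
) -> ObjectiveTerms:
    """Evaluate J(A, s) = ||As - x||^2 + lambda*penalty + gamma*||A||^2."""
    A = np.asarray(A, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if A.shape[1] != s.shape[0] or A.shape[0] != x.shape[0] or s.shape[1] != x.shape[1]:
        raise ValueError(
            f"non-conformable shapes A{A.shape}, s{s.shape}, x{x.shape}"
        )
    recon = A @ s
    residual = x - recon
    sse = float(np.sum(residual * residual))
    penalty = smoothed_group_penalty(s, V, cfg.epsilon)
    decay = float(np.sum(A * A))
    J = sse + cfg.lambda_ * penalty + cfg.gamma * decay
    return ObjectiveTerms(
        J=J,
        sse=sse,
        penalty=penalty,
        decay=decay,
        recon=ReconstructionResult(recon, residual, sse),
    )


def grad_codes(
    A: np.ndarray,
    s: np.ndarray,
    x: np.ndarray,
    V: GroupingMatrix | np.ndarray,
    cfg: TscConfig,
) -> np.ndarray:
    """dJ/ds = 2 A^T (As - x) + lambda * s * (V^T (V(s o s) + eps)^{-1/2}).

    Each coefficient is weighted by the sum over the groups containing
    its atom of the reciprocal smoothed group magnitude. Requires
    epsilon > 0 (the unsmoothed penalty is not differentiable at zero).
    """
    if cfg.epsilon <= 0:
        raise ValueError("grad_codes requires epsilon > 0")
    A = np.asarray(A, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    Vm = _as_V(V)
    grad = 2.0 * (A.T @ (A @ s - x))
    if cfg.lambda_ != 0:
        inv_mag = 1.0 / np.sqrt(Vm @ (s * s) + cfg.epsilon)
        grad += cfg.lambda_ * s * (Vm.T @ inv_mag)
    return grad


def grad_dictionary(
    A: np.ndarray, s: np.ndarray, x: np.ndarray, cfg: TscConfig
) -> np.ndarray:
    """dJ/dA = 2 (As - x) s^T + 2 gamma A."""
    A = np.asarray(A, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if A.shape[1] != s.shape[0] or A.shape[0] != x.shape[0] or s.shape[1] != x.shape[1]:
        raise ValueError(
            f"non-conformable shapes A{A.shape}, s{s.shape}, x{x.shape}"
        )
    return 2.0 * ((A @ s - x) @ s.T) + 2.0 * cfg.gamma * A


def init_codes(A: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Initial codes s = A^T x with row r divided by the norm of atom r."""
    A = np.asarray(A, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("dictionary contains a zero-norm atom")
    return (A.T @ x) / norms[:, None]


def project_codes(s: np.ndarray, C: float) -> np.ndarray:
    """Rescale any code column with squared norm > C onto the C-ball."""
    if not np.isfinite(C):
        return s
    sq = np.sum(s * s, axis=0)
    scale = np.ones_like(sq)
    over = sq > C
    scale[over] = np.sqrt(C / sq[over])
    return s * scale


def encode(
    A: np.ndarray,
    x: np.ndarray,
    V: GroupingMatrix | np.ndarray,
    cfg: TscConfig,
    s0: np.ndarray | None = None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Minimize J over the codes with A fixed (a convex problem).

    Projected gradient descent with backtracking line search from the
    analytic initialization (or ``s0``). A step is accepted only if it
    satisfies a sufficient-decrease condition after projection onto the
    per-column C-ball, so the traced objective sequence is non-increasing.
    Terminates when the relative objective change drops below
    ``cfg.tol_rel`` or after ``cfg.max_inner_iters`` iterations.
    """
    A = np.asarray(A, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    s = init_codes(A, x) if s0 is None else np.array(s0, dtype=np.float64)
    s = project_codes(s, cfg.C)
    terms = objective(A, s, x, V, cfg)
    if not np.isfinite(terms.J):
        raise DivergenceError("non-finite objective at initialization")
    trace = OptimizationTrace()
    trace.append(TraceRecord(0, terms.J, terms.sse, terms.penalty, terms.decay, 0.0))
    step = cfg.step_init
    for it in range(1, cfg.max_inner_iters + 1):
        g = grad_codes(A, s, x, V, cfg)
        t = step
        accepted = False
        for _ in range(60):
            s_new = project_codes(s - t * g, cfg.C)
            terms_new = objective(A, s_new, x, V, cfg)
            if not np.isfinite(terms_new.J):
                raise DivergenceError(f"non-finite objective at iteration {it}")
            # Armijo sufficient decrease for projected gradient steps
            decrease = 1e-4 / t * float(np.sum((s_new - s) ** 2))
            if terms_new.J <= terms.J - decrease:
                accepted = True
                break
            t *= 0.5
            if t < 1e-15:
                break
        if not accepted:
            break
        rel_change = abs(terms.J - terms_new.J) / max(abs(terms.J), 1.0)
        s, terms = s_new, terms_new
        trace.append(
            TraceRecord(it, terms.J, terms.sse, terms.penalty, terms.decay, t)
        )
        step = min(t * 2.0, 1e3 * cfg.step_init)
        if rel_change < cfg.tol_rel:
            break
    return s, trace


def _dict_objective(A: np.ndarray, s: np.ndarray, x: np.ndarray, gamma: float) -> float:
    r = A @ s - x
    return float(np.sum(r * r) + gamma * np.sum(A * A))


def _dict_step(
    A: np.ndarray, s: np.ndarray, x: np.ndarray, cfg: TscConfig, step: float
) -> tuple[np.ndarray, float]:
    """One backtracking gradient step on the A-dependent part of J."""
    f0 = _dict_objective(A, s, x, cfg.gamma)
    g = grad_dictionary(A, s, x, cfg)
    gnorm2 = float(np.sum(g * g))
    t = step
    for _ in range(60):
        A_new = A - t * g
        if _dict_objective(A_new, s, x, cfg.gamma) <= f0 - 1e-4 * t * gnorm2:
            return A_new, t
        t *= 0.5
        if t < 1e-15:
            break
    return A, 0.0


# refresh is suspended this many outer iterations before the budget ends
# so the dictionary settles after the last atom replacement
_REFRESH_SETTLE = 60


def _refresh_atoms(
    A: np.ndarray,
    x: np.ndarray,
    V: GroupingMatrix | np.ndarray,
    cfg: TscConfig,
) -> np.ndarray:
    """Replace underused or near-duplicate atoms with directions of the
    worst-reconstructed residuals (the classical dictionary-learning
    escape from dead-atom and duplicate-atom local minima)."""
    s_full, _ = encode(A, x, V, cfg)
    usage = np.abs(s_full).mean(axis=1)
    resid = x - A @ s_full
    errs = np.sum(resid * resid, axis=0)
    gram = np.abs(A.T @ A)
    np.fill_diagonal(gram, 0.0)
    bad = set(np.flatnonzero(usage < cfg.refresh_usage_frac * usage.max()).tolist())
    for j in range(A.shape[1]):
        jj = int(np.argmax(gram[j]))
        if gram[j, jj] > cfg.refresh_coherence and jj not in bad:
            bad.add(j)
    A = A.copy()
    for j in sorted(bad):
        w = int(np.argmax(errs))
        v = resid[:, w]
        nv = np.linalg.norm(v)
        if nv > 1e-9:
            A[:, j] = v / nv
        errs[w] = 0.0
    return A


def learn(
    x: np.ndarray,
    cfg: TscConfig,
    V: GroupingMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, OptimizationTrace]:
    """Learn dictionary and codes by alternating mini-batch minimization.

    Each outer iteration (i) draws a mini-batch of sample columns with
    the seeded RNG, (ii) optimizes the batch codes with A fixed,
    (iii) takes backtracking gradient step(s) on A with the codes fixed,
    and (iv) renormalizes the atoms to unit norm. Convergence is declared
    when the relative change of the full-data objective (with freshly
    encoded codes) falls below ``cfg.tol_rel``.

    Every ``cfg.atom_refresh_every`` iterations, atoms that are barely
    used or nearly duplicate another atom are replaced by the direction
    of a poorly reconstructed residual. The refresh escapes permutation
    local minima but may transiently raise the objective; with
    ``atom_refresh_every=0`` (and full-batch ``batch_size >= N``) the
    procedure is plain alternating minimization and the traced objective
    is non-increasing.

    Returns the learned dictionary, full-data codes, and the outer trace.
    """
    x = np.asarray(x, dtype=np.float64)
    d, N = x.shape
    batch_size = min(cfg.batch_size, N)
    rng = np.random.default_rng(cfg.seed)
    grid_r, grid_c = cfg.grid_shape()
    if V is None:
        V = build_grouping_matrix(grid_r, grid_c, cfg.group_size, cfg.wraparound)
    if cfg.init == "data":
        cols = rng.choice(N, size=cfg.k, replace=N < cfg.k)
        A = x[:, cols] + 1e-6 * rng.standard_normal((d, cfg.k))
    else:
        A = rng.standard_normal((d, cfg.k))
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A = A / norms

    s_full, _ = encode(A, x, V, cfg)
    terms = objective(A, s_full, x, V, cfg)
    trace = OptimizationTrace()
    trace.append(TraceRecord(0, terms.J, terms.sse, terms.penalty, terms.decay, 0.0))
    dict_step_size = cfg.step_init
    patience = 0

    for outer in range(1, cfg.max_outer_iters + 1):
        idx = rng.choice(N, size=batch_size, replace=False)
        xb = x[:, idx]
        sb, _ = encode(A, xb, V, cfg)
        for _ in range(cfg.dict_steps):
            A, used = _dict_step(A, sb, xb, cfg, dict_step_size)
            if used > 0:
                dict_step_size = min(used * 2.0, 1e3 * cfg.step_init)
            else:
                dict_step_size = max(dict_step_size * 0.5, 1e-12)
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        A = A / norms

        if (
            cfg.atom_refresh_every > 0
            and outer % cfg.atom_refresh_every == 0
            and outer <= cfg.max_outer_iters - _REFRESH_SETTLE
        ):
            A = _refresh_atoms(A, x, V, cfg)

        s_full, _ = encode(A, x, V, cfg)
        terms_new = objective(A, s_full, x, V, cfg)
        if not np.isfinite(terms_new.J):
            raise DivergenceError(f"non-finite objective at outer iteration {outer}")
        trace.append(
            TraceRecord(
                outer,
                terms_new.J,
                terms_new.sse,
                terms_new.penalty,
                terms_new.decay,
                dict_step_size,
                batch=tuple(int(i) for i in idx),
            )
        )
        rel_change = abs(terms.J - terms_new.J) / max(abs(terms.J), 1.0)
        terms = terms_new
        # with mini-batches the objective fluctuates, so one small change
        # is not convergence; require a run of them
        patience_needed = 1 if batch_size >= N else 5
        if rel_change < cfg.tol_rel:
            patience += 1
            if patience >= patience_needed:
                break
        else:
            patience = 0
    return A, s_full, trace


def match_atoms(learned: np.ndarray, truth: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Greedy sign/permutation matching between two dictionaries.

    Repeatedly pairs the learned/true atom pair with the largest absolute
    cosine similarity, removing both from further consideration. Returns
    the pairing and the mean absolute cosine similarity over pairs.
    """
    L = learned / np.linalg.norm(learned, axis=0, keepdims=True)
    T = truth / np.linalg.norm(truth, axis=0, keepdims=True)
    sim = np.abs(L.T @ T)
    n = min(sim.shape)
    pairs: list[tuple[int, int]] = []
    scores: list[float] = []
    work = sim.copy()
    for _ in range(n):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j)))
        scores.append(float(work[i, j]))
        work[i, :] = -1.0
        work[:, j] = -1.0
    return pairs, float(np.mean(scores))
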