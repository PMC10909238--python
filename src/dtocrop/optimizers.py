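"""Population-based swarm optimizers for bounded minimization.

Three algorithms against one interface:

* **DTO** (dipper-throated optimization): a bird-foraging swarm keeping
  positions P, velocities V, per-individual bests and a global best.  Each
  individual either swoops toward its personal best,

      X = P_best(i) - K1 * |K2 * P_best(i) - P(i)|,

  or follows a velocity update

      V(i+1) = K3*V(i) + K4*r1*(P_best(i) - P(i)) + K5*r2*(P_Gbest - P(i)),
      Y = P(i) + V(i+1),

  taking X when r3 < 0.5 and Y otherwise.  K4 = 1.7 and K5 = 1.8 are fixed
  coefficients; K1, K2, K3 are drawn fresh per individual per iteration from
  [0, 2]; r1, r2, r3 are uniform on [0, 1].

* **SCA** (sine cosine algorithm): each coordinate moves toward the
  destination (global best) by a sine- or cosine-scaled step,

      X' = X + r1 * sin(r2) * |r3*P - X|   (r4 < 0.5)
      X' = X + r1 * cos(r2) * |r3*P - X|   (r4 >= 0.5)

  with r2 ~ U(0, 2*pi), r3 ~ U(0, 2), r4 ~ U(0, 1) per coordinate and the
  amplitude r1 = a*(1 - t/T) decaying linearly over the budget.

* **MSCA**: SCA hybridized with the firefly attraction move

      x_i' = x_i + beta0 * exp(-gamma * r_ij^2) * (x_j - x_i)
                 + alpha^t * (kappa - 0.5),

  where r_ij is the Euclidean distance to the partner, kappa is a standard
  Gaussian draw per coordinate, and alpha^t = alpha0 * alpha_decay^t.  Each
  solution draws phi ~ U(0, 1) per iteration; the firefly branch fires only
  when phi exceeds the switch threshold (default 0.5) *and* at least one
  third of the iteration budget has elapsed — early iterations run pure SCA
  for stability.

All three are elitist: the recorded global best is never overwritten by a
worse value, so best-fitness histories are non-increasing.  Bound handling is
clipping after every move.  Randomness is split into independent named
streams (init / move / firefly) derived from one seed, so the MSCA trajectory
coincides bit-for-bit with pure SCA whenever the firefly branch never fires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .features import SearchSpace

__all__ = [
    "Swarm",
    "DTOConfig",
    "MSCAConfig",
    "OptimizeResult",
    "dto_step",
    "sca_step",
    "firefly_move",
    "msca_step",
    "optimize",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass
class Swarm:
    """Optimizer population state.

    P and V are (m, d) position and velocity matrices; f the current fitness
    vector; P_best/f_best per-individual bests; P_Gbest/f_Gbest the elitist
    global best (never overwritten by a worse value).
    """

    P: np.ndarray
    V: np.ndarray
    f: np.ndarray
    P_best: np.ndarray
    f_best: np.ndarray
    P_Gbest: np.ndarray
    f_Gbest: float

    @classmethod
    def initialize(
        cls, m: int, space: SearchSpace, objective: Objective, rng: np.random.Generator
    ) -> "Swarm":
        """Uniform random positions over the box, zero velocities."""
        P = rng.uniform(space.lower, space.upper, size=(m, space.dim))
        f = _evaluate_population(objective, P, space, rng)
        best = int(np.argmin(f))
        return cls(
            P=P,
            V=np.zeros_like(P),
            f=f,
            P_best=P.copy(),
            f_best=f.copy(),
            P_Gbest=P[best].copy(),
            f_Gbest=float(f[best]),
        )

    def update_bests(self) -> None:
        """Strict-improvement bookkeeping for per-individual and global bests."""
        improved = self.f < self.f_best
        self.P_best[improved] = self.P[improved]
        self.f_best[improved] = self.f[improved]
        best = int(np.argmin(self.f_best))
        if self.f_best[best] < self.f_Gbest:
            self.f_Gbest = float(self.f_best[best])
            self.P_Gbest = self.P_best[best].copy()


@dataclass(frozen=True)
class DTOConfig:
    """DTO settings: swarm size m, budget T, fixed coefficients K4/K5 and the
    sampling range for the per-step weights K1..K3."""

    m: int = 20
    T: int = 100
    K4: float = 1.7
    K5: float = 1.8
    k_range: tuple[float, float] = (0.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError("swarm size m must be >= 2")
        if self.T < 0:
            raise ConfigurationError("iteration budget T must be >= 0")
        if self.K4 <= 0 or self.K5 <= 0:
            raise ConfigurationError("K4 and K5 must be positive")
        lo, hi = self.k_range
        if not (0.0 <= lo < hi <= 2.0):
            raise ConfigurationError("k_range must be a sub-interval of [0, 2]")


@dataclass(frozen=True)
class MSCAConfig:
    """SCA / firefly-hybrid settings.

    ``a`` scales the linearly decaying SCA amplitude; ``beta0``/``gamma``
    control firefly attraction strength and distance damping; ``alpha0`` and
    ``alpha_decay`` set the Gaussian jitter schedule; ``phi_threshold`` is the
    per-solution switch level and ``activation_fraction`` the fraction of the
    budget before which the firefly branch is disabled.
    """

    m: int = 20
    T: int = 100
    a: float = 2.0
    beta0: float = 1.0
    gamma: float = 1.0
    alpha0: float = 0.2
    alpha_decay: float = 0.97
    phi_threshold: float = 0.5
    activation_fraction: float = 1.0 / 3.0
    fa_partner: str = "gbest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError("swarm size m must be >= 2")
        if self.T < 0:
            raise ConfigurationError("iteration budget T must be >= 0")
        for name in ("a", "beta0", "gamma", "alpha0", "alpha_decay"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 <= self.phi_threshold <= 1.0):
            raise ConfigurationError("phi_threshold must be in [0, 1]")
        if not (0.0 <= self.activation_fraction < 1.0):
            raise ConfigurationError("activation_fraction must be in [0, 1)")
        if self.fa_partner not in ("gbest", "pairwise"):
            raise ConfigurationError("fa_partner must be 'gbest' or 'pairwise'")


def _evaluate_population(
    objective: Objective,
    P: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evaluate every row; non-finite values get one retry, then the
    individual is reset to a random in-bounds position (logged) and, failing
    that too, receives a +inf penalty."""
    f = np.empty(len(P))
    for i, x in enumerate(P):
        val = float(objective(x))
        if not np.isfinite(val):
            val = float(objective(x))  # one retry
        if not np.isfinite(val):
            logger.warning("non-finite fitness at %s; resetting individual %d", x, i)
            P[i] = rng.uniform(space.lower, space.upper, size=space.dim)
            val = float(objective(P[i]))
            if not np.isfinite(val):
                val = np.inf
        f[i] = val
    return f


def dto_step(
    swarm: Swarm,
    objective: Objective,
    space: SearchSpace,
    cfg: DTOConfig,
    t: int,
    rng: np.random.Generator,
) -> Swarm:
    """One DTO iteration (in place): per-individual draws, branch selection,
    clipping, evaluation and elitist best updates.

    Draw order (relevant for seeded reproduction): r = rng.random((m, 3)) for
    (r1, r2, r3), then K = rng.uniform(*k_range, (m, 3)) for (K1, K2, K3).
    """
    m = len(swarm.P)
    r = rng.random((m, 3))
    K = rng.uniform(cfg.k_range[0], cfg.k_range[1], size=(m, 3))
    r1, r2, r3 = r[:, 0:1], r[:, 1:2], r[:, 2:3]
    K1, K2, K3 = K[:, 0:1], K[:, 1:2], K[:, 2:3]

    X = swarm.P_best - K1 * np.abs(K2 * swarm.P_best - swarm.P)
    V_new = (
        K3 * swarm.V
        + cfg.K4 * r1 * (swarm.P_best - swarm.P)
        + cfg.K5 * r2 * (swarm.P_Gbest[None, :] - swarm.P)
    )
    Y = swarm.P + V_new
    swarm.V = V_new
    swarm.P = space.clip(np.where(r3 < 0.5, X, Y))
    swarm.f = _evaluate_population(objective, swarm.P, space, rng)
    swarm.update_bests()
    return swarm


def sca_step(
    positions: np.ndarray,
    best: np.ndarray,
    t: int,
    cfg: MSCAConfig,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
) -> np.ndarray:
    """One SCA position update for a whole population (no evaluation).

    Per-coordinate draws, in order: r2 ~ U(0, 2*pi), r3 ~ U(0, 2),
    r4 ~ U(0, 1), each of shape (m, d).  The amplitude r1 = a*(1 - t/T) is
    deterministic in t.
    """
    if cfg.T == 0:
        raise ConfigurationError("iteration budget T must be positive")
    positions = np.asarray(positions, dtype=float)
    shape = positions.shape
    r2 = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    r3 = rng.uniform(0.0, 2.0, size=shape)
    r4 = rng.random(shape)
    r1 = cfg.a * (1.0 - t / cfg.T)
    step = np.abs(r3 * best[None, :] - positions)
    new = positions + r1 * np.where(r4 < 0.5, np.sin(r2), np.cos(r2)) * step
    return space.clip(new) if space is not None else new


def firefly_move(
    xi: np.ndarray,
    xj: np.ndarray,
    t: int,
    cfg: MSCAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Attraction step of xi toward a brighter solution xj, plus decayed
    Gaussian jitter: xi + beta0*exp(-gamma*r^2)*(xj - xi) + alpha^t*(kappa - 0.5)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ConfigurationError(f"shape mismatch: {xi.shape} vs {xj.shape}")
    r2 = float(np.sum((xj - xi) ** 2))
    alpha_t = cfg.alpha0 * cfg.alpha_decay**t
    jitter = alpha_t * (rng.standard_normal(xi.shape) - 0.5) if cfg.alpha0 > 0 else 0.0
    return xi + cfg.beta0 * np.exp(-cfg.gamma * r2) * (xj - xi) + jitter


def msca_step(
    swarm: Swarm,
    objective: Objective,
    space: SearchSpace,
    cfg: MSCAConfig,
    t: int,
    rng_move: np.random.Generator,
    rng_fa: np.random.Generator,
) -> Swarm:
    """One MSCA iteration (in place).

    The SCA random field is always drawn from ``rng_move`` (whole population
    at once), keeping the move stream aligned with pure SCA; the per-solution
    switch phi and firefly jitter draw only from ``rng_fa`` and only once the
    firefly branch is active (t >= activation_fraction * T).
    """
    m = len(swarm.P)
    sca_new = sca_step(swarm.P, swarm.P_Gbest, t, cfg, rng_move, space=None)

    active = t >= cfg.activation_fraction * cfg.T
    if active:
        phi = rng_fa.random(m)
        fa_rows = np.flatnonzero(phi > cfg.phi_threshold)
    else:
        fa_rows = np.empty(0, dtype=int)

    new = sca_new
    for i in fa_rows:
        if cfg.fa_partner == "gbest":
            new[i] = firefly_move(swarm.P[i], swarm.P_Gbest, t, cfg, rng_fa)
        else:  # pairwise: sequential attraction toward every brighter solution
            xi = swarm.P[i].copy()
            for j in np.flatnonzero(swarm.f < swarm.f[i]):
                xi = firefly_move(xi, swarm.P[j], t, cfg, rng_fa)
            new[i] = xi

    swarm.P = space.clip(new)
    swarm.f = _evaluate_population(objective, swarm.P, space, rng_move)
    swarm.update_bests()
    return swarm


@dataclass
class OptimizeResult:
    """Best position/fitness plus the per-iteration global-best record."""

    x: np.ndarray
    fun: float
    history: np.ndarray
    nfev: int
    algo: str

    def history_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"iteration": np.arange(len(self.history)), "f_gbest": self.history}
        ).to_csv(path, index=False)


def optimize(
    objective: Objective,
    space: SearchSpace,
    algo: str = "dto",
    cfg: DTOConfig | MSCAConfig | None = None,
    callback: Callable[[int, Swarm], None] | None = None,
) -> OptimizeResult:
    """Minimize ``objective`` over the box with the chosen swarm algorithm.

    ``history`` holds f_Gbest after initialization and after each of the T
    iterations (length T+1, non-increasing).  Exactly m*(T+1) objective
    evaluations are performed, plus any retries for non-finite values.  The
    seed in ``cfg`` is split into independent init / move / firefly streams.
    """
    if algo not in ("dto", "sca", "msca"):
        raise ConfigurationError(f"unknown algorithm {algo!r}")
    if cfg is None:
        cfg = DTOConfig() if algo == "dto" else MSCAConfig()
    if algo == "dto" and not isinstance(cfg, DTOConfig):
        raise ConfigurationError("dto requires a DTOConfig")
    if algo in ("sca", "msca") and not isinstance(cfg, MSCAConfig):
        raise ConfigurationError(f"{algo} requires an MSCAConfig")

    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(3)
    rng_init = np.random.default_rng(seeds[0])
    rng_move = np.random.default_rng(seeds[1])
    rng_fa = np.random.default_rng(seeds[2])

    nfev = [0]

    def counted(x: np.ndarray) -> float:
        nfev[0] += 1
        return objective(x)

    swarm = Swarm.initialize(cfg.m, space, counted, rng_init)
    history = [swarm.f_Gbest]
    for t in range(cfg.T):
        if algo == "dto":
            dto_step(swarm, counted, space, cfg, t, rng_move)
        elif algo == "sca":
            swarm.P = sca_step(swarm.P, swarm.P_Gbest, t, cfg, rng_move, space=space)
            swarm.f = _evaluate_population(counted, swarm.P, space, rng_move)
            swarm.update_bests()
        else:
            msca_step(swarm, counted, space, cfg, t, rng_move, rng_fa)
        history.append(swarm.f_Gbest)
        if callback is not None:
            callback(t, swarm)

    return OptimizeResult(
        x=swarm.P_Gbest.copy(),
        fun=swarm.f_Gbest,
        history=np.asarray(history),
        nfev=nfev[0],
        algo=algo,
    )
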