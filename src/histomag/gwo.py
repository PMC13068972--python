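"""Grey Wolf Optimizer over the 5-D ViT hyperparameter space.

Wolves move by encircling the three best solutions (alpha, beta, delta):
D = |C * X_p - X|, X(t+1) = X_p - A * D, with A = 2a*r1 - a, C = 2*r2 and
the control coefficient a decreasing linearly from 2 to 0.  Each wolf's new
position is the average of its three leader-guided candidates, clipped to
the box.  Integer and log-scaled dimensions are optimized in continuous
space and only materialized at decode time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .nn.vit import ViTConfig, validate_config

Dimension = tuple[str, str, float, float]  # (name, kind, lower, upper)


@dataclass
class SearchSpace:
    """Ordered (name, kind, lower, upper) dimensions; kind in
    {continuous, integer, log10}.  Bounds are in the continuous
    representation (log10 dims store exponents)."""

    dimensions: tuple[Dimension, ...] = (
        ("learning_rate", "log10", -5.0, -3.0),
        ("projection_dim", "integer", 64.0, 256.0),
        ("num_heads", "integer", 4.0, 12.0),
        ("depth", "integer", 4.0, 12.0),
        ("dropout", "continuous", 0.05, 0.3),
    )

    def __post_init__(self) -> None:
        names = [d[0] for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ConfigError("dimension names must be unique")
        for name, kind, lo, hi in self.dimensions:
            if kind not in ("continuous", "integer", "log10"):
                raise ConfigError(f"unknown dimension kind {kind!r}")
            if not lo < hi:
                raise ConfigError(f"dimension {name}: lower must be < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([d[2] for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d[3] for d in self.dimensions])

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform within bounds (log-uniform on log10 dims, by construction)."""
        return rng.uniform(self.lower, self.upper)


def coefficient_a(t: int, T: int) -> float:
    """Linear decay 2 * (1 - t / T) from 2 at t=0 to 0 at t=T."""
    if T < 1 or not 0 <= t <= T:
        raise ConfigError("require 0 <= t <= T and T >= 1")
    return 2.0 * (1.0 - t / T)


def encircle(x: np.ndarray, x_p: np.ndarray, a_vec: np.ndarray, c_vec: np.ndarray) -> np.ndarray:
    """Component-wise D = |C*X_p - X|; returns X_p - A*D."""
    d = np.abs(c_vec * x_p - x)
    return x_p - a_vec * d


def sample_coefficients(a: float, rng: np.random.Generator, size: int):
    """(A, C) vectors: A in [-a, a], C in [0, 2], from uniform r1, r2."""
    if not 0.0 <= a <= 2.0:
        raise ConfigError("a must be in [0, 2]")
    r1 = rng.random(size)
    r2 = rng.random(size)
    return 2.0 * a * r1 - a, 2.0 * r2


# ---------------------------------------------------------------------------
# Decode / encode
# ---------------------------------------------------------------------------

def _nearest_multiple(value: int, base: int, lo: int, hi: int) -> int:
    candidate = int(base * round(value / base))
    candidate = max(candidate, base * -(-lo // base))  # smallest multiple >= lo
    candidate = min(candidate, base * (hi // base))  # largest multiple <= hi
    return candidate


def decode(position: np.ndarray, space: SearchSpace,
           base_config: ViTConfig | None = None) -> tuple[float, ViTConfig]:
    """Materialize a wolf position as (learning_rate, valid ViTConfig).

    log10 dimensions are exponentiated, integer dimensions rounded, and the
    projection dimension snapped to the nearest in-bounds multiple of the
    decoded head count so the config always validates.
    """
    values = {}
    for (name, kind, lo, hi), x in zip(space.dimensions, position):
        x = float(np.clip(x, lo, hi))
        if kind == "log10":
            values[name] = 10.0 ** x
        elif kind == "integer":
            values[name] = int(round(x))
        else:
            values[name] = x
    base = base_config or ViTConfig()
    heads = values["num_heads"]
    bounds = next((lo, hi) for name, _, lo, hi in space.dimensions if name == "projection_dim")
    proj = _nearest_multiple(values["projection_dim"], heads, int(bounds[0]), int(bounds[1]))
    cfg = replace(
        base,
        projection_dim=proj,
        num_heads=heads,
        key_dim=max(1, proj // heads),
        depth=values["depth"],
        attention_dropout=values["dropout"],
        mlp_dropout=values["dropout"],
    )
    return values["learning_rate"], validate_config(cfg)


def encode(learning_rate: float, cfg: ViTConfig, space: SearchSpace) -> np.ndarray:
    """Inverse of decode for in-bounds valid configs."""
    lookup = {
        "learning_rate": np.log10(learning_rate),
        "projection_dim": float(cfg.projection_dim),
        "num_heads": float(cfg.num_heads),
        "depth": float(cfg.depth),
        "dropout": float(cfg.attention_dropout),
    }
    return np.array([lookup[name] for name, *_ in space.dimensions])


def _cache_key(lr: float, cfg: ViTConfig) -> tuple:
    return (round(lr, 12), cfg.projection_dim, cfg.num_heads, cfg.depth,
            round(cfg.attention_dropout, 6))


# ---------------------------------------------------------------------------
# Pack state and the optimization loop
# ---------------------------------------------------------------------------

@dataclass
class Wolf:
    position: np.ndarray
    fitness: float = -np.inf


@dataclass
class Pack:
    wolves: list[Wolf]
    t: int = 0
    T: int = 25
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    cache_hits: int = 0
    evaluations: int = 0
    # historical best solutions: leadership persists even after the wolves
    # that found them move on (the canonical alpha/beta/delta bookkeeping)
    alpha: Wolf | None = None
    beta: Wolf | None = None
    delta: Wolf | None = None

    def _ensure_leaders(self) -> None:
        if self.alpha is None:
            ranked = sorted(range(len(self.wolves)),
                            key=lambda i: (-self.wolves[i].fitness, i))
            top = [self.wolves[i] for i in ranked[:3]]
            self.alpha, self.beta, self.delta = (
                Wolf(w.position.copy(), w.fitness) for w in top)

    def leaders(self) -> tuple[Wolf, Wolf, Wolf]:
        """(alpha, beta, delta) historical bests; alpha dominates the pack."""
        self._ensure_leaders()
        return self.alpha, self.beta, self.delta

    def update_leaders(self, wolf: Wolf) -> None:
        """Cascade-insert a freshly evaluated wolf into the leader ranks.

        Strict comparisons implement the tie rule: an earlier-evaluated
        leader keeps its rank against an equal newcomer.
        """
        self._ensure_leaders()
        snap = Wolf(wolf.position.copy(), wolf.fitness)
        if snap.fitness > self.alpha.fitness:
            self.alpha, self.beta, self.delta = snap, self.alpha, self.beta
        elif snap.fitness > self.beta.fitness:
            self.beta, self.delta = snap, self.beta
        elif snap.fitness > self.delta.fitness:
            self.delta = snap

    @property
    def a(self) -> float:
        return coefficient_a(self.t, self.T)


@dataclass
class ConvergenceTrace:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    a_values: list[float] = field(default_factory=list)
    alpha_positions: list[np.ndarray] = field(default_factory=list)

    def record(self, pack: Pack) -> None:
        alpha = pack.leaders()[0]
        best = alpha.fitness
        if self.best_fitness:
            best = max(best, self.best_fitness[-1])  # best-so-far is monotone
        self.best_fitness.append(best)
        self.mean_fitness.append(float(np.mean([w.fitness for w in pack.wolves])))
        self.a_values.append(pack.a)
        self.alpha_positions.append(alpha.position.copy())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(len(self.best_fitness)),
            "best": self.best_fitness,
            "mean": self.mean_fitness,
            "a": self.a_values,
        })


class _CachedFitness:
    """Memoizes fitness by decoded-config key; failures are logged, and the
    wolf keeps its previous position/fitness.

    In raw mode the fitness receives the position vector directly (used for
    toy objectives) and the cache key is the rounded position.
    """

    def __init__(self, fitness, space: SearchSpace,
                 base_config: ViTConfig | None = None, raw: bool = False):
        self.fitness = fitness
        self.space = space
        self.base_config = base_config
        self.raw = raw
        self.cache: dict[tuple, float] = {}
        self.hits = 0
        self.failures: list[str] = []

    def __call__(self, position: np.ndarray) -> float:
        if self.raw:
            key = tuple(np.round(position, 12))
            if key in self.cache:
                self.hits += 1
                return self.cache[key]
            value = float(self.fitness(position))
        else:
            lr, cfg = decode(position, self.space, self.base_config)
            key = _cache_key(lr, cfg)
            if key in self.cache:
                self.hits += 1
                return self.cache[key]
            value = float(self.fitness(lr, cfg))
        self.cache[key] = value
        return value


def pack_step(pack: Pack, space: SearchSpace, fitness: _CachedFitness) -> Pack:
    """One GWO iteration: every wolf averages its three leader-guided
    candidate positions, is clipped to bounds and re-evaluated; then t
    advances (shrinking a) and the leaders are re-ranked implicitly."""
    a = pack.a
    alpha, beta, delta = pack.leaders()
    ndim = len(space.dimensions)
    for wolf in pack.wolves:
        candidates = []
        for leader in (alpha, beta, delta):
            a_vec, c_vec = sample_coefficients(a, pack.rng, ndim)
            candidates.append(encircle(wolf.position, leader.position, a_vec, c_vec))
        new_pos = space.clip(np.mean(candidates, axis=0))
        try:
            new_fit = fitness(new_pos)
        except Exception as exc:  # noqa: BLE001 - contract: keep previous position
            fitness.failures.append(f"t={pack.t}: {exc}")
            continue
        wolf.position = new_pos
        wolf.fitness = new_fit
        pack.update_leaders(wolf)
        pack.evaluations += 1
    pack.t += 1
    pack.cache_hits = fitness.hits
    return pack


def optimize(
    space: SearchSpace,
    fitness,
    pop_size: int = 10,
    T: int = 25,
    seed: int = 42,
    base_config: ViTConfig | None = None,
    raw: bool = False,
):
    """Run GWO; returns (best, trace, final pack), maximizing the fitness.

    Normally ``fitness(learning_rate, cfg) -> score`` is evaluated on decoded
    configurations (cached by decoded-config key) and ``best`` is the decoded
    ``(learning_rate, ViTConfig)`` pair.  With ``raw=True`` the fitness sees
    position vectors directly and ``best`` is the best position.
    Deterministic under ``seed``.
    """
    if pop_size < 3:
        raise ConfigError("pop_size must be >= 3 (alpha/beta/delta must exist)")
    rng = np.random.default_rng(seed)
    cached = _CachedFitness(fitness, space, base_config, raw=raw)
    wolves = []
    for _ in range(pop_size):
        pos = space.sample(rng)
        wolves.append(Wolf(position=pos, fitness=cached(pos)))
    pack = Pack(wolves=wolves, t=0, T=T, rng=rng)
    pack.evaluations = pop_size

    trace = ConvergenceTrace()
    best_pos = max(wolves, key=lambda w: w.fitness).position.copy()
    best_fit = max(w.fitness for w in wolves)
    trace.record(pack)
    for _ in range(T):
        pack_step(pack, space, cached)
        alpha = pack.leaders()[0]
        if alpha.fitness > best_fit:
            best_fit = alpha.fitness
            best_pos = alpha.position.copy()
        trace.record(pack)
    best = best_pos if raw else decode(best_pos, space, base_config)
    return best, trace, pack
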