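"""Network propagation: spread seed relevance ("heat") over the interactome.

The propagation is a random walk with restart: the fixed point of

    p = r·p0 + (1 − r)·W·p

where ``p0`` is the relevance-weighted seed distribution, ``W`` a
normalized adjacency operator and ``r`` the restart probability that
controls locality (larger r keeps heat closer to the seeds). With the
column-stochastic operator the fixed point conserves the unit mass of
``p0``, and sorting non-seed genes by converged heat yields a proximity
ranking of candidate disease genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import linalg as splinalg

from .errors import ConfigurationError, ConvergenceError, InputError, ValidationError
from .interactome import Interactome, OPERATOR_MODES, PropagationOperator
from .seeds import SeedGene

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionConfig:
    """Parameters of the random-walk-with-restart propagation.

    restart:
        Fraction of probability mass re-injected at the seeds each step,
        in (0, 1]. Default 0.3.
    tol:
        Max-norm convergence threshold on successive iterates.
    max_iter:
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    normalization:
        Operator mode, ``column-stochastic`` (default) or ``symmetric-degree``.
    """

    restart: float = 0.3
    tol: float = 1e-8
    max_iter: int = 10000
    normalization: str = "column-stochastic"

    def __post_init__(self):
        if not (0.0 < self.restart <= 1.0):
            raise ConfigurationError(f"restart must be in (0, 1], got {self.restart}")
        if not (self.tol > 0):
            raise ConfigurationError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be positive, got {self.max_iter}")
        if self.normalization not in OPERATOR_MODES:
            raise ConfigurationError(f"unknown normalization: {self.normalization!r}")


@dataclass
class HeatVector:
    """Per-node heat for one propagation run, aligned with node order."""

    nodes: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    stage: str | None = None
    iterations: int = 0
    residual: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValidationError("heat vector length does not match node list")
        if np.any(self.values < -1e-15):
            raise ValidationError("heat values must be non-negative")

    def __getitem__(self, symbol: str) -> float:
        return float(self.values[self.nodes.index(symbol)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.nodes), name="heat")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def make_seed_vector(
    seeds: Sequence[SeedGene] | Mapping[str, float],
    net: Interactome,
    stage: str | None = None,
) -> HeatVector:
    """Initial heat: each in-network seed gets relevance / Σ relevance.

    Seeds absent from the interactome are dropped with a logged count —
    they can neither emit nor receive heat.
    """
    if isinstance(seeds, Mapping):
        weights = {s: float(r) for s, r in seeds.items()}
    else:
        weights = {}
        for g in seeds:
            if g.relevance is None:
                raise ValidationError(f"seed {g.symbol} has no relevance score")
            weights[g.symbol] = max(weights.get(g.symbol, 0.0), g.relevance)
    in_net = {s: r for s, r in weights.items() if s in net}
    dropped = len(weights) - len(in_net)
    if dropped:
        logger.info("dropped %d seeds absent from the interactome", dropped)
    if not in_net:
        raise InputError("no seed gene is present in the interactome")
    total = sum(in_net.values())
    if total <= 0:
        raise ValidationError("seed relevances sum to zero; cannot normalize")
    values = np.zeros(net.n_nodes)
    for sym, rel in in_net.items():
        values[net.node_index[sym]] = rel / total
    return HeatVector(nodes=net.nodes, values=values, stage=stage)


def propagate(
    op: PropagationOperator,
    p0: HeatVector,
    cfg: DiffusionConfig | None = None,
) -> HeatVector:
    """Iterate p ← r·p0 + (1−r)·W·p to the fixed point.

    Returns a new :class:`HeatVector` carrying the iteration count and the
    final max-norm residual.
    """
    cfg = cfg or DiffusionConfig()
    if op.nodes != p0.nodes:
        raise ValidationError("operator and heat vector use different node orders")
    if not math.isclose(p0.total, 1.0, abs_tol=1e-9):
        raise ValidationError(f"initial heat must sum to 1, got {p0.total}")
    r = cfg.restart
    if r == 1.0:
        return HeatVector(nodes=p0.nodes, values=p0.values.copy(), stage=p0.stage,
                          iterations=0, residual=0.0)
    w = op.matrix
    base = r * p0.values
    p = p0.values.copy()
    for it in range(1, cfg.max_iter + 1):
        nxt = base + (1.0 - r) * (w @ p)
        residual = float(np.max(np.abs(nxt - p)))
        p = nxt
        if residual < cfg.tol:
            np.clip(p, 0.0, None, out=p)
            return HeatVector(nodes=p0.nodes, values=p, stage=p0.stage,
                              iterations=it, residual=residual)
    raise ConvergenceError(
        f"propagation did not converge in {cfg.max_iter} iterations "
        f"(last residual {residual:.3e})",
        residual=residual,
    )


def propagate_direct(
    op: PropagationOperator,
    p0: HeatVector,
    cfg: DiffusionConfig | None = None,
) -> HeatVector:
    """Solve (I − (1−r)·W)·p = r·p0 directly (sparse LU). Small graphs only."""
    cfg = cfg or DiffusionConfig()
    if op.nodes != p0.nodes:
        raise ValidationError("operator and heat vector use different node orders")
    r = cfg.restart
    n = op.n
    from scipy import sparse

    system = sparse.identity(n, format="csc") - (1.0 - r) * op.matrix.tocsc()
    p = splinalg.spsolve(system, r * p0.values)
    p = np.clip(np.asarray(p, dtype=float), 0.0, None)
    return HeatVector(nodes=p0.nodes, values=p, stage=p0.stage, iterations=0, residual=0.0)


def proximity_ranking(
    heat: HeatVector,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Non-excluded genes sorted by heat descending, ties lexicographic."""
    pairs = [
        (sym, float(h))
        for sym, h in zip(heat.nodes, heat.values)
        if sym not in exclude
    ]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs


def heat_table(heat: HeatVector, seeds: set[str]) -> pd.DataFrame:
    """Per-stage heat table: symbol, heat, rank (1 = hottest), is_seed."""
    order = sorted(zip(heat.nodes, heat.values), key=lambda t: (-t[1], t[0]))
    df = pd.DataFrame(order, columns=["symbol", "heat"])
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_seed"] = df["symbol"].isin(seeds)
    return df
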