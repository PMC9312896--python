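"""Positive-unlabelled prioritization of candidate disease genes.

Only positive labels exist (the seed genes); every other gene is
unlabelled and may be a hidden positive. We use bagged PU learning in the
Mordelet–Vert style: each bagging round draws a random sample of
unlabelled genes as provisional negatives, fits a regularized linear
classifier on seeds vs the sample, and scores the out-of-bag unlabelled
genes. A gene's PU score is its mean out-of-bag positive-class
probability; the top-K scorers become the "likely positive" (LP) set.

Features are cheap topological/diffusion summaries per gene: converged
heat, log degree, fraction of seed neighbours, mean neighbour heat, and
capped shortest-path distance to the seed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .diffusion import HeatVector
from .errors import ConfigurationError, InputError, ValidationError
from .interactome import Interactome

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "heat",
    "log_degree",
    "seed_neighbor_frac",
    "neighbor_mean_heat",
    "seed_distance",
)

#: shortest-path distances to the seed set are capped here
DISTANCE_CAP = 5


@dataclass(frozen=True)
class APUConfig:
    """Bagged-PU parameters.

    n_bags:
        Number of bagging rounds (default 100).
    negatives_per_bag:
        Provisional negatives drawn per round, as a multiple of the
        positive count (≥ 1, default 1.0).
    C:
        Inverse L2 regularization strength of the logistic classifier.
    K:
        Number of likely-positive genes to select per stage (default 150).
    rng_seed:
        Seed for the bag sampler; fixes all scores.
    """

    n_bags: int = 100
    negatives_per_bag: float = 1.0
    C: float = 1.0
    K: int = 150
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_bags < 1:
            raise ConfigurationError(f"n_bags must be positive, got {self.n_bags}")
        if self.negatives_per_bag < 1.0:
            raise ConfigurationError(
                f"negatives_per_bag must be >= 1, got {self.negatives_per_bag}"
            )
        if self.C <= 0:
            raise ConfigurationError(f"C must be positive, got {self.C}")
        if self.K < 1:
            raise ConfigurationError(f"K must be positive, got {self.K}")


def extract_features(
    net: Interactome,
    heat: HeatVector,
    seeds: Iterable[str],
) -> pd.DataFrame:
    """Per-gene feature matrix, standardized column-wise over all nodes.

    Columns: converged heat; log(1+degree); fraction of neighbours that
    are seeds; mean heat over neighbours; shortest-path distance to the
    seed set capped at 5. Constant columns are left at 0 after centring.
    """
    if heat.nodes != net.nodes:
        raise ValidationError("heat vector does not match interactome node order")
    seed_set = {s for s in seeds if s in net}
    g = net.graph
    n = net.n_nodes
    heat_v = heat.values
    deg = np.array([g.degree[s] for s in net.nodes], dtype=float)

    seed_frac = np.zeros(n)
    nbr_heat = np.zeros(n)
    for i, sym in enumerate(net.nodes):
        nbrs = list(g.neighbors(sym))
        if nbrs:
            idx = [net.node_index[v] for v in nbrs]
            seed_frac[i] = sum(v in seed_set for v in nbrs) / len(nbrs)
            nbr_heat[i] = float(heat_v[idx].mean())

    dist = np.full(n, DISTANCE_CAP, dtype=float)
    if seed_set:
        lengths = nx.multi_source_dijkstra_path_length(
            g, seed_set, cutoff=DISTANCE_CAP, weight=None
        )
        for sym, d in lengths.items():
            dist[net.node_index[sym]] = min(d, DISTANCE_CAP)

    x = np.column_stack([heat_v, np.log1p(deg), seed_frac, nbr_heat, dist])
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0  # constant features stay at 0 after centring
    x = (x - mean) / std
    return pd.DataFrame(x, index=list(net.nodes), columns=list(FEATURE_NAMES))


def pu_bag_scores(
    features: pd.DataFrame,
    positives: Iterable[str],
    cfg: APUConfig | None = None,
) -> pd.Series:
    """Bagged-PU scores for every unlabelled (non-seed) gene.

    Each round fits seeds vs a random unlabelled sample and scores the
    out-of-bag unlabelled genes; the PU score is the mean out-of-bag
    positive-class probability. Genes never out-of-bag fall back to their
    mean in-bag score (logged). Deterministic given ``cfg.rng_seed``.
    """
    cfg = cfg or APUConfig()
    pos = sorted(set(positives) & set(features.index))
    if len(pos) < 5:
        raise InputError(f"need at least 5 in-network positive genes, got {len(pos)}")
    unlabelled = sorted(set(features.index) - set(pos))
    if not unlabelled:
        raise InputError("unlabelled gene pool is empty")

    x = features.to_numpy()
    idx = {s: i for i, s in enumerate(features.index)}
    pos_idx = np.array([idx[s] for s in pos])
    unl_idx = np.array([idx[s] for s in unlabelled])
    n_neg = max(1, int(round(cfg.negatives_per_bag * len(pos))))
    n_neg = min(n_neg, len(unlabelled))

    rng = np.random.default_rng(cfg.rng_seed)
    oob_sum = np.zeros(len(unlabelled))
    oob_cnt = np.zeros(len(unlabelled), dtype=int)
    inbag_sum = np.zeros(len(unlabelled))
    inbag_cnt = np.zeros(len(unlabelled), dtype=int)
    y = np.concatenate([np.ones(len(pos)), np.zeros(n_neg)])
    fitted = 0
    for _ in range(cfg.n_bags):
        bag = rng.choice(len(unlabelled), size=n_neg, replace=False)
        xtrain = np.vstack([x[pos_idx], x[unl_idx[bag]]])
        if len(np.unique(y)) < 2:
            logger.warning("bag skipped: single-class training set")
            continue
        clf = LogisticRegression(C=cfg.C, max_iter=1000)
        try:
            clf.fit(xtrain, y)
        except ValueError as exc:
            logger.warning("bag skipped: %s", exc)
            continue
        fitted += 1
        proba = clf.predict_proba(x[unl_idx])[:, list(clf.classes_).index(1.0)]
        in_bag = np.zeros(len(unlabelled), dtype=bool)
        in_bag[bag] = True
        oob_sum[~in_bag] += proba[~in_bag]
        oob_cnt[~in_bag] += 1
        inbag_sum[in_bag] += proba[in_bag]
        inbag_cnt[in_bag] += 1
    if fitted == 0:
        raise InputError("all PU bags were skipped; cannot score genes")

    scores = np.empty(len(unlabelled))
    has_oob = oob_cnt > 0
    scores[has_oob] = oob_sum[has_oob] / oob_cnt[has_oob]
    n_fallback = int((~has_oob).sum())
    if n_fallback:
        logger.info("%d genes never out-of-bag; using in-bag mean score", n_fallback)
        scores[~has_oob] = np.where(
            inbag_cnt[~has_oob] > 0, inbag_sum[~has_oob] / np.maximum(inbag_cnt[~has_oob], 1), 0.5
        )
    return pd.Series(scores, index=unlabelled, name="pu_score")


def select_lp(
    scores: pd.Series | Mapping[str, float],
    seeds: Iterable[str],
    k: int = 150,
) -> pd.DataFrame:
    """Top-K non-seed genes by PU score (ties lexicographic by symbol).

    Returns a DataFrame (symbol, pu_score, rank) of min(K, #candidates) rows.
    """
    if k < 1:
        raise ValidationError(f"K must be positive, got {k}")
    seed_set = set(seeds)
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    items = [(s, float(v)) for s, v in scores.items() if s not in seed_set]
    items.sort(key=lambda t: (-t[1], t[0]))
    top = items[:k]
    return pd.DataFrame(
        {
            "symbol": [s for s, _ in top],
            "pu_score": [v for _, v in top],
            "rank": np.arange(1, len(top) + 1),
        }
    )


def combine_seed_lp(seeds: Iterable[str], lp: pd.DataFrame) -> pd.DataFrame:
    """Union of seed and LP genes with a provenance label per gene."""
    seed_list = sorted(set(seeds))
    lp_syms = list(lp["symbol"])
    clash = set(seed_list) & set(lp_syms)
    if clash:
        raise ValidationError(f"LP set overlaps seeds: {sorted(clash)[:5]}")
    return pd.DataFrame(
        {
            "symbol": seed_list + lp_syms,
            "provenance": ["seed"] * len(seed_list) + ["LP"] * len(lp_syms),
        }
    )
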