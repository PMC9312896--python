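"""Over-representation analysis against GMT gene-set collections.

A query gene set (seeds or likely-positive genes) is tested against each
annotation set (drug–gene or pathway sets) with the one-sided upper-tail
Fisher exact test — P(X ≥ k) under Hypergeometric(N, K_set, n_query) with
the protein-coding background of size N — followed by Benjamini–Hochberg
step-up FDR adjustment across all size-filtered sets in the collection.
Mirrors the WebGestalt ORA defaults: sets with fewer than 5 or more than
2000 background-mapped members are excluded; significance is FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("drug", "pathway")

#: fixed output column order, for diffable CSVs
ORA_COLUMNS = (
    "set_id", "name", "category", "k", "K_set", "n_query", "N",
    "p", "fdr", "significant", "overlap_genes",
)


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (drug target list or pathway membership)."""

    id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"annotation set {self.id} has no members")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"annotation set {self.id} has invalid category {self.category!r}"
            )


def read_gmt(path: str | Path, default_category: str = "pathway") -> list[AnnotationSet]:
    """Read a GMT file (name TAB description TAB member...).

    The description field may carry a category tag as ``drug|display name``
    or ``pathway|display name`` (the fixture writer's dialect); plain
    descriptions fall back to ``default_category``. Duplicate members on a
    line are deduplicated; duplicate set ids raise an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: list[AnnotationSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            if set_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            category, name = default_category, desc or set_id
            if "|" in desc:
                prefix, rest = desc.split("|", 1)
                if prefix in CATEGORIES:
                    category, name = prefix, rest or set_id
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets.append(AnnotationSet(id=set_id, name=name, category=category,
                                      members=members))
    return sets


def write_gmt(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    """Write sets as GMT, encoding the category in the description field."""
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.id}\t{s.category}|{s.name}\t{members}\n")


def read_background(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line background gene list."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"background list not found: {path}")
    with open(path) as fh:
        background = {line.strip().upper() for line in fh if line.strip()}
    if not background:
        raise InputError(f"background list {path} is empty")
    return background


def filter_sets(
    collection: Sequence[AnnotationSet],
    background: set[str],
    min_ids: int = 5,
    max_ids: int = 2000,
) -> list[tuple[AnnotationSet, frozenset[str]]]:
    """Intersect each set with the background and apply size limits.

    Returns (set, background-mapped members) pairs for sets whose mapped
    size is within [min_ids, max_ids]; removals are logged.
    """
    if not background:
        raise ValidationError("background is empty")
    kept: list[tuple[AnnotationSet, frozenset[str]]] = []
    removed = 0
    for s in collection:
        mapped = frozenset(s.members & background)
        if min_ids <= len(mapped) <= max_ids:
            kept.append((s, mapped))
        else:
            removed += 1
    if removed:
        logger.info("filtered out %d/%d sets by mapped size", removed, len(collection))
    return kept


def fisher_upper_tail(k: int, K_set: int, n_query: int, N: int) -> float:
    """One-sided enrichment p-value: P(X ≥ k), X ~ Hypergeometric(N, K_set, n_query)."""
    if not (0 <= k <= K_set <= N and k <= n_query <= N):
        raise ValidationError(
            f"inconsistent counts: k={k}, K_set={K_set}, n_query={n_query}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K_set, n_query))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, aligned to input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def run_ora(
    query: Iterable[str],
    collection: Sequence[AnnotationSet],
    background: set[str],
    min_ids: int = 5,
    max_ids: int = 2000,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Full ORA of a query gene set against one collection.

    The query is intersected with the background (out-of-background genes
    dropped with a logged count), sets are size-filtered, each is Fisher
    tested, and BH adjustment runs across all tested sets. Rows are sorted
    by p then set id.
    """
    query_raw = {str(g).strip().upper() for g in query}
    mapped_query = query_raw & background
    dropped = len(query_raw) - len(mapped_query)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    if not mapped_query:
        raise InputError("no query gene maps to the background")
    n_query = len(mapped_query)
    n_bg = len(background)

    rows = []
    for s, mapped in filter_sets(collection, background, min_ids, max_ids):
        overlap = sorted(mapped & mapped_query)
        k = len(overlap)
        p = fisher_upper_tail(k, len(mapped), n_query, n_bg)
        rows.append(
            {
                "set_id": s.id,
                "name": s.name,
                "category": s.category,
                "k": k,
                "K_set": len(mapped),
                "n_query": n_query,
                "N": n_bg,
                "p": p,
                "overlap_genes": ";".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ORA_COLUMNS if c not in ("fdr", "significant")])
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["fdr"] < fdr_cut
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df[list(ORA_COLUMNS)]
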