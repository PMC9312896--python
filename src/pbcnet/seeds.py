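"""Seed-gene curation: symbol normalization, deduplication, relevance scoring.

Disease-associated seed genes arrive as raw rows (symbol token, stage
label, source, optional gene–disease association score components). This
module canonicalizes symbols against an alias table, merges duplicate
rows, and attaches a relevance score in [0, 1]:

* database-sourced (``disgenet``) genes carry a GDA score — the sum of a
  curated-source component C, a model-organism component M, a GWAS-type
  component I and a text-mining component L, clamped to 1;
* manually ``curated`` genes take the maximum database score observed for
  their disease stage, so that curated genes dominate the diffusion
  initialization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("early", "late", "unspecified")
SOURCES = ("disgenet", "curated")


@dataclass(frozen=True)
class GDAComponents:
    """Components of a gene–disease association score (all non-negative)."""

    C: float = 0.0
    M: float = 0.0
    I: float = 0.0
    L: float = 0.0

    def __post_init__(self):
        for name in ("C", "M", "I", "L"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"GDA component {name} must be a non-negative real, got {v}")


@dataclass(frozen=True)
class SeedGene:
    """A canonical seed gene with stage labels, provenance and relevance.

    ``relevance`` is ``None`` only transiently for curated genes awaiting
    :func:`assign_curated_scores`.
    """

    symbol: str
    stages: frozenset[str]
    source: str
    relevance: float | None = None

    def __post_init__(self):
        if not self.stages:
            raise ValidationError(f"seed gene {self.symbol} has no stage labels")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValidationError(f"seed gene {self.symbol} has invalid stages: {sorted(bad)}")
        if self.source not in SOURCES:
            raise ValidationError(f"seed gene {self.symbol} has invalid source: {self.source!r}")
        if self.relevance is not None and not (0.0 <= self.relevance <= 1.0):
            raise ValidationError(
                f"seed gene {self.symbol} relevance {self.relevance} outside [0, 1]"
            )


class NormalizedSymbol(NamedTuple):
    symbol: str
    mapped: bool


class AliasMap:
    """Case-insensitive mapping from raw symbol tokens to canonical symbols.

    Canonical symbols always map to themselves.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for raw, canonical in mapping.items():
                self.add(raw, canonical)

    def add(self, raw: str, canonical: str) -> None:
        key = raw.strip().upper()
        target = canonical.strip().upper()
        existing = self._map.get(key)
        if existing is not None and existing != target:
            raise ValidationError(f"alias {key!r} maps to both {existing!r} and {target!r}")
        self._map[key] = target
        self._map.setdefault(target, target)

    def lookup(self, token: str) -> str | None:
        return self._map.get(token.strip().upper())

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Load a two-column (raw TAB canonical) alias table with header."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"alias table not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise InputError(f"alias table {path} needs two columns (raw, canonical)")
        amap = cls()
        for raw, canonical in zip(df.iloc[:, 0], df.iloc[:, 1]):
            amap.add(str(raw), str(canonical))
        return amap


def normalize_symbol(raw: str, aliases: AliasMap | None = None) -> NormalizedSymbol:
    """Canonicalize one symbol token.

    Uppercases and trims, then resolves through the alias map. Tokens absent
    from the map are kept uppercased and flagged ``mapped=False``.
    """
    token = str(raw).strip()
    if not token:
        raise ValidationError("empty gene symbol token")
    upper = token.upper()
    if aliases is not None:
        hit = aliases.lookup(upper)
        if hit is not None:
            return NormalizedSymbol(hit, True)
        logger.debug("symbol %r not in alias map; kept as %s", raw, upper)
        return NormalizedSymbol(upper, False)
    return NormalizedSymbol(upper, True)


def gda_score(components: GDAComponents) -> float:
    """Gene–disease association score: min(1, C + M + I + L)."""
    return min(1.0, components.C + components.M + components.I + components.L)


def dedup_seed_table(
    rows: Iterable[tuple],
    aliases: AliasMap | None = None,
) -> tuple[list[SeedGene], int]:
    """Merge raw seed rows into one :class:`SeedGene` per canonical symbol.

    Each row is ``(raw_symbol, stage, source[, components])`` where
    ``components`` is a :class:`GDAComponents` (ignored for curated rows).
    Stage labels are unioned across duplicates; if any duplicate row is
    database-sourced the merged gene is ``disgenet`` and its relevance is
    the maximum GDA score among those rows, otherwise it stays ``curated``
    with relevance unset. Malformed rows are skipped with a warning.

    Returns the merged genes (sorted by symbol) and the count of skipped rows.
    """
    merged: dict[str, dict] = {}
    skipped = 0
    for row in rows:
        try:
            raw, stage = row[0], row[1]
            source = row[2]
            components = row[3] if len(row) > 3 else None
            if stage not in STAGES:
                raise ValidationError(f"invalid stage {stage!r}")
            if source not in SOURCES:
                raise ValidationError(f"invalid source {source!r}")
            symbol = normalize_symbol(raw, aliases).symbol
            score = None
            if source == "disgenet":
                comp = components if components is not None else GDAComponents()
                score = gda_score(comp)
        except (ValidationError, IndexError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed seed row %r: %s", row, exc)
            continue
        entry = merged.setdefault(symbol, {"stages": set(), "disgenet": False, "score": None})
        entry["stages"].add(stage)
        if source == "disgenet":
            entry["disgenet"] = True
            entry["score"] = score if entry["score"] is None else max(entry["score"], score)
    genes = [
        SeedGene(
            symbol=sym,
            stages=frozenset(e["stages"]),
            source="disgenet" if e["disgenet"] else "curated",
            relevance=e["score"] if e["disgenet"] else None,
        )
        for sym, e in sorted(merged.items())
    ]
    return genes, skipped


def assign_curated_scores(
    curated: Sequence[SeedGene],
    stage_tables: Mapping[str, Sequence[float]],
) -> list[SeedGene]:
    """Score manually curated genes by the stage-maximum rule.

    Each curated gene's relevance is the maximum database (disgenet) score
    among the stages it is labelled with; a stage with no database scores
    contributes 1.0, so curated genes always dominate. Genes already scored
    are returned unchanged.
    """
    stage_max = {
        stage: (max(scores) if len(scores) else 1.0)
        for stage, scores in stage_tables.items()
    }
    out = []
    for gene in curated:
        if gene.relevance is not None:
            out.append(gene)
            continue
        score = max(stage_max.get(stage, 1.0) for stage in gene.stages)
        out.append(replace(gene, relevance=score))
    return out


def curate_seed_table(
    rows: Iterable[tuple],
    aliases: AliasMap | None = None,
) -> tuple[list[SeedGene], int]:
    """Full curation: dedup + curated-gene scoring. Returns (genes, skipped)."""
    genes, skipped = dedup_seed_table(rows, aliases)
    stage_tables: dict[str, list[float]] = {s: [] for s in STAGES}
    for g in genes:
        if g.source == "disgenet" and g.relevance is not None:
            for stage in g.stages:
                stage_tables[stage].append(g.relevance)
    scored = assign_curated_scores(genes, stage_tables)
    return scored, skipped


def read_seed_csv(path: str | Path) -> list[tuple]:
    """Read a seeds CSV (symbol, stage, source, C, M, I, L[, score]) into raw rows."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"seed table not found: {path}")
    df = pd.read_csv(path)
    required = {"symbol", "stage", "source"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"seed table {path} is missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        comp = None
        if all(hasattr(rec, c) for c in ("C", "M", "I", "L")):
            vals = [getattr(rec, c) for c in ("C", "M", "I", "L")]
            vals = [0.0 if pd.isna(v) else float(v) for v in vals]
            comp = GDAComponents(*vals)
        rows.append((rec.symbol, rec.stage, rec.source, comp))
    return rows


def write_seed_csv(genes: Sequence[SeedGene], path: str | Path) -> None:
    """Write curated seed genes to CSV (one row per gene, stages ;-joined)."""
    df = pd.DataFrame(
        {
            "symbol": [g.symbol for g in genes],
            "stages": [";".join(sorted(g.stages)) for g in genes],
            "source": [g.source for g in genes],
            "relevance": [g.relevance for g in genes],
        }
    ).sort_values("symbol", kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")
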