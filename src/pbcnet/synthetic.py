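"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates a scale-free interactome (preferential attachment, emulating
the heavy-tailed degree distribution of curated PPI repositories), plants
a topologically cohesive "disease module", samples stage-labelled seed
genes from it with gene–disease-association-like scores, and builds
drug/pathway annotation collections in which some sets are enriched in
the module. Fixture writers emit the same file dialects the real pipeline
reads (edge-list TSV, seeds CSV, GMT, background TXT) so the whole
analysis is exercisable at desk scale with known ground truth.

Default sizes reflect the corpus the method targets at a reduced scale: a
seed pool split across early / late / unspecified disease stages in
roughly the proportions 238 : 183 : 728 observed for stage-annotated
disease genes in primary biliary cholangitis, scaled to 30 seeds inside a
60-gene module of a 1000-gene network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import seeds as seeds_mod
from .enrichment import AnnotationSet, write_gmt
from .errors import ConfigurationError, InputError
from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic universe.

    n_genes / attachment_m:
        Size and edges-per-new-node of the preferential-attachment
        interactome.
    module_size / module_cohesion:
        Size of the planted disease module and the probability that each
        module gene receives one extra edge to another module gene.
    n_seeds_early / n_seeds_late / n_seeds_us:
        Stage-labelled seeds drawn from the module (a gene may carry
        several stage labels; defaults scale the 238:183:728 stage split).
    curated_frac:
        Fraction of seed rows marked manually curated rather than
        database-sourced.
    score_alpha / score_beta:
        Beta-distribution parameters of database-like relevance scores.
    n_annotation_sets / n_planted_sets / planted_overlap_frac / set_size_range:
        Annotation-collection shape; planted sets draw that fraction of
        members from the module.
    """

    n_genes: int = 1000
    attachment_m: int = 3
    module_size: int = 60
    module_cohesion: float = 0.9
    n_seeds_early: int = 6
    n_seeds_late: int = 5
    n_seeds_us: int = 19
    curated_frac: float = 0.3
    score_alpha: float = 2.0
    score_beta: float = 5.0
    n_annotation_sets: int = 50
    n_planted_sets: int = 5
    planted_overlap_frac: float = 0.75
    set_size_range: tuple[int, int] = (5, 50)
    rng_seed: int = 0

    def __post_init__(self):
        def bad(fieldname: str, why: str):
            raise ConfigurationError(f"SyntheticConfig.{fieldname}: {why}")

        if self.n_genes < 2:
            bad("n_genes", f"must be >= 2, got {self.n_genes}")
        if self.attachment_m < 1:
            bad("attachment_m", f"must be >= 1, got {self.attachment_m}")
        if self.n_genes < self.attachment_m + 1:
            bad("n_genes", f"must exceed attachment_m ({self.attachment_m})")
        if not (1 <= self.module_size < self.n_genes):
            bad("module_size", f"must be in [1, n_genes), got {self.module_size}")
        if not (0.0 <= self.module_cohesion <= 1.0):
            bad("module_cohesion", f"must be in [0, 1], got {self.module_cohesion}")
        for name in ("n_seeds_early", "n_seeds_late", "n_seeds_us"):
            v = getattr(self, name)
            if v < 0:
                bad(name, f"must be non-negative, got {v}")
            if v > self.module_size:
                bad(name, f"cannot exceed module_size ({self.module_size}), got {v}")
        if not (0.0 <= self.curated_frac <= 1.0):
            bad("curated_frac", f"must be in [0, 1], got {self.curated_frac}")
        if self.score_alpha <= 0:
            bad("score_alpha", f"must be positive, got {self.score_alpha}")
        if self.score_beta <= 0:
            bad("score_beta", f"must be positive, got {self.score_beta}")
        if self.n_annotation_sets < 0:
            bad("n_annotation_sets", f"must be non-negative, got {self.n_annotation_sets}")
        if self.n_planted_sets > self.n_annotation_sets:
            bad("n_planted_sets", "cannot exceed n_annotation_sets")
        if not (0.0 <= self.planted_overlap_frac <= 1.0):
            bad("planted_overlap_frac", f"must be in [0, 1], got {self.planted_overlap_frac}")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            bad("set_size_range", f"must be ordered within [1, n_genes], got {self.set_size_range}")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    module_genes: set[str] = field(default_factory=set)
    seed_assignments: dict[str, set[str]] = field(default_factory=dict)
    planted_set_ids: set[str] = field(default_factory=set)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng([config.rng_seed, stream])


def _symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def generate_interactome(config: SyntheticConfig) -> Interactome:
    """Preferential-attachment (Barabási–Albert) graph over synthetic symbols.

    Connected simple graph with m·(n−m) edges; node i is named ``G%06d``.
    """
    g = nx.barabasi_albert_graph(
        config.n_genes, config.attachment_m, seed=int(config.rng_seed) & 0x7FFFFFFF
    )
    g = nx.relabel_nodes(g, {i: _symbol(i) for i in g.nodes})
    return Interactome(g)


def plant_disease_module(net: Interactome, config: SyntheticConfig) -> GroundTruth:
    """Grow a connected disease module and tighten it by cohesion rewiring.

    The module is grown by seeded random expansion from a random root
    (each step adds a uniformly chosen frontier neighbour). Then, with
    probability ``module_cohesion``, each module gene gains one edge to a
    random non-adjacent module gene; where possible one of its edges to a
    non-module gene is rewired (removed) in exchange, so cohesion both
    densifies the module and reduces its leakage to the rest of the
    network while keeping total degree roughly constant. Removals that
    would disconnect the graph are rolled back to plain additions.

    The expansion and the rewiring use separate random streams, so the
    module membership is identical across cohesion settings under the
    same ``rng_seed``.
    """
    if config.module_size > net.n_nodes:
        raise InputError(
            f"module_size {config.module_size} exceeds network size {net.n_nodes}"
        )
    grow = _rng(config, 1)
    root = net.nodes[grow.integers(net.n_nodes)]
    module = {root}
    frontier = set(net.neighbors(root))
    while len(module) < config.module_size:
        if not frontier:
            raise InputError("module expansion exhausted the frontier (graph too small)")
        pick = sorted(frontier)[grow.integers(len(frontier))]
        module.add(pick)
        frontier.update(net.neighbors(pick))
        frontier -= module

    rewire = _rng(config, 2)
    g = net.graph
    for gene in sorted(module):
        if rewire.random() >= config.module_cohesion:
            continue
        candidates = sorted(module - {gene} - set(net.neighbors(gene)))
        if not candidates:
            continue
        external = sorted(
            v for v in g.neighbors(gene) if v not in module and g.degree[v] >= 2
        )
        if external:
            out = external[rewire.integers(len(external))]
            g.remove_edge(gene, out)
            if not nx.has_path(g, out, gene):  # removed a bridge: roll back
                g.add_edge(gene, out)
        net.add_edge(gene, candidates[rewire.integers(len(candidates))])
    return GroundTruth(module_genes=module)


def sample_seeds_and_scores(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Stage-labelled seed rows drawn from the planted module.

    Each stage draws its genes without replacement (a gene may recur
    across stages, i.e. multi-stage labelling). Database-sourced rows get
    a Beta(score_alpha, score_beta) relevance score clipped to (0, 1],
    split into GDA-like components C, M, I, L; curated rows get the
    stage-maximum database score via the curation rule.

    Columns: symbol, stage, source, C, M, I, L, score. Updates
    ``truth.seed_assignments`` in place.
    """
    if not truth.module_genes:
        raise InputError("ground-truth module is empty; cannot sample seeds")
    rng = _rng(config, 3)
    module = sorted(truth.module_genes)
    counts = {
        "early": config.n_seeds_early,
        "late": config.n_seeds_late,
        "unspecified": config.n_seeds_us,
    }
    rows = []
    for stage in seeds_mod.STAGES:
        n = counts[stage]
        if n == 0:
            continue
        chosen = rng.choice(module, size=n, replace=False)
        for sym in sorted(chosen):
            curated = rng.random() < config.curated_frac
            if curated:
                rows.append((sym, stage, "curated", 0.0, 0.0, 0.0, 0.0, np.nan))
            else:
                score = float(np.clip(rng.beta(config.score_alpha, config.score_beta),
                                      1e-12, 1.0))
                parts = rng.dirichlet(np.ones(4)) * score
                rows.append((sym, stage, "disgenet", *np.round(parts, 12), score))
            truth.seed_assignments.setdefault(sym, set()).add(stage)
    df = pd.DataFrame(rows, columns=["symbol", "stage", "source", "C", "M", "I", "L", "score"])

    # curated rows take the per-stage maximum of the database scores
    stage_tables = {
        stage: df.loc[(df["stage"] == stage) & (df["source"] == "disgenet"), "score"].tolist()
        for stage in seeds_mod.STAGES
    }
    stage_max = {s: (max(v) if v else 1.0) for s, v in stage_tables.items()}
    curated_mask = df["source"] == "curated"
    df.loc[curated_mask, "score"] = df.loc[curated_mask, "stage"].map(stage_max)
    return df.sort_values(["stage", "symbol"], kind="mergesort").reset_index(drop=True)


def generate_annotation_collection(
    net: Interactome,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> tuple[list[AnnotationSet], set[str]]:
    """Drug/pathway annotation sets, a few enriched in the disease module.

    The first ``n_planted_sets`` sets draw ``planted_overlap_frac`` of
    their members from the module and the rest uniformly from non-module
    genes; decoys draw uniformly from all genes. Categories alternate
    drug / pathway by index. Returns (collection, planted ids).
    """
    rng = _rng(config, 4)
    module = sorted(truth.module_genes)
    non_module = sorted(set(net.nodes) - truth.module_genes)
    all_genes = list(net.nodes)
    lo, hi = config.set_size_range
    sets: list[AnnotationSet] = []
    planted: set[str] = set()
    for i in range(config.n_annotation_sets):
        set_id = f"SET{i + 1:04d}"
        category = "drug" if i % 2 == 0 else "pathway"
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_planted_sets:
            n_mod = min(int(round(config.planted_overlap_frac * size)), len(module))
            members = set(rng.choice(module, size=n_mod, replace=False))
            pool = non_module if non_module else all_genes
            extra = rng.choice(pool, size=min(size - n_mod, len(pool)), replace=False)
            members.update(extra)
            planted.add(set_id)
        else:
            members = set(rng.choice(all_genes, size=min(size, len(all_genes)), replace=False))
        sets.append(
            AnnotationSet(
                id=set_id,
                name=f"synthetic {category} set {i + 1}",
                category=category,
                members=frozenset(members),
            )
        )
    truth.planted_set_ids = set(planted)
    return sets, planted


@dataclass
class SyntheticBundle:
    """All generated artifacts for one configuration."""

    config: SyntheticConfig
    net: Interactome
    truth: GroundTruth
    seed_rows: pd.DataFrame
    collection: list[AnnotationSet]
    planted_ids: set[str]

    @property
    def background(self) -> list[str]:
        return list(self.net.nodes)


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Run every generator stage under one config."""
    config = config or SyntheticConfig()
    net = generate_interactome(config)
    truth = plant_disease_module(net, config)
    seed_rows = sample_seeds_and_scores(truth, config)
    collection, planted = generate_annotation_collection(net, truth, config)
    return SyntheticBundle(
        config=config, net=net, truth=truth, seed_rows=seed_rows,
        collection=collection, planted_ids=planted,
    )


def write_fixture_bundle(dir_path: str | Path, bundle: SyntheticBundle) -> dict:
    """Write every artifact in the dialect the pipeline readers expect.

    Files: ``edges.tsv`` (symbol_a TAB symbol_b with header), ``seeds.csv``,
    ``annotations.gmt``, ``background.txt``, ``ground_truth.json``, and a
    ``manifest.json`` listing each file with its row count. Byte-identical
    across runs with equal config.
    """
    out = Path(dir_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create fixture directory {out}: {exc}") from exc

    edges = bundle.net.edges()
    with open(out / "edges.tsv", "w") as fh:
        fh.write("symbol_a\tsymbol_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")

    bundle.seed_rows.to_csv(out / "seeds.csv", index=False, float_format="%.12g")
    write_gmt(bundle.collection, out / "annotations.gmt")
    with open(out / "background.txt", "w") as fh:
        for sym in bundle.background:
            fh.write(sym + "\n")

    truth_payload = {
        "module_genes": sorted(bundle.truth.module_genes),
        "seed_assignments": {
            s: sorted(st) for s, st in sorted(bundle.truth.seed_assignments.items())
        },
        "planted_set_ids": sorted(bundle.truth.planted_set_ids),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "edges.tsv": {"rows": len(edges)},
        "seeds.csv": {"rows": int(len(bundle.seed_rows))},
        "annotations.gmt": {"rows": len(bundle.collection)},
        "background.txt": {"rows": len(bundle.background)},
        "ground_truth.json": {"rows": len(bundle.truth.module_genes)},
        "config": dataclasses.asdict(bundle.config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote fixture bundle to %s", out)
    return manifest
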