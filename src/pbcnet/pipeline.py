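"""Per-stage orchestration: curation → diffusion → PU ranking → LP → ORA.

Each disease stage (early, late, unspecified) runs independently: its
seed genes initialize the diffusion, a PU learner ranks the remaining
genes, the top-K become the likely-positive (LP) set, and both the seed
set and the LP set are tested for drug and pathway over-representation.
Outputs are plain CSV tables; a given config and seed fully determine
every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import diffusion as diff_mod
from . import enrichment as enr_mod
from . import pulearn as pu_mod
from . import seeds as seeds_mod
from .errors import ConfigurationError, InputError, PbcnetError
from .interactome import Interactome, build_operator, read_edge_list

logger = logging.getLogger(__name__)

STAGE_RNG_OFFSET = {"early": 1, "late": 2, "unspecified": 3}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    ``collections`` maps a collection name to a GMT path; ORA runs per
    (collection, category) family. ``pool_unspecified`` adds the
    unspecified-stage seeds to the early and late runs.
    """

    edges: Path
    seeds: Path
    background: Path
    collections: Mapping[str, Path]
    out_dir: Path
    aliases: Path | None = None
    stages: tuple[str, ...] = ("early", "late", "unspecified")
    diffusion: diff_mod.DiffusionConfig = field(default_factory=diff_mod.DiffusionConfig)
    apu: pu_mod.APUConfig = field(default_factory=pu_mod.APUConfig)
    min_ids: int = 5
    max_ids: int = 2000
    fdr_cut: float = 0.05
    pool_unspecified: bool = False
    emit_combined_ora: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        bad = set(self.stages) - set(seeds_mod.STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        if not self.stages:
            raise ConfigurationError("stages must be non-empty")
        if self.min_ids < 1 or self.max_ids < self.min_ids:
            raise ConfigurationError(
                f"invalid set-size bounds [{self.min_ids}, {self.max_ids}]"
            )
        if not (0.0 < self.fdr_cut <= 1.0):
            raise ConfigurationError(f"fdr_cut must be in (0, 1], got {self.fdr_cut}")

    def validate_paths(self) -> None:
        for name, p in [("edges", self.edges), ("seeds", self.seeds),
                        ("background", self.background)] + [
                        (f"collections[{k}]", v) for k, v in self.collections.items()]:
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: file not found: {p}")
        if self.aliases is not None and not Path(self.aliases).exists():
            raise ConfigurationError(f"aliases: file not found: {self.aliases}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not part of the analysis
        payload = json.loads(json.dumps(payload, default=str, sort_keys=True))
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


_TOP_KEYS = {
    "edges", "seeds", "background", "collections", "out_dir", "aliases", "stages",
    "diffusion", "apu", "min_ids", "max_ids", "fdr_cut", "pool_unspecified",
    "emit_combined_ora", "rng_seed",
}


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    kwargs: dict = {}
    for key in ("edges", "seeds", "background", "out_dir"):
        if key not in raw:
            raise ConfigurationError(f"config is missing required key: {key}")
        kwargs[key] = _resolve(raw[key])
    if raw.get("aliases"):
        kwargs["aliases"] = _resolve(raw["aliases"])
    if "collections" not in raw or not raw["collections"]:
        raise ConfigurationError("config is missing required key: collections")
    kwargs["collections"] = {k: _resolve(v) for k, v in dict(raw["collections"]).items()}
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "diffusion" in raw:
        sub = dict(raw["diffusion"])
        unknown = set(sub) - {f.name for f in dataclasses.fields(diff_mod.DiffusionConfig)}
        if unknown:
            raise ConfigurationError(f"unknown diffusion keys: {sorted(unknown)}")
        kwargs["diffusion"] = diff_mod.DiffusionConfig(**sub)
    if "apu" in raw:
        sub = dict(raw["apu"])
        unknown = set(sub) - {f.name for f in dataclasses.fields(pu_mod.APUConfig)}
        if unknown:
            raise ConfigurationError(f"unknown apu keys: {sorted(unknown)}")
        kwargs["apu"] = pu_mod.APUConfig(**sub)
    for key in ("min_ids", "max_ids", "fdr_cut", "pool_unspecified",
                "emit_combined_ora", "rng_seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


@dataclass
class PipelineInputs:
    """Loaded, curated inputs shared by all stage runs."""

    net: Interactome
    seed_genes: list[seeds_mod.SeedGene]
    background: set[str]
    collections: dict[str, list[enr_mod.AnnotationSet]]


@dataclass
class StageRun:
    """All outputs of one stage."""

    stage: str
    seed_symbols: list[str]
    heat: diff_mod.HeatVector
    lp: pd.DataFrame
    combined: pd.DataFrame
    seed_ora: dict[tuple[str, str], pd.DataFrame]
    lp_ora: dict[tuple[str, str], pd.DataFrame]
    combined_ora: dict[tuple[str, str], pd.DataFrame]
    config_hash: str
    rng_seed: int


def load_inputs(cfg: RunConfig) -> PipelineInputs:
    """Read and curate every input file referenced by the config."""
    cfg.validate_paths()
    net = read_edge_list(cfg.edges)
    aliases = seeds_mod.AliasMap.from_tsv(cfg.aliases) if cfg.aliases else None
    rows = seeds_mod.read_seed_csv(cfg.seeds)
    seed_genes, skipped = seeds_mod.curate_seed_table(rows, aliases)
    if skipped:
        logger.warning("skipped %d malformed seed rows", skipped)
    background = enr_mod.read_background(cfg.background)
    collections = {name: enr_mod.read_gmt(p) for name, p in cfg.collections.items()}
    logger.info(
        "inputs: %d network genes, %d curated seeds, %d background genes, %d collections",
        net.n_nodes, len(seed_genes), len(background), len(collections),
    )
    return PipelineInputs(net=net, seed_genes=seed_genes, background=background,
                          collections=collections)


def _stage_seeds(stage: str, cfg: RunConfig,
                 genes: Sequence[seeds_mod.SeedGene]) -> list[seeds_mod.SeedGene]:
    wanted = {stage}
    if cfg.pool_unspecified and stage != "unspecified":
        wanted.add("unspecified")
    return [g for g in genes if g.stages & wanted]


def run_stage(stage: str, cfg: RunConfig, inputs: PipelineInputs | None = None) -> StageRun:
    """Execute the full chain for one stage.

    Raises with stage context attached if any inner step fails.
    """
    inputs = inputs or load_inputs(cfg)
    try:
        stage_seeds = _stage_seeds(stage, cfg, inputs.seed_genes)
        seed_symbols = sorted({g.symbol for g in stage_seeds})
        if not any(s in inputs.net for s in seed_symbols):
            raise InputError(f"stage {stage!r} has no in-network seeds")

        op = build_operator(inputs.net, cfg.diffusion.normalization)
        p0 = diff_mod.make_seed_vector(stage_seeds, inputs.net, stage=stage)
        heat = diff_mod.propagate(op, p0, cfg.diffusion)

        features = pu_mod.extract_features(inputs.net, heat, seed_symbols)
        apu = replace(
            cfg.apu,
            rng_seed=(cfg.rng_seed * 8 + STAGE_RNG_OFFSET[stage]) % (2**31),
        )
        scores = pu_mod.pu_bag_scores(features, seed_symbols, apu)
        lp = pu_mod.select_lp(scores, seed_symbols, apu.K)
        combined = pu_mod.combine_seed_lp(seed_symbols, lp)

        def family(query):
            out = {}
            for cname, sets in inputs.collections.items():
                for category in enr_mod.CATEGORIES:
                    fam = [s for s in sets if s.category == category]
                    if fam:
                        out[(cname, category)] = enr_mod.run_ora(
                            query, fam, inputs.background,
                            cfg.min_ids, cfg.max_ids, cfg.fdr_cut,
                        )
            return out

        seed_ora = family(seed_symbols)
        lp_ora = family(list(lp["symbol"]))
        combined_ora = family(list(combined["symbol"])) if cfg.emit_combined_ora else {}
        return StageRun(
            stage=stage, seed_symbols=seed_symbols, heat=heat, lp=lp,
            combined=combined, seed_ora=seed_ora, lp_ora=lp_ora,
            combined_ora=combined_ora, config_hash=cfg.config_hash(),
            rng_seed=cfg.rng_seed,
        )
    except PbcnetError as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc


def write_stage_outputs(run: StageRun, out_dir: str | Path) -> dict:
    """Write one stage's tables; returns a file → row-count manifest entry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    heat_df = diff_mod.heat_table(run.heat, set(run.seed_symbols))
    name = f"heat_{run.stage}.csv"
    heat_df.to_csv(out / name, index=False, float_format="%.10g")
    files[name] = len(heat_df)

    name = f"lp_{run.stage}.csv"
    run.lp.to_csv(out / name, index=False, float_format="%.10g")
    files[name] = len(run.lp)

    name = f"combined_{run.stage}.csv"
    run.combined.to_csv(out / name, index=False)
    files[name] = len(run.combined)

    for query_type, tables in (
        ("seed", run.seed_ora), ("lp", run.lp_ora), ("combined", run.combined_ora)
    ):
        for (cname, category), df in sorted(tables.items()):
            name = f"ora_{run.stage}_{query_type}_{cname}_{category}.csv"
            df.to_csv(out / name, index=False, float_format="%.10g")
            files[name] = len(df)
    return files


def run_pipeline(cfg: RunConfig) -> list[StageRun]:
    """Run every configured stage; stages without seeds are skipped.

    Succeeds if at least one stage ran; writes all tables plus a manifest
    under ``cfg.out_dir``.
    """
    inputs = load_inputs(cfg)
    runs: list[StageRun] = []
    skipped: list[str] = []
    for stage in cfg.stages:
        stage_seeds = _stage_seeds(stage, cfg, inputs.seed_genes)
        if not any(g.symbol in inputs.net for g in stage_seeds):
            logger.warning("stage %r skipped: no in-network seeds", stage)
            skipped.append(stage)
            continue
        runs.append(run_stage(stage, cfg, inputs))
    if not runs:
        raise InputError("no stage had in-network seeds; nothing to run")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "stages_run": [r.stage for r in runs],
        "stages_skipped": skipped,
        "files": {},
    }
    for run in runs:
        manifest["files"].update(write_stage_outputs(run, out))
    report = assemble_report(runs)
    report.to_csv(out / "report.csv", index=False, float_format="%.10g")
    manifest["files"]["report.csv"] = len(report)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return runs


REPORT_COLUMNS = (
    "stage", "query_type", "collection", "category", "set_id", "name",
    "k", "K_set", "p", "fdr", "significant",
)


def assemble_report(runs: Sequence[StageRun], top: int = 10) -> pd.DataFrame:
    """Tidy long-format summary: top enriched sets per (stage, query, category).

    Rows are ordered by fdr, then p, then set id within each family.
    """
    if not runs:
        raise InputError("no stage runs to report on")
    chunks = []
    for run in runs:
        for query_type, tables in (
            ("seed", run.seed_ora), ("lp", run.lp_ora), ("combined", run.combined_ora)
        ):
            for (cname, category), df in sorted(tables.items()):
                if df.empty:
                    continue
                best = (
                    df.sort_values(["fdr", "p", "set_id"], kind="mergesort")
                    .head(top)
                    .copy()
                )
                best.insert(0, "stage", run.stage)
                best.insert(1, "query_type", query_type)
                best.insert(2, "collection", cname)
                chunks.append(best[list(REPORT_COLUMNS)])
    if not chunks:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    return pd.concat(chunks, ignore_index=True)
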