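"""End-to-end analysis orchestration from a single YAML config.

One run covers several (taxonomic order × urban class) groups: each group
gets its dataset assembled (complete cases, realm-restricted background,
complementary-class exclusion), its candidate model set enumerated from a
trait-only DAG plus direct trait → outcome links, the d-sep scan, CICc
selection, and conditional model averaging.  All thresholds and defaults
are echoed into the run manifest so every run is self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dsep import PhylogeneticPathAnalysis
from .graphs import CausalDAG, enumerate_models
from .traits import DatasetSkipped, add_diet_diversity, assemble_order_dataset
from .tree import read_newick, read_trait_table, vcv

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "validate_config", "run_full_analysis"]


@dataclass
class GroupSpec:
    order: str
    urban_class: str
    trait_only_edges: list[tuple]
    candidate_links: list[tuple]
    vertices: list[str]


@dataclass
class RunConfig:
    tree_path: str
    traits_path: str
    schema: dict
    continuous_vars: list[str]
    groups: list[GroupSpec]
    log_vars: list[str] = field(default_factory=list)
    diet_cols: list[str] = field(default_factory=list)
    shannon_base: float | None = None
    binary_var: str = "urban"
    min_n: int = 20
    delta_threshold: float = 2.0
    alpha: float = 0.05
    realm_filter: bool = True
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["groups"] = [
            {
                "order": g.order,
                "urban_class": g.urban_class,
                "vertices": g.vertices,
                "trait_only_edges": [list(e) for e in g.trait_only_edges],
                "candidate_links": [list(e) for e in g.candidate_links],
            }
            for g in self.groups
        ]
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = [
        GroupSpec(
            order=g["order"],
            urban_class=g["urban_class"],
            trait_only_edges=[tuple(e) for e in g.get("trait_only_edges", [])],
            candidate_links=[tuple(e) for e in g.get("candidate_links", [])],
            vertices=list(g["vertices"]),
        )
        for g in raw["groups"]
    ]
    return RunConfig(
        tree_path=raw["tree"],
        traits_path=raw["traits"],
        schema=dict(raw["schema"]),
        continuous_vars=list(raw["continuous_vars"]),
        groups=groups,
        log_vars=list(raw.get("log_vars", [])),
        diet_cols=list(raw.get("diet_cols", [])),
        shannon_base=raw.get("shannon_base"),
        binary_var=raw.get("binary_var", "urban"),
        min_n=int(raw.get("min_n", 20)),
        delta_threshold=float(raw.get("delta_threshold", 2.0)),
        alpha=float(raw.get("alpha", 0.05)),
        realm_filter=bool(raw.get("realm_filter", True)),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "results"),
    )


def validate_config(config: RunConfig, check_files: bool = True) -> list[str]:
    """Return a list of problems (empty when the config is valid).

    All violations are collected and reported at once.
    """
    problems = []
    if check_files:
        for p, what in ((config.tree_path, "tree"), (config.traits_path, "traits")):
            if not Path(p).is_file():
                problems.append(f"{what} file does not exist: {p}")
    if config.min_n < 2:
        problems.append("min_n must be >= 2")
    if config.delta_threshold <= 0:
        problems.append("delta_threshold must be positive")
    if not 0 < config.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    for key in ("species", "urban"):
        if key not in config.schema:
            problems.append(f"schema missing required key {key!r}")
    if not config.groups:
        problems.append("no analysis groups defined")
    for g in config.groups:
        tag = f"group {g.order}/{g.urban_class}"
        if g.urban_class not in ("visitor", "dweller"):
            problems.append(f"{tag}: urban_class must be visitor or dweller")
        try:
            dag = CausalDAG(g.vertices, g.trait_only_edges,
                            binary_vertex=config.binary_var)
            enumerate_models(dag, g.candidate_links)
        except ValueError as exc:
            problems.append(f"{tag}: {exc}")
        unknown = [v for v in g.vertices
                   if v != config.binary_var and v not in config.continuous_vars]
        if unknown:
            problems.append(f"{tag}: vertices not among continuous_vars: {unknown}")
    return problems


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured group end to end and write the result bundle.

    Returns a summary dict: per-group selection tables, averaged models,
    and skip reasons.  Result files go under ``output_dir/<order>_<class>/``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    tree = read_newick(config.tree_path)
    schema = dict(config.schema)
    schema.setdefault("traits", list(config.continuous_vars))
    schema.setdefault("diet", list(config.diet_cols))
    table = read_trait_table(config.traits_path, schema)
    if config.diet_cols:
        table = add_diet_diversity(table, config.diet_cols,
                                   base=config.shannon_base)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    summary: dict = {"groups": {}, "skipped": {}}
    for g in config.groups:
        tag = f"{g.order}_{g.urban_class}"
        try:
            design, sub_tree = assemble_order_dataset(
                table, tree, order=g.order, urban_class=g.urban_class,
                schema=config.schema,
                continuous_vars=[v for v in g.vertices if v != config.binary_var],
                log_vars=set(config.log_vars) & set(g.vertices),
                realm_filter=config.realm_filter, min_n=config.min_n,
            )
        except DatasetSkipped as exc:
            log.info("skipping %s: %s", tag, exc)
            summary["skipped"][tag] = str(exc)
            continue
        dag = CausalDAG(g.vertices, g.trait_only_edges,
                        binary_vertex=config.binary_var, name="Trait-only")
        model_set = enumerate_models(dag, g.candidate_links)
        cov = vcv(sub_tree, 1.0)
        ppa = PhylogeneticPathAnalysis(
            delta_threshold=config.delta_threshold, alpha=config.alpha
        ).fit(design, cov, model_set)
        gdir = out_root / tag
        gdir.mkdir(parents=True, exist_ok=True)
        sel = ppa.selection_.to_frame()
        sel.to_csv(gdir / "selection_table.csv", index=False,
                   float_format="%.6g")
        if ppa.averaged_ is not None:
            avg = ppa.averaged_.to_frame()
            avg.to_csv(gdir / "averaged_model.csv", index=False,
                       float_format="%.6g")
        else:
            avg = None
        claims = {
            f.model_id: [c.to_dict() for c in f.claims]
            for f in ppa.fits_ + ppa.unevaluable_
        }
        with open(gdir / "claims.json", "w") as fh:
            json.dump(claims, fh, indent=2)
        summary["groups"][tag] = {
            "n": design.n,
            "n_models": len(model_set.models),
            "n_evaluable": len(ppa.fits_),
            "best_model": sel.iloc[0]["model"],
            "n_supported": int(sel["supported"].sum()),
            "selection_table": str(gdir / "selection_table.csv"),
        }
    with open(out_root / "run_manifest.json", "w") as fh:
        json.dump({"config": config.to_dict(), "summary": _jsonable(summary)},
                  fh, indent=2)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
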