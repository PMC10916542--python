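"""Config-driven community construction used by the command-line interface.

An assembly config (YAML or JSON) lists sub-model files, tags, per-strain
edits and enzyme tables, shared metabolites, exchanges, and the inoculation
ratio:

.. code-block:: yaml

    submodels:
      - {path: up.json, tag: A}
      - {path: down.json, tag: B}
    edits:
      A: {knockouts: [RXN1], additions: [], bounds: {RXN2: [0, 5]}}
    enzyme_tables:
      A: {path: kcats_A.tsv, fallback: exclude}
    pools:
      A: {ptot: 0.56, f: 0.406, sigma: 0.5}
    shared: [glc__D_e, tyr__L_e, prod_e]
    exchanges:
      - {metabolite: glc__D_e, uptake: 10, secretion: 0}
      - {metabolite: prod_e, uptake: 0, secretion: .inf}
    substrate_ratio:            # optional
      total: 10
      weights: {EX_glc__D_shared_reverse: 4, EX_xyl__D_shared_reverse: 1}
    ratio: {A: 2, B: 1}
    objective: EX_prod_shared
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import yaml

from .community_assembly import (
    CommunityModel,
    RatioSpec,
    add_shared_exchange,
    assemble,
    namespace,
    set_substrate_ratio,
)
from .enzyme_constraints import attach, load_enzyme_table, pool_budget
from .gem_io import apply_edits, read_gem, split_reversible

__all__ = ["load_config", "build_community_from_config"]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _build_strain(spec: Mapping, cfg: Mapping, base_dir: Path):
    tag = spec["tag"]
    model = read_gem(base_dir / spec["path"])
    edits = (cfg.get("edits") or {}).get(tag)
    if edits:
        model = apply_edits(
            model,
            knockouts=edits.get("knockouts", ()),
            additions=edits.get("additions", ()),
            bound_changes={k: tuple(v) for k, v in (edits.get("bounds") or {}).items()},
        )
    model = split_reversible(model)
    table_spec = (cfg.get("enzyme_tables") or {}).get(tag)
    if table_spec:
        entries = load_enzyme_table(base_dir / table_spec["path"])
        model = attach(model, entries,
                       fallback=table_spec.get("fallback", "exclude")).model
    pool_spec = (cfg.get("pools") or {}).get(tag)
    if pool_spec:
        model.pool = pool_budget(tag=tag, **pool_spec)
    return namespace(model, tag)


def build_community_from_config(cfg: Mapping, base_dir=".") -> CommunityModel:
    """Build a ready-to-solve community model from a parsed assembly config."""
    base_dir = Path(base_dir)
    submodels = [_build_strain(s, cfg, base_dir) for s in cfg["submodels"]]
    ratio = RatioSpec.of(cfg["ratio"])
    community = assemble(submodels, cfg["shared"], ratio)
    for ex in cfg.get("exchanges", ()):
        community = add_shared_exchange(
            community,
            ex["metabolite"],
            uptake_ub=float(ex.get("uptake", 0.0)),
            secretion_ub=float(ex.get("secretion", math.inf)),
        )
    sub_ratio = cfg.get("substrate_ratio")
    if sub_ratio:
        community = set_substrate_ratio(
            community, sub_ratio["weights"], total=float(sub_ratio["total"])
        )
    community.objective = cfg.get("objective")
    return community
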