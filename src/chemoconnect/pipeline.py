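"""Pipeline stages: simulate -> merge -> score -> enrich, with provenance.

Each stage is a plain function over file paths so it can be driven equally
from the command line, the analysis scripts, or tests.  Every output file
gets a sibling ``<name>.prov.json`` recording the configuration, the seed
and SHA-256 hashes of the inputs — enough to reproduce it exactly.  All
randomness flows from one top-level seed through named substreams (the
simulator and the enrichment null use disjoint spawn keys), so stages can be
re-run independently with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from . import io as cio
from .chemogenomics import (
    CATEGORIES,
    EnrichmentConfig,
    EnrichmentRecord,
    run_enrichment,
)
from .connectivity import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_MIN_OVERLAP,
    CompoundRanking,
    ConnectivityRecord,
    QuerySignature,
    build_query,
    rank_compounds,
    score_library,
)
from .rank_merge import merge_library
from .synthetic import (
    SimulationConfig,
    SyntheticBundle,
    config_to_dict,
    generate_library,
)
from .universe import GeneUniverse, ValidationError

__all__ = [
    "cmd_simulate",
    "cmd_merge",
    "cmd_score",
    "cmd_enrich",
    "cmd_run_all",
    "map_query_to_universe",
]

logger = logging.getLogger(__name__)

FEATURE_FILES = {
    "target": "features_target.gmt",
    "off_target": "features_off_target.gmt",
    "side_effect": "features_side_effect.gmt",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(
    output: Path, *, config: Mapping, seed: Optional[int], inputs: Sequence[Path]
) -> None:
    def _rel(p: Path) -> str:
        # paths relative to the output dir keep artifact trees relocatable
        # (and byte-identical across runs in different directories)
        try:
            return os.path.relpath(p, output.parent)
        except ValueError:
            return p.name

    payload = {
        "output": output.name,
        "config": dict(config),
        "seed": seed,
        "inputs": {_rel(p): _sha256(p) for p in sorted(set(map(Path, inputs)))},
    }
    prov = output.with_name(output.name + ".prov.json")
    cio.atomic_write_text(prov, lambda fh: json.dump(payload, fh, indent=1, sort_keys=True))


def _check_overwrite(paths: Sequence[Path], force: bool) -> None:
    existing = [p for p in paths if Path(p).exists()]
    if existing and not force:
        raise ValidationError(
            f"refusing to overwrite existing outputs {[str(p) for p in existing]}; "
            "pass force=True / --force"
        )


def map_query_to_universe(
    query: QuerySignature, universe: GeneUniverse, *, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> QuerySignature:
    """Restrict a query signature to a library universe, counting drops."""
    up = {g for g in query.up if g in universe}
    down = {g for g in query.down if g in universe}
    n_dropped = (len(query.up) - len(up)) + (len(query.down) - len(down))
    if n_dropped:
        logger.info("dropped %d query genes absent from the library universe", n_dropped)
    for name, direction, total in (("up", up, query.up), ("down", down, query.down)):
        if len(direction) < min_overlap:
            raise ValidationError(
                f"query direction {name!r} has {len(direction)} mapped genes "
                f"(of {len(total)}); need at least {min_overlap}"
            )
    return QuerySignature(
        up=frozenset(up),
        down=frozenset(down),
        fdr_threshold=query.fdr_threshold,
        n_dropped_unmapped=query.n_dropped_unmapped + n_dropped,
    )


def cmd_simulate(
    out_dir: Path,
    cfg: SimulationConfig,
    *,
    force: bool = False,
) -> SyntheticBundle:
    """Generate a synthetic bundle and write every pipeline input format."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out_dir / "profiles.tsv",
        "query": out_dir / "query.tsv",
        "truth": out_dir / "truth.json",
        **{cat: out_dir / FEATURE_FILES[cat] for cat in CATEGORIES},
    }
    _check_overwrite(list(paths.values()), force)
    bundle = generate_library(cfg)
    cio.write_replicate_profiles_long(bundle.profiles, paths["profiles"])
    cio.write_query_list(bundle.query, paths["query"])
    for cat in CATEGORIES:
        cio.write_gmt(bundle.features[cat], paths[cat])
    cio.write_truth(bundle.truth, paths["truth"])
    for p in paths.values():
        _write_provenance(p, config=config_to_dict(cfg), seed=cfg.seed, inputs=[])
    logger.info(
        "simulated %d compounds x %d replicates, %d genes, %d planted",
        cfg.n_compounds, cfg.n_replicates, cfg.n_genes, cfg.n_planted,
    )
    return bundle


def cmd_merge(library: Path, out_dir: Path, *, force: bool = False) -> Path:
    """Merge replicate profiles into the PRL rank matrix."""
    library = Path(library)
    out_dir = Path(out_dir)
    out = out_dir / "prl.tsv"
    _check_overwrite([out], force)
    profiles = cio.read_replicate_profiles(library)
    prls = merge_library(profiles)
    for cid in sorted(prls):
        logger.info("compound %s: merged %d replicates", cid, prls[cid].n_replicates_merged)
    cio.write_prl_matrix(prls, out)
    _write_provenance(out, config={"stage": "merge"}, seed=None, inputs=[library])
    return out


def cmd_score(
    prl_path: Path,
    out_dir: Path,
    *,
    deg_table: Optional[Path] = None,
    query_list: Optional[Path] = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    null_same_sign: bool = True,
    force: bool = False,
) -> Path:
    """Score every compound's connectivity with the query and rank them."""
    if (deg_table is None) == (query_list is None):
        raise ValidationError("exactly one of deg_table or query_list is required")
    prl_path = Path(prl_path)
    out = Path(out_dir) / "connectivity.tsv"
    _check_overwrite([out], force)
    prls = cio.read_prl_matrix(prl_path)
    universe = next(iter(prls.values())).ranking.universe
    if deg_table is not None:
        records_in = cio.read_deg_table(deg_table)
        query = build_query(records_in, universe, fdr_threshold, min_overlap=min_overlap)
        query_input = Path(deg_table)
    else:
        query = map_query_to_universe(
            cio.read_query_list(query_list), universe, min_overlap=min_overlap
        )
        query_input = Path(query_list)
    logger.info(
        "query: %d up, %d down mapped genes (%d dropped)",
        len(query.up), len(query.down), query.n_dropped_unmapped,
    )
    records = score_library(query, prls, null_same_sign=null_same_sign)
    cio.write_connectivity(records, out)
    _write_provenance(
        out,
        config={
            "stage": "score",
            "fdr_threshold": fdr_threshold,
            "min_overlap": min_overlap,
            "null_same_sign": null_same_sign,
            "n_up": len(query.up),
            "n_down": len(query.down),
            "n_dropped_unmapped": query.n_dropped_unmapped,
        },
        seed=None,
        inputs=[prl_path, query_input],
    )
    return out


def cmd_enrich(
    connectivity: Path,
    feature_files: Mapping[str, Path],
    out_dir: Path,
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    bh_scope: Literal["within_category", "global"] = "within_category",
    force: bool = False,
) -> Path:
    """Run chemogenomic enrichment over the ranked compounds."""
    connectivity = Path(connectivity)
    out = Path(out_dir) / "enrichment.tsv"
    _check_overwrite([out], force)
    unknown = set(feature_files) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown feature categories {sorted(unknown)}")
    if not feature_files:
        raise ValidationError("at least one feature file is required")
    for cat, p in feature_files.items():
        if not Path(p).exists():
            raise ValidationError(f"feature file for {cat!r} not found: {p}")
    ranking = cio.read_connectivity(connectivity)
    features = []
    for cat in CATEGORIES:
        if cat in feature_files:
            features.extend(cio.read_gmt(Path(feature_files[cat]), cat))
    cfg = EnrichmentConfig(n_perm=n_perm, seed=seed, bh_scope=bh_scope)
    records = run_enrichment(features, ranking, cfg)
    if not records:
        raise ValidationError("no usable features; nothing to report")
    cio.write_enrichment(records, out)
    _write_provenance(
        out,
        config={"stage": "enrich", "n_perm": n_perm, "bh_scope": bh_scope},
        seed=seed,
        inputs=[connectivity, *feature_files.values()],
    )
    return out


def cmd_run_all(
    out_dir: Path,
    sim_cfg: SimulationConfig,
    *,
    n_perm: int = 10_000,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    bh_scope: Literal["within_category", "global"] = "within_category",
    force: bool = False,
) -> dict[str, Path]:
    """Simulate a bundle, then merge, score and enrich it end to end.

    One top-level seed (``sim_cfg.seed``) governs both stochastic stages.
    """
    out_dir = Path(out_dir)
    cmd_simulate(out_dir, sim_cfg, force=force)
    prl = cmd_merge(out_dir / "profiles.tsv", out_dir, force=force)
    conn = cmd_score(
        prl, out_dir, query_list=out_dir / "query.tsv",
        min_overlap=min_overlap, force=force,
    )
    enr = cmd_enrich(
        conn,
        {cat: out_dir / FEATURE_FILES[cat] for cat in CATEGORIES},
        out_dir,
        n_perm=n_perm,
        seed=sim_cfg.seed,
        bh_scope=bh_scope,
        force=force,
    )
    return {"prl": prl, "connectivity": conn, "enrichment": enr}
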