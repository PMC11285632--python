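"""Readers and writers for the pipeline's plain-text formats.

All outputs are TSV/GMT/JSON; floats are printed with 6 significant digits
so that byte-identity of repeated runs is a meaningful contract.  Writes go
to a temporary file in the destination directory followed by an atomic
rename, so a failed run never leaves a partial artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemogenomics import EnrichmentRecord, FeatureAnnotation
from .connectivity import CompoundRanking, ConnectivityRecord, DegRecord, QuerySignature
from .synthetic import SyntheticTruth, config_to_dict
from .universe import (
    GeneUniverse,
    PrototypeRankedList,
    Ranking,
    ReplicateProfile,
    ValidationError,
)

__all__ = [
    "read_replicate_profiles",
    "write_replicate_profiles_long",
    "read_prl_matrix",
    "write_prl_matrix",
    "read_deg_table",
    "read_query_list",
    "write_query_list",
    "read_gmt",
    "write_gmt",
    "write_connectivity",
    "read_connectivity",
    "write_enrichment",
    "write_truth",
    "read_truth",
    "atomic_write_text",
]


def fmt6(x: float) -> str:
    """Format a float with 6 significant digits."""
    return f"{x:.6g}"


def atomic_write_text(path: Path, write: Callable) -> None:
    """Write via a temp file + atomic rename; ``write`` receives a text handle."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="\n") as fh:
            write(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------- replicates


def write_replicate_profiles_long(profiles: Sequence[ReplicateProfile], path: Path) -> None:
    def _write(fh):
        fh.write("compound_id\treplicate_id\tgene_id\trank\n")
        for p in sorted(profiles, key=lambda p: (p.compound_id, p.replicate_id)):
            uni = p.ranking.universe
            for i, g in enumerate(uni.genes):
                fh.write(f"{p.compound_id}\t{p.replicate_id}\t{g}\t{p.ranking.ranks[i]}\n")

    atomic_write_text(path, _write)


def _profiles_from_rank_table(
    table: Mapping[tuple[str, str], dict[str, int]]
) -> list[ReplicateProfile]:
    all_genes: set[str] = set()
    for ranks in table.values():
        all_genes.update(ranks)
    universe = GeneUniverse.from_genes(all_genes)
    profiles = []
    for (cid, rid), gene_ranks in sorted(table.items()):
        if set(gene_ranks) != all_genes:
            missing = sorted(all_genes - set(gene_ranks))[0]
            raise ValidationError(
                f"profile {cid}::{rid} is missing gene {missing!r}"
            )
        ranks = np.array([gene_ranks[g] for g in universe.genes], dtype=np.int64)
        try:
            ranking = Ranking(universe, ranks)
        except ValidationError as exc:
            raise ValidationError(f"profile {cid}::{rid}: {exc}") from None
        profiles.append(ReplicateProfile(cid, rid, ranking))
    return profiles


def read_replicate_profiles(path: Path) -> list[ReplicateProfile]:
    """Read replicate rank profiles from long or wide TSV (sniffed by header)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:4] == ["compound_id", "replicate_id", "gene_id", "rank"]:
        return _read_replicates_long(path)
    if header and header[0] == "gene_id" and all("::" in c for c in header[1:]):
        return _read_replicates_wide(path)
    raise ValidationError(
        f"{path}: unrecognized replicate-profile header {header[:4]}"
    )


def _read_replicates_long(path: Path) -> list[ReplicateProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "replicate_id": str, "gene_id": str})
    try:
        df["rank"] = df["rank"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-integer rank values ({exc})") from None
    table: dict[tuple[str, str], dict[str, int]] = {}
    for row_no, (cid, rid, gid, rank) in enumerate(
        zip(df["compound_id"], df["replicate_id"], df["gene_id"], df["rank"]), start=2
    ):
        key = (cid, rid)
        ranks = table.setdefault(key, {})
        if gid in ranks:
            raise ValidationError(f"{path} row {row_no}: duplicate gene {gid!r} in {cid}::{rid}")
        ranks[gid] = int(rank)
    return _profiles_from_rank_table(table)


def _read_replicates_wide(path: Path) -> list[ReplicateProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    table: dict[tuple[str, str], dict[str, int]] = {}
    for col in df.columns:
        cid, _, rid = col.partition("::")
        table[(cid, rid)] = {g: int(v) for g, v in df[col].items()}
    return _profiles_from_rank_table(table)


# ----------------------------------------------------------------------- PRL


def write_prl_matrix(prls: Mapping[str, PrototypeRankedList], path: Path) -> None:
    """Wide rank matrix: rows = genes (canonical order), columns = compounds."""
    cids = sorted(prls)
    if not cids:
        raise ValidationError("no PRLs to write")
    universe = prls[cids[0]].ranking.universe

    def _write(fh):
        fh.write("gene_id\t" + "\t".join(cids) + "\n")
        cols = [prls[c].ranking.ranks for c in cids]
        for i, g in enumerate(universe.genes):
            fh.write(g + "\t" + "\t".join(str(col[i]) for col in cols) + "\n")

    atomic_write_text(path, _write)


def read_prl_matrix(path: Path) -> dict[str, PrototypeRankedList]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    universe = GeneUniverse.from_genes(df.index)
    order = [universe.index_of(g) for g in df.index]
    prls = {}
    for cid in df.columns:
        ranks = np.empty(universe.size, dtype=np.int64)
        ranks[order] = df[cid].to_numpy(dtype=np.int64)
        prls[cid] = PrototypeRankedList(
            compound_id=cid, ranking=Ranking(universe, ranks), n_replicates_merged=1
        )
    return prls


# ----------------------------------------------------------------- DEG/query


def read_deg_table(path: Path) -> list[DegRecord]:
    """TSV with required columns gene_id, log2fc, pvalue, padj; extras ignored.

    Decimal commas are normalized to periods before parsing."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "log2fc", "pvalue", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing DEG columns {missing}")
    records = []
    for _, row in df[required].iterrows():
        try:
            records.append(
                DegRecord(
                    gene_id=row["gene_id"],
                    log2fc=float(str(row["log2fc"]).replace(",", ".")),
                    pvalue=float(str(row["pvalue"]).replace(",", ".")),
                    padj=float(str(row["padj"]).replace(",", ".")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad DEG row for {row['gene_id']!r}: {exc}") from None
    return records


def write_query_list(query: QuerySignature, path: Path) -> None:
    def _write(fh):
        fh.write("gene_id\tdirection\n")
        for g in sorted(query.up):
            fh.write(f"{g}\tup\n")
        for g in sorted(query.down):
            fh.write(f"{g}\tdown\n")

    atomic_write_text(path, _write)


def read_query_list(path: Path) -> QuerySignature:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "direction"]:
        raise ValidationError(f"{path}: expected columns gene_id, direction")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValidationError(f"{path}: unknown directions {sorted(bad)}")
    up = frozenset(df.loc[df["direction"] == "up", "gene_id"])
    down = frozenset(df.loc[df["direction"] == "down", "gene_id"])
    return QuerySignature(up=up, down=down)


# ----------------------------------------------------------------------- GMT


def read_gmt(path: Path, category: str) -> list[FeatureAnnotation]:
    """GMT: feature_id TAB description TAB member ids...; category from file role."""
    features = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path} line {line_no}: GMT rows need id, description and >=1 member"
                )
            fid = parts[0]
            if fid in seen:
                raise ValidationError(f"{path} line {line_no}: duplicate feature {fid!r}")
            seen.add(fid)
            features.append(
                FeatureAnnotation(
                    feature_id=fid, category=category, members=frozenset(parts[2:])
                )
            )
    return features


def write_gmt(features: Sequence[FeatureAnnotation], path: Path) -> None:
    def _write(fh):
        for f in features:
            fh.write(f.feature_id + "\t" + f.category + "\t" + "\t".join(sorted(f.members)) + "\n")

    atomic_write_text(path, _write)


# ------------------------------------------------------------------ outputs


def write_connectivity(records: Sequence[ConnectivityRecord], path: Path) -> None:
    ordered = sorted(records, key=lambda r: (-r.score, r.compound_id))

    def _write(fh):
        fh.write("rank\tcompound_id\tes_up\tes_down\tscore\n")
        for i, r in enumerate(ordered, start=1):
            fh.write(
                f"{i}\t{r.compound_id}\t{fmt6(r.es_up)}\t{fmt6(r.es_down)}\t{fmt6(r.score)}\n"
            )

    atomic_write_text(path, _write)


def read_connectivity(path: Path) -> CompoundRanking:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    return CompoundRanking(
        compound_ids=tuple(df["compound_id"]),
        scores=tuple(float(s) for s in df["score"]),
    )


def write_enrichment(records: Sequence[EnrichmentRecord], path: Path) -> None:
    def _write(fh):
        fh.write("category\tfeature_id\tn_members_in_library\tes\tp_two_tailed\tp_adj\n")
        for r in records:
            fh.write(
                f"{r.category}\t{r.feature_id}\t{r.n_members_in_library}\t"
                f"{fmt6(r.es)}\t{fmt6(r.p_two_tailed)}\t{fmt6(r.p_adj)}\n"
            )

    atomic_write_text(path, _write)


# -------------------------------------------------------------------- truth


def write_truth(truth: SyntheticTruth, path: Path) -> None:
    payload = {
        "planted_compounds": sorted(truth.planted_compounds),
        "planted_feature_id": truth.planted_feature_id,
        "latent_prototypes": {
            cid: truth.latent_prototypes[cid].tolist()
            for cid in sorted(truth.latent_prototypes)
        },
        "config": config_to_dict(truth.config),
    }
    atomic_write_text(path, lambda fh: json.dump(payload, fh, indent=1, sort_keys=True))


def read_truth(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
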