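"""Ranked-list compilation and causal-network edge export.

The per-cluster kinase rankings are condensed into a unique top-k list
(the candidate mediators of the response), and curated relationships
between those nodes are written as a Cytoscape-compatible SIF file plus
an edge-attribute TSV (direction enhancing/inhibitory, basis
direct/indirect, net target activity).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger("kinbayes")

DIRECTIONS = frozenset({"enhancing", "inhibitory"})
BASES = frozenset({"direct", "indirect"})
TARGET_ACTIVITIES = frozenset({"increased", "decreased", "complex"})


class EdgeConflictError(ValueError):
    """Two records for the same edge carry conflicting annotations."""


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    direction: str
    basis: str
    target_activity: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge node names must be non-empty")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {sorted(BASES)}")
        if self.target_activity not in TARGET_ACTIVITIES:
            raise ValueError(
                f"target_activity must be one of {sorted(TARGET_ACTIVITIES)}"
            )


def compile_top_kinases(
    rankings: dict[str, pd.DataFrame], k: int = 5
) -> pd.DataFrame:
    """Union of the top-k kinases over all clusters, with provenance.

    Returns one row per unique kinase with the clusters it scored in and
    its rank there, sorted by best rank then symbol.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not rankings:
        raise ValueError("no rankings to compile")
    hits: dict[str, list[tuple[str, int]]] = {}
    for cluster in sorted(rankings):
        top = rankings[cluster].nsmallest(k, "rank")
        for row in top.itertuples():
            hits.setdefault(row.kinase, []).append((cluster, int(row.rank)))
    rows = [
        {
            "kinase": kinase,
            "best_rank": min(r for _, r in entries),
            "n_clusters": len(entries),
            "clusters": ";".join(f"{c}:{r}" for c, r in entries),
        }
        for kinase, entries in hits.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["best_rank", "kinase"])
        .reset_index(drop=True)
    )


def export_network(
    edges: list[NetworkEdge],
    sif_path,
    attributes_path,
    allowed_nodes: set[str] | None = None,
) -> None:
    """Write a SIF file and its edge-attribute TSV.

    If ``allowed_nodes`` is given, only edges whose source and target are
    both in the compiled top list (or explicitly whitelisted) are written.
    Duplicate edges with conflicting annotations raise.
    """
    seen: dict[tuple[str, str], NetworkEdge] = {}
    kept = []
    for e in edges:
        if allowed_nodes is not None and (
            e.source not in allowed_nodes or e.target not in allowed_nodes
        ):
            logger.info("dropping edge %s -> %s: node not in compiled list",
                        e.source, e.target)
            continue
        key = (e.source, e.target)
        if key in seen:
            if seen[key] != e:
                raise EdgeConflictError(
                    f"conflicting annotations for edge {e.source} -> {e.target}: "
                    f"{seen[key]} vs {e}"
                )
            continue
        seen[key] = e
        kept.append(e)
    with open(sif_path, "w", encoding="utf-8") as fh:
        for e in kept:
            fh.write(f"{e.source}\t{e.direction}\t{e.target}\n")
    pd.DataFrame(
        {
            "source": [e.source for e in kept],
            "target": [e.target for e in kept],
            "direction": [e.direction for e in kept],
            "basis": [e.basis for e in kept],
            "target_activity": [e.target_activity for e in kept],
        }
    ).to_csv(attributes_path, sep="\t", index=False)


def read_network(sif_path, attributes_path) -> list[NetworkEdge]:
    """Round-trip reader for export_network output."""
    attrs = pd.read_csv(attributes_path, sep="\t")
    edges = [
        NetworkEdge(
            source=str(r.source),
            target=str(r.target),
            direction=str(r.direction),
            basis=str(r.basis),
            target_activity=str(r.target_activity),
        )
        for r in attrs.itertuples()
    ]
    sif_pairs = set()
    with open(sif_path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                source, _, target = line.rstrip("\n").split("\t")
                sif_pairs.add((source, target))
    if sif_pairs != {(e.source, e.target) for e in edges}:
        raise ValueError("SIF and attribute files describe different edge sets")
    return edges


def rankings_to_long(rankings: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-cluster rankings into one long (cluster, rank, ...) table."""
    frames = []
    for cluster in sorted(rankings):
        df = rankings[cluster].copy()
        df.insert(0, "cluster", cluster)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, seed, thresholds, pivots, inputs) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "seed": seed,
        "thresholds": thresholds,
        "pivots": {k: (v if isinstance(v, (int, float, str)) else repr(v))
                   for k, v in pivots.items()},
        "input_checksums": {name: file_checksum(p) for name, p in inputs.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
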