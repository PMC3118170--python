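"""Readers and writers for the on-disk formats.

Formats: OBO 1.2 ontologies (via :mod:`netcoherence.ontology`), GAF 2.x and
two-column TSV annotation files, BLAST tabular (outfmt 6), plain TSV edge /
correlation / co-occurrence lists, MCL-dialect cluster files (one cluster per
line, tab-separated ids) and TSV evidence edge lists.  Protein identifiers
are opaque, case-sensitive strings throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .mcl import Clustering
from .network import EvidenceNetwork, EvidenceType

PathLike = Union[str, Path]

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


def read_gaf(path: PathLike, namespace: str = "biological_process") -> dict[str, set[str]]:
    """Read GAF 2.x annotations for one namespace.

    Uses column 2 (DB object id) as the protein, column 5 as the GO id and
    column 9 (aspect P/F/C) as the namespace filter.  Comment lines start
    with ``!``.  NOT-qualified annotations are skipped.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: malformed GAF record at line {i}")
            if "NOT" in cols[3].split("|"):
                continue
            if _ASPECT_TO_NAMESPACE.get(cols[8]) != namespace:
                continue
            out.setdefault(cols[1], set()).add(cols[4])
    return out


def read_annotation_tsv(path: PathLike) -> dict[str, set[str]]:
    """Read the 2-column TSV fallback: protein <tab> GO id."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: expected 2 columns at line {i}")
            out.setdefault(cols[0], set()).add(cols[1])
    return out


def write_annotation_tsv(direct: dict[str, Iterable[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for protein in sorted(direct):
            for term in sorted(direct[protein]):
                fh.write(f"{protein}\t{term}\n")


def read_correlation_tsv(path: PathLike) -> list[tuple[str, str, float]]:
    """proteinA <tab> proteinB <tab> Pearson r."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b", "r"], dtype={"a": str, "b": str})
    return list(df.itertuples(index=False, name=None))


def read_cooccurrence_tsv(path: PathLike) -> list[tuple[str, str, int]]:
    """proteinA <tab> proteinB <tab> shared abstract count."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b", "n"], dtype={"a": str, "b": str, "n": int})
    return list(df.itertuples(index=False, name=None))


def read_pairs_tsv(path: PathLike) -> list[tuple[str, str]]:
    """proteinA <tab> proteinB interaction pairs."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: expected 2 columns at line {i}")
            out.append((cols[0], cols[1]))
    return out


def read_blast_tabular(path: PathLike) -> list[list[str]]:
    """BLAST outfmt 6 rows as 12-column string lists."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}: malformed BLAST tabular row at line {i} "
                    f"({len(cols)} columns, expected 12)"
                )
            rows.append(cols)
    return rows


def write_network_tsv(net: EvidenceNetwork, path: PathLike) -> None:
    """Serialise a combined network: proteinA, proteinB, comma-joined evidence."""
    with open(path, "w") as fh:
        for node in sorted(net.nodes):
            if net.graph.degree(node) == 0:
                fh.write(f"{node}\t\t\n")  # orphan record keeps the node set intact
        for a, b, ev in sorted(
            ((min(a, b), max(a, b), ev) for a, b, ev in net.edges())
        ):
            joined = ",".join(sorted(e.value for e in ev))
            fh.write(f"{a}\t{b}\t{joined}\n")


def read_network_tsv(path: PathLike) -> EvidenceNetwork:
    net = EvidenceNetwork()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: expected 3 columns at line {i}")
            a, b, ev = cols[0], cols[1], cols[2]
            if not b and not ev:
                net.add_node(a)
                continue
            types = {EvidenceType(x) for x in ev.split(",") if x}
            if not types:
                raise ValueError(f"{path}: edge without evidence at line {i}")
            net.add_edge(a, b, types)
    return net


def read_clusters(path: PathLike) -> Clustering:
    """Read an MCL-dialect cluster file (one cluster per line, tab-separated).

    Duplicate membership across lines and empty lines are hard errors,
    because the downstream metrics require a true partition.
    """
    clusters: list[set[str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                raise ValueError(f"{path}: empty line {i} in cluster file")
            ids = [x for x in stripped.split("\t") if x]
            dup = seen & set(ids)
            if dup or len(set(ids)) != len(ids):
                offender = sorted(dup or {x for x in ids if ids.count(x) > 1})[0]
                raise ValueError(
                    f"{path}: protein {offender!r} assigned to two clusters (line {i})"
                )
            seen |= set(ids)
            clusters.append(set(ids))
    return Clustering.from_iterable(clusters)


def write_clusters(clustering: Clustering, path: PathLike) -> None:
    with open(path, "w") as fh:
        for cluster in sorted(clustering, key=lambda c: (-len(c), min(c))):
            fh.write("\t".join(sorted(cluster)) + "\n")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
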