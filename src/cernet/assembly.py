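"""Assembly of the ceRNA network from binding results and target evidence.

Two edge layers are built and joined on the shared miRNA:

* circRNA-miRNA edges: pairs with a retained binding site whose circRNA
  and miRNA are differentially expressed in *opposite* directions (a
  sponge and its miRNA should move oppositely);
* miRNA-mRNA edges: pairs present in the interaction evidence table with
  at least one database flag, both members differentially expressed, in
  opposite directions.

Joining the two layers on the miRNA yields circRNA-miRNA-mRNA triplets;
by construction the circRNA and mRNA share a direction and the miRNA has
the opposite one.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .datatypes import (BindingSite, CeRNATriplet, EVIDENCE_SOURCES,
                        InputError, InteractionRecord)

logger = logging.getLogger(__name__)


def load_interaction_table(path) -> list[InteractionRecord]:
    """Read a miRNA-target evidence TSV, keeping rows with >= 1 flag.

    Schema: mir_id, gene_id, then one boolean column per source database
    (targetscan, pictar, rna22, pita, miranda).  Rows with zero evidence
    are dropped (and counted in the log).
    """
    tab = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = ["mir_id", "gene_id", *EVIDENCE_SOURCES]
    if list(tab.columns) != expected:
        raise InputError(f"interaction table columns {list(tab.columns)} != {expected}")
    records: list[InteractionRecord] = []
    dropped = 0
    for lineno, row in enumerate(tab.itertuples(index=False), start=2):
        flags = []
        for src, val in zip(EVIDENCE_SOURCES, row[2:]):
            if val not in ("0", "1"):
                raise InputError(
                    f"line {lineno}: flag {src}={val!r} is not 0/1")
            flags.append(val == "1")
        rec = InteractionRecord(row.mir_id, row.gene_id, tuple(flags))
        if rec.evidence_count >= 1:
            records.append(rec)
        else:
            dropped += 1
    if not records:
        logger.warning("interaction table %s has no evidence-supported rows", path)
    if dropped:
        logger.info("dropped %d interaction rows with zero evidence", dropped)
    return records


def build_circ_mir_edges(binding_pairs: list[BindingSite],
                         circ_directions: dict[str, str],
                         mir_directions: dict[str, str]) -> pd.DataFrame:
    """circRNA-miRNA edges: bound pairs with opposite DE directions.

    ``binding_pairs`` carry target_id = circRNA id; pairs whose members
    are not DE-retained are skipped (logged).  Multiple sites per pair
    are assumed already collapsed to the best one.
    """
    rows = []
    skipped = 0
    for site in binding_pairs:
        cd = circ_directions.get(site.target_id)
        md = mir_directions.get(site.mir_id)
        if cd is None or md is None:
            skipped += 1
            continue
        if cd != md:
            rows.append((site.target_id, site.mir_id, cd, md,
                         site.score, site.energy))
    if skipped:
        logger.info("skipped %d binding pairs outside the DE sets", skipped)
    edges = pd.DataFrame(rows, columns=["circ_id", "mir_id", "circ_direction",
                                        "mir_direction", "score", "energy"])
    return edges.sort_values(["circ_id", "mir_id"], ignore_index=True)


def build_mir_mrna_edges(interactions: list[InteractionRecord],
                         mir_directions: dict[str, str],
                         mrna_directions: dict[str, str]) -> pd.DataFrame:
    """miRNA-mRNA edges: evidence-supported pairs, both DE, opposite."""
    rows = []
    for rec in interactions:
        md = mir_directions.get(rec.mir_id)
        gd = mrna_directions.get(rec.gene_id)
        if md is None or gd is None:
            continue
        if md != gd:
            rows.append((rec.mir_id, rec.gene_id, md, gd, rec.evidence_count))
    edges = pd.DataFrame(rows, columns=["mir_id", "mrna_id", "mir_direction",
                                        "mrna_direction", "evidence_count"])
    return edges.sort_values(["mir_id", "mrna_id"], ignore_index=True)


def assemble_triplets(circ_mir_edges: pd.DataFrame,
                      mir_mrna_edges: pd.DataFrame) -> list[CeRNATriplet]:
    """Join the two edge layers on the shared miRNA into sponge triplets.

    One triplet per (circ, mir, mrna) combination whose two edges share
    the miRNA; sorted by (circ_id, mir_id, mrna_id).  Raises if the two
    layers disagree on a miRNA's direction (cannot happen when both were
    built from the same DE results).
    """
    if circ_mir_edges.empty or mir_mrna_edges.empty:
        return []
    joined = circ_mir_edges.merge(mir_mrna_edges, on="mir_id",
                                  suffixes=("_cm", "_mm"))
    triplets = []
    for row in joined.itertuples(index=False):
        if row.mir_direction_cm != row.mir_direction_mm:
            raise RuntimeError(
                f"inconsistent miRNA direction for {row.mir_id}: "
                f"{row.mir_direction_cm} vs {row.mir_direction_mm}")
        triplets.append(CeRNATriplet(
            circ_id=row.circ_id, mir_id=row.mir_id, mrna_id=row.mrna_id,
            circ_direction=row.circ_direction,
            mir_direction=row.mir_direction_cm,
            mrna_direction=row.mrna_direction,
            binding_score=float(row.score),
            evidence_count=int(row.evidence_count)))
    triplets.sort(key=lambda t: (t.circ_id, t.mir_id, t.mrna_id))
    return triplets


def filter_by_coexpression(triplets: list[CeRNATriplet],
                           coexpression_edges: pd.DataFrame) -> list[CeRNATriplet]:
    """Optionally require each triplet's (circ, mrna) to be co-expressed."""
    if coexpression_edges.empty:
        return []
    allowed = set(zip(coexpression_edges["circ_id"], coexpression_edges["mrna_id"]))
    return [t for t in triplets if (t.circ_id, t.mrna_id) in allowed]


def triplet_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """Flat DataFrame rendering of a triplet list."""
    return pd.DataFrame(
        [(t.circ_id, t.mir_id, t.mrna_id, t.circ_direction, t.mir_direction,
          t.mrna_direction, t.binding_score, t.evidence_count)
         for t in triplets],
        columns=["circ_id", "mir_id", "mrna_id", "circ_direction",
                 "mir_direction", "mrna_direction", "binding_score",
                 "evidence_count"])


def to_graph(triplets: list[CeRNATriplet],
             log2fc: dict[str, float] | None = None) -> nx.DiGraph:
    """Network view of the triplets with node/edge attributes.

    Nodes carry rna_class, direction and (where known) log2fc; edges are
    typed ``binds`` (circRNA-miRNA, with the binding score) or
    ``targets`` (miRNA-mRNA, with the evidence count).
    """
    log2fc = log2fc or {}
    g = nx.DiGraph()
    for t in triplets:
        for node, cls, direction in ((t.circ_id, "circRNA", t.circ_direction),
                                     (t.mir_id, "miRNA", t.mir_direction),
                                     (t.mrna_id, "mRNA", t.mrna_direction)):
            attrs = {"rna_class": cls, "direction": direction}
            if node in log2fc:
                attrs["log2fc"] = float(log2fc[node])
            g.add_node(node, **attrs)
        g.add_edge(t.circ_id, t.mir_id, type="binds", score=t.binding_score)
        g.add_edge(t.mir_id, t.mrna_id, type="targets",
                   evidence_count=t.evidence_count)
    return g


def export_network(triplets: list[CeRNATriplet], path, fmt: str,
                   log2fc: dict[str, float] | None = None,
                   provenance: str | None = None) -> None:
    """Write the triplet network as SIF or GraphML.

    SIF lines are ``node<TAB>relation<TAB>node``; GraphML carries the
    node/edge attributes.  An empty network produces a valid empty file
    with a warning.
    """
    if not triplets:
        logger.warning("exporting an empty network to %s", path)
    g = to_graph(triplets, log2fc)
    if fmt == "sif":
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"#{provenance}\n")
            for u, v, data in sorted(g.edges(data=True)):
                rel = data.get("type", "edge")
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt == "graphml":
        if provenance:
            g.graph["provenance"] = provenance
        nx.write_graphml(g, path)
    else:
        raise InputError(f"unknown network format {fmt!r} (use 'sif' or 'graphml')")
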