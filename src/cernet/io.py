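"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are TSV (first column = feature id, header = sample
ids) with a two-column sample-group TSV alongside; sequences are FASTA
(via Biopython); gene sets are GMT; interactions and disease pathways
are TSV with fixed schemas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ExpressionMatrix, InputError

logger = logging.getLogger(__name__)


def read_groups(path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series indexed by sample."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if list(tab.columns) != ["sample_id", "group"]:
        raise InputError(f"{path}: expected columns sample_id, group, "
                         f"got {list(tab.columns)}")
    if tab["sample_id"].duplicated().any():
        dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"{path}: duplicate sample ids {dup}")
    return pd.Series(tab["group"].values, index=tab["sample_id"].values,
                     name="group")


def read_expression_matrix(path, groups_path,
                           collapse_duplicates: bool = False) -> ExpressionMatrix:
    """Load an expression TSV plus its group file into an ExpressionMatrix.

    Feature order follows the file.  Duplicate feature ids are an error
    unless ``collapse_duplicates`` is set, in which case each duplicated
    id keeps the row with the highest mean expression (multi-probe
    collapse; logged).
    """
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if tab.index.has_duplicates:
        if not collapse_duplicates:
            dup = tab.index[tab.index.duplicated()].unique().tolist()
            raise InputError(f"{path}: duplicate feature ids {dup}")
        means = tab.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for pos, fid in enumerate(tab.index):
            if fid not in best or means[pos] > means[best[fid]]:
                best[fid] = pos
        first_seen = list(dict.fromkeys(tab.index))
        n_before = len(tab)
        tab = tab.iloc[[best[fid] for fid in first_seen]]
        logger.info("collapsed %d duplicate probe rows in %s",
                    n_before - len(tab), path)
    bad = tab.columns[~tab.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise InputError(f"{path}: non-numeric values in columns {list(bad)}")
    groups = read_groups(groups_path)
    missing = [s for s in tab.columns if s not in groups.index]
    if missing:
        raise InputError(f"{path}: samples missing from group file: {missing}")
    return ExpressionMatrix(tab, groups)


def write_expression_matrix(m: ExpressionMatrix, path, groups_path=None) -> None:
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.6f")
    if groups_path is not None:
        g = m.groups.rename_axis("sample_id").reset_index()
        g.to_csv(groups_path, sep="\t", index=False)


def write_fasta(seqs: dict[str, str], path, alphabet: str = "ACGU") -> None:
    """Write a sequence pool as FASTA, declaring the alphabet per file."""
    records = [SeqRecord(Seq(s), id=name, description=f"alphabet={alphabet}")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA pool; T is not remapped here (the aligner maps T->U)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gmt(collection: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection):
            name, members = collection[set_id]
            fh.write("\t".join([set_id, name, *members]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT lines: set_id <TAB> description <TAB> gene ids..."""
    collection: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs id, "
                                 f"description and >= 1 gene")
            if parts[0] in collection:
                raise InputError(f"{path}:{lineno}: duplicate set id {parts[0]!r}")
            collection[parts[0]] = (parts[1], parts[2:])
    return collection


def write_interactions(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def write_disease_list(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def read_disease_list(path) -> set[str]:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "pathway_id" not in tab.columns:
        raise InputError(f"{path}: expected a 'pathway_id' column, "
                         f"got {list(tab.columns)}")
    return set(tab["pathway_id"])


def write_de_table(tab: pd.DataFrame, path) -> None:
    out = tab.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_fixture(config, out_dir) -> dict[str, Path]:
    """Materialise a complete synthetic study on disk.

    Generates expression (training + validation), sequences and
    annotations from ``config`` and writes every pipeline input file
    under ``out_dir``; returns the path map.  Ground truth goes to
    ``truth_*.tsv`` tables for benchmarking.
    """
    from . import simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    circ, mir, mrna, truth = simulate.generate_expression(config)
    mir_seqs, circ_seqs, mrna_seqs = simulate.generate_sequences(config, truth)
    interactions, collection, disease = simulate.generate_annotations(config, truth)
    vmir, vmrna = simulate.generate_validation(config, truth)

    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    write_expression_matrix(circ, p("circ_expr.tsv"), p("groups.tsv"))
    write_expression_matrix(mir, p("mir_expr.tsv"))
    write_expression_matrix(mrna, p("mrna_expr.tsv"))
    write_expression_matrix(vmir, p("validation_mir_expr.tsv"),
                            p("validation_groups.tsv"))
    write_expression_matrix(vmrna, p("validation_mrna_expr.tsv"))
    write_fasta(mir_seqs, p("mirnas.fasta"), alphabet="ACGU")
    write_fasta(circ_seqs, p("circ_targets.fasta"), alphabet="ACGU")
    write_fasta(mrna_seqs, p("mrna_targets.fasta"), alphabet="ACGU")
    write_interactions(interactions, p("interactions.tsv"))
    write_gmt(collection, p("gene_sets.gmt"))
    write_disease_list(disease, p("disease_pathways.tsv"))

    pd.DataFrame(truth.planted_triplets,
                 columns=["circ_id", "mir_id", "mrna_id", "direction"]) \
        .to_csv(p("truth_triplets.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.planted_sites,
                 columns=["target_id", "mir_id", "start", "end"]) \
        .to_csv(p("truth_sites.tsv"), sep="\t", index=False)
    de_rows = [(profile, fid, shift)
               for profile, feats in truth.de_features.items()
               for fid, shift in feats]
    pd.DataFrame(de_rows, columns=["profile", "feature_id", "true_shift"]) \
        .to_csv(p("truth_de_features.tsv"), sep="\t", index=False)
    return paths
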