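"""End-to-end ceRNA network inference as a model/results pair.

`CeRNANetworkModel` bundles the study inputs (three matched expression
profiles, sequence pools, the target-evidence table, gene sets and a
disease-pathway list) with the screening thresholds; `fit()` executes
the stages in order —

    differential expression (x3)  ->  co-expression network
    ->  binding prediction        ->  edge filtering and triplet join
    ->  pathway enrichment        ->  disease-pathway intersection
    ->  independent-cohort validation

— and returns a `CeRNANetworkResults` carrying every intermediate table,
the final sponge triplets, and a `summary()` of the funnel.  The whole
run is deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import assembly, binding, coexpression, diffexpr, enrichment, io, validation
from .datatypes import (AlignParams, CeRNATriplet, ConsistencyRecord,
                        EnrichmentResult, ExpressionMatrix, InputError,
                        InteractionRecord)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Every screening threshold of the pipeline, at its default value."""

    fdr_max: float = 0.05
    lfc_min: float = 1.0
    pcc_min: float = 0.9
    absolute_pcc: bool = False
    enrich_p: float = 0.05
    validation_p: float = 0.05
    ease: bool = False
    require_coexpression: bool = False
    moderated: bool = True
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        for name, lo, hi in (("fdr_max", 0, 1), ("enrich_p", 0, 1),
                             ("validation_p", 0, 1)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise InputError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if not (-1 <= self.pcc_min <= 1):
            raise InputError(f"pcc_min must lie in [-1, 1], got {self.pcc_min}")
        if self.lfc_min < 0:
            raise InputError(f"lfc_min must be >= 0, got {self.lfc_min}")


class CeRNANetworkModel:
    """ceRNA sponge-network inference model over a matched study.

    Parameters
    ----------
    circ, mir, mrna : ExpressionMatrix
        Matched training profiles (same samples, log2 scale).
    mir_seqs, circ_seqs : dict
        Sequence pools for binding prediction (id -> sequence).
    interactions : list of InteractionRecord
        Evidence-supported miRNA-target records.
    collection : dict
        Gene sets, set_id -> (description, member genes).
    disease_ids : set or None
        Disease-pathway id list; with None the disease stage is skipped.
    validation_mir, validation_mrna : ExpressionMatrix or None
        Independent cohort profiles for direction validation.
    thresholds : Thresholds
    """

    def __init__(self, circ: ExpressionMatrix, mir: ExpressionMatrix,
                 mrna: ExpressionMatrix, mir_seqs: dict[str, str],
                 circ_seqs: dict[str, str],
                 interactions: list[InteractionRecord],
                 collection: dict[str, tuple[str, list[str]]] | None = None,
                 disease_ids: set[str] | None = None,
                 validation_mir: ExpressionMatrix | None = None,
                 validation_mrna: ExpressionMatrix | None = None,
                 thresholds: Thresholds | None = None):
        self.circ, self.mir, self.mrna = circ, mir, mrna
        self.mir_seqs, self.circ_seqs = mir_seqs, circ_seqs
        self.interactions = interactions
        self.collection = collection or {}
        self.disease_ids = disease_ids
        self.validation_mir = validation_mir
        self.validation_mrna = validation_mrna
        self.thresholds = thresholds or Thresholds()

    @classmethod
    def from_files(cls, circ_expr, mir_expr, mrna_expr, groups,
                   mir_fasta, circ_fasta, interactions_tsv,
                   gmt=None, disease_tsv=None,
                   validation_mir_expr=None, validation_mrna_expr=None,
                   validation_groups=None,
                   thresholds: Thresholds | None = None) -> "CeRNANetworkModel":
        """Build the model from the on-disk formats."""
        circ = io.read_expression_matrix(circ_expr, groups)
        mir = io.read_expression_matrix(mir_expr, groups)
        mrna = io.read_expression_matrix(mrna_expr, groups)
        vmir = vmrna = None
        if validation_mir_expr is not None:
            vmir = io.read_expression_matrix(validation_mir_expr, validation_groups)
        if validation_mrna_expr is not None:
            vmrna = io.read_expression_matrix(validation_mrna_expr, validation_groups)
        return cls(
            circ, mir, mrna,
            mir_seqs=io.read_fasta(mir_fasta),
            circ_seqs=io.read_fasta(circ_fasta),
            interactions=assembly.load_interaction_table(interactions_tsv),
            collection=io.read_gmt(gmt) if gmt is not None else None,
            disease_ids=(io.read_disease_list(disease_tsv)
                         if disease_tsv is not None else None),
            validation_mir=vmir, validation_mrna=vmrna,
            thresholds=thresholds)

    @classmethod
    def from_synthetic(cls, config, thresholds: Thresholds | None = None,
                       with_validation: bool = True) -> tuple["CeRNANetworkModel", "object"]:
        """Generate a full synthetic study in memory; returns (model, truth)."""
        from . import simulate

        circ, mir, mrna, truth = simulate.generate_expression(config)
        mir_seqs, circ_seqs, _ = simulate.generate_sequences(config, truth)
        itab, collection, disease = simulate.generate_annotations(config, truth)
        records = [InteractionRecord(r.mir_id, r.gene_id,
                                     tuple(bool(int(v)) for v in r[2:]))
                   for r in itab.itertuples(index=False)]
        records = [r for r in records if r.evidence_count >= 1]
        vmir = vmrna = None
        if with_validation:
            vmir, vmrna = simulate.generate_validation(config, truth)
        model = cls(circ, mir, mrna, mir_seqs, circ_seqs, records,
                    collection=collection,
                    disease_ids=set(disease["pathway_id"]),
                    validation_mir=vmir, validation_mrna=vmrna,
                    thresholds=thresholds)
        return model, truth

    def fit(self) -> "CeRNANetworkResults":
        """Run every stage and return the results object."""
        th = self.thresholds
        logger.info("stage 1/6: differential expression")
        de_circ = diffexpr.de_table(self.circ, moderated=th.moderated,
                                    fdr_max=th.fdr_max, lfc_min=th.lfc_min)
        de_mir = diffexpr.de_table(self.mir, moderated=th.moderated,
                                   fdr_max=th.fdr_max, lfc_min=th.lfc_min)
        de_mrna = diffexpr.de_table(self.mrna, moderated=th.moderated,
                                    fdr_max=th.fdr_max, lfc_min=th.lfc_min)
        circ_dir = diffexpr.directions(de_circ)
        mir_dir = diffexpr.directions(de_mir)
        mrna_dir = diffexpr.directions(de_mrna)
        collision = (set(circ_dir) & set(mir_dir)) | \
                    (set(circ_dir) & set(mrna_dir)) | \
                    (set(mir_dir) & set(mrna_dir))
        if collision:
            raise InputError(f"feature ids shared across RNA classes: "
                             f"{sorted(collision)[:5]}")

        logger.info("stage 2/6: co-expression network (%d circ x %d mRNA)",
                    len(circ_dir), len(mrna_dir))
        coexpr = coexpression.build_coexpression_network(
            self.circ, self.mrna, sorted(circ_dir), sorted(mrna_dir),
            threshold=th.pcc_min, absolute=th.absolute_pcc)

        logger.info("stage 3/6: binding prediction")
        mirs = {m: self.mir_seqs[m] for m in sorted(mir_dir)
                if m in self.mir_seqs}
        circs = {c: self.circ_seqs[c] for c in sorted(circ_dir)
                 if c in self.circ_seqs}
        binding_pairs = binding.predict_pairs(mirs, circs, th.align)

        logger.info("stage 4/6: network assembly (%d bound pairs)",
                    len(binding_pairs))
        circ_mir = assembly.build_circ_mir_edges(binding_pairs, circ_dir, mir_dir)
        mir_mrna = assembly.build_mir_mrna_edges(self.interactions,
                                                 mir_dir, mrna_dir)
        triplets = assembly.assemble_triplets(circ_mir, mir_mrna)
        if th.require_coexpression:
            triplets = assembly.filter_by_coexpression(triplets, coexpr)

        results = CeRNANetworkResults(
            model=self, de_circ=de_circ, de_mir=de_mir, de_mrna=de_mrna,
            coexpression_edges=coexpr, binding_pairs=binding_pairs,
            circ_mir_edges=circ_mir, mir_mrna_edges=mir_mrna,
            triplets=triplets)

        logger.info("stage 5/6: enrichment and disease filtering (%d triplets)",
                    len(triplets))
        network_mrnas = sorted({t.mrna_id for t in triplets})
        if network_mrnas and self.collection:
            background = set(de_mrna.index)
            for _, members in self.collection.values():
                background |= set(members)
            enriched = enrichment.enrich_gene_sets(
                network_mrnas, self.collection, background, ease=th.ease)
            results.enrichment = enriched
            significant = [r for r in enriched if r.p < th.enrich_p]
            results.significant_sets = significant
            if self.disease_ids is None:
                logger.warning("no disease-pathway list configured; "
                               "stopping after enrichment")
            else:
                flagged = enrichment.intersect_disease_pathways(
                    significant, self.disease_ids)
                results.disease_sets = flagged
                sub, memberships = enrichment.extract_disease_subnetwork(
                    triplets, flagged, self.collection)
                results.disease_triplets = sub
                results.pathway_memberships = memberships
        elif not network_mrnas:
            logger.warning("empty ceRNA network; enrichment skipped")

        logger.info("stage 6/6: cross-dataset validation")
        net_features: dict[str, tuple[str, str]] = {}
        for t in (results.disease_triplets
                  if results.disease_triplets is not None else triplets):
            net_features[t.mir_id] = ("miRNA", t.mir_direction)
            net_features[t.mrna_id] = ("mRNA", t.mrna_direction)
        if net_features and (self.validation_mir is not None
                             or self.validation_mrna is not None):
            records: list[ConsistencyRecord] = []
            for cls_name, matrix in (("miRNA", self.validation_mir),
                                     ("mRNA", self.validation_mrna)):
                feats = {f: v for f, v in net_features.items()
                         if v[0] == cls_name}
                if feats and matrix is not None:
                    records += validation.cross_dataset_consistency(feats, matrix)
            results.consistency = records
        return results


@dataclass
class CeRNANetworkResults:
    """Everything the fitted pipeline produced, stage by stage."""

    model: CeRNANetworkModel
    de_circ: pd.DataFrame
    de_mir: pd.DataFrame
    de_mrna: pd.DataFrame
    coexpression_edges: pd.DataFrame
    binding_pairs: list
    circ_mir_edges: pd.DataFrame
    mir_mrna_edges: pd.DataFrame
    triplets: list[CeRNATriplet]
    enrichment: list[EnrichmentResult] | None = None
    significant_sets: list[EnrichmentResult] | None = None
    disease_sets: list[EnrichmentResult] | None = None
    disease_triplets: list[CeRNATriplet] | None = None
    pathway_memberships: list[tuple[str, str]] | None = None
    consistency: list[ConsistencyRecord] | None = None

    # -- reporting ---------------------------------------------------------

    def funnel(self) -> dict[str, int]:
        """Stage-by-stage counts, the comparison point for real studies."""
        n_ret = lambda tab: int((tab["direction"] != "ns").sum())
        counts = {
            "de_circ": n_ret(self.de_circ),
            "de_mir": n_ret(self.de_mir),
            "de_mrna": n_ret(self.de_mrna),
            "coexpression_edges": len(self.coexpression_edges),
            "binding_pairs": len(self.binding_pairs),
            "circ_mir_edges": len(self.circ_mir_edges),
            "mir_mrna_edges": len(self.mir_mrna_edges),
            "triplets": len(self.triplets),
        }
        if self.significant_sets is not None:
            counts["enriched_pathways"] = len(self.significant_sets)
        if self.disease_sets is not None:
            counts["disease_pathways"] = len(self.disease_sets)
        if self.disease_triplets is not None:
            counts["disease_triplets"] = len(self.disease_triplets)
        if self.consistency is not None:
            tested = [r for r in self.consistency if r.tested]
            counts["validation_tested"] = len(tested)
            counts["validation_consistent"] = sum(bool(r.consistent)
                                                  for r in tested)
        return counts

    def summary(self) -> str:
        """Human-readable funnel table, statsmodels-style."""
        lines = ["ceRNA network inference results",
                 "=" * 34]
        for key, val in self.funnel().items():
            lines.append(f"{key:<24s} {val:>6d}")
        if self.disease_triplets:
            lines.append("-" * 34)
            lines.append("disease-related sponge triplets:")
            for t in self.disease_triplets[:20]:
                lines.append(f"  {t.circ_id}({t.circ_direction}) -| "
                             f"{t.mir_id}({t.mir_direction}) -| "
                             f"{t.mrna_id}({t.mrna_direction})")
            if len(self.disease_triplets) > 20:
                lines.append(f"  ... and {len(self.disease_triplets) - 20} more")
        return "\n".join(lines)

    def log2fc_map(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for tab in (self.de_circ, self.de_mir, self.de_mrna):
            out.update(tab["log2fc"].to_dict())
        return out

    def save(self, out_dir, seed: int | None = None) -> dict:
        """Write all stage artifacts plus a run manifest under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_de_table(self.de_circ, out / "de_circ.tsv")
        io.write_de_table(self.de_mir, out / "de_mir.tsv")
        io.write_de_table(self.de_mrna, out / "de_mrna.tsv")
        self.coexpression_edges.to_csv(out / "coexpression_edges.tsv",
                                       sep="\t", index=False,
                                       float_format="%.6f")
        with open(out / "coexpression.sif", "w") as fh:
            for row in self.coexpression_edges.itertuples(index=False):
                fh.write(f"{row.circ_id}\tco_expr\t{row.mrna_id}\n")
        pd.DataFrame(
            [(s.mir_id, s.target_id, s.target_start, s.target_end, s.score,
              s.max_score, s.ratio, s.energy) for s in self.binding_pairs],
            columns=["mir_id", "target_id", "start", "end", "score",
                     "max_score", "ratio", "energy"]) \
            .to_csv(out / "binding_pairs.tsv", sep="\t", index=False,
                    float_format="%.4f")
        assembly.triplet_table(self.triplets).to_csv(
            out / "triplets.tsv", sep="\t", index=False, float_format="%.4f")
        prov = self._provenance(seed)
        assembly.export_network(self.triplets, out / "cerna_network.sif",
                                "sif", self.log2fc_map(), provenance=prov)
        assembly.export_network(self.triplets, out / "cerna_network.graphml",
                                "graphml", self.log2fc_map(), provenance=prov)
        if self.enrichment is not None:
            pd.DataFrame(
                [(r.set_id, r.set_name, r.k, r.K, r.n, r.N, r.p,
                  r.disease_flag, ";".join(r.overlap))
                 for r in self.enrichment],
                columns=["set_id", "set_name", "k", "K", "n", "N", "p",
                         "disease_flag", "overlap"]) \
                .to_csv(out / "enrichment.tsv", sep="\t", index=False,
                        float_format="%.6g")
        if self.disease_triplets is not None:
            assembly.triplet_table(self.disease_triplets).to_csv(
                out / "disease_triplets.tsv", sep="\t", index=False,
                float_format="%.4f")
            assembly.export_network(self.disease_triplets,
                                    out / "disease_network.sif", "sif",
                                    self.log2fc_map(), provenance=prov)
            pd.DataFrame(self.pathway_memberships or [],
                         columns=["pathway_id", "mrna_id"]) \
                .to_csv(out / "pathway_memberships.tsv", sep="\t", index=False)
        if self.consistency is not None:
            validation.consistency_table(self.consistency).to_csv(
                out / "validation_consistency.tsv", sep="\t", index=False,
                float_format="%.6g")
            (out / "validation_summary.txt").write_text(
                validation.summarize(self.consistency) + "\n")
        manifest = {
            "version": __version__,
            "seed": seed,
            "thresholds_hash": self._config_hash(),
            "counts": self.funnel(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
        return manifest

    def _config_hash(self) -> str:
        blob = json.dumps(asdict(self.model.thresholds), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def _provenance(self, seed) -> str:
        return (f"cernet {__version__} config={self._config_hash()} "
                f"seed={seed}")


def run_pipeline(model: CeRNANetworkModel, out_dir,
                 seed: int | None = None) -> dict:
    """Fit the model and persist every artifact; returns the manifest."""
    results = model.fit()
    return results.save(out_dir, seed=seed)
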