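"""Directional miRNA-mRNA regulation and ceRNA triplet network assembly.

A *regulatory edge* links a significantly dysregulated miRNA to a
significantly dysregulated predicted target moving in the opposite
direction (up-miRNA with down-mRNA, or down-miRNA with up-mRNA) — the
anti-regulation signature expected of direct miRNA repression.

A *ceRNA triplet* (lncRNA, miRNA, mRNA) models the sponge hypothesis: a
lncRNA that shares a miRNA response element with an mRNA and is
co-expressed with it can titrate the miRNA away and de-repress the mRNA.
A triplet is emitted when all of the following hold:

1. the lncRNA is dysregulated (FC >= fc_min, p < p_max);
2. the mRNA is a passed target prediction of the miRNA forming a
   regulatory edge (so miRNA and mRNA are both significant, opposite);
3. the lncRNA itself carries a passed MRE for the same miRNA;
4. the lncRNA-mRNA pair is a retained co-expression edge with r > 0;
5. lncRNA and mRNA share their direction (both opposite the miRNA) —
   optional via ``require_direction``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .coexpr import CoexpressionEdge
from .mre_scan import SeedSite, TargetPrediction

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatoryEdge:
    """miRNA -> target edge with opposite DE directions."""

    mirna_id: str
    target_id: str
    mirna_direction: str
    target_direction: str
    prediction: TargetPrediction

    def __post_init__(self) -> None:
        if {self.mirna_direction, self.target_direction} != {"up", "down"}:
            raise ValueError("regulatory edge requires opposite up/down directions")


@dataclass(frozen=True)
class CeRNAThresholds:
    """Criteria for the triplet assembly stage.

    The lncRNA dysregulation filter conventionally uses an inclusive fold
    change bound (FC >= 2.0) and a strict p bound (p < 0.05); both are
    distinct from the per-class DE-calling thresholds and owned by this
    stage.
    """

    lnc_fc_min: float = 2.0
    lnc_p_max: float = 0.05
    require_direction: bool = True
    require_positive_corr: bool = True


@dataclass
class CeRNATriplet:
    """One lncRNA-miRNA-mRNA sponge candidate with its supporting evidence."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    phase: str = ""
    lnc_de: dict = field(default_factory=dict)
    mir_de: dict = field(default_factory=dict)
    mrna_de: dict = field(default_factory=dict)
    lnc_mre: SeedSite | None = None
    mrna_mre: SeedSite | None = None
    coexpr: CoexpressionEdge | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def _de_index(de_table: pd.DataFrame) -> dict[str, dict]:
    return {row["gene_id"]: row.to_dict() for _, row in de_table.iterrows()}


def mirna_mrna_network(
    mir_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    predictions: list[TargetPrediction],
) -> list[RegulatoryEdge]:
    """Edges miRNA -> mRNA: passed prediction, both significant, opposite.

    Predictions referencing genes absent from either DE table are logged
    and skipped.
    """
    mir = _de_index(mir_de)
    mrna = _de_index(mrna_de)
    edges: list[RegulatoryEdge] = []
    for pred in predictions:
        if not pred.passed:
            continue
        if pred.mirna_id not in mir or pred.target_id not in mrna:
            log.warning("prediction %s->%s references a gene absent from the DE tables",
                        pred.mirna_id, pred.target_id)
            continue
        m, t = mir[pred.mirna_id], mrna[pred.target_id]
        if not (m["significant"] and t["significant"]):
            continue
        if {m["direction"], t["direction"]} != {"up", "down"}:
            continue
        edges.append(RegulatoryEdge(
            mirna_id=pred.mirna_id, target_id=pred.target_id,
            mirna_direction=m["direction"], target_direction=t["direction"],
            prediction=pred,
        ))
    edges.sort(key=lambda e: (e.mirna_id, e.target_id))
    return edges


def _lnc_passes(row: dict, thr: CeRNAThresholds) -> bool:
    fc = row["fc"]
    return (fc >= thr.lnc_fc_min or fc <= 1.0 / thr.lnc_fc_min) and row["p"] < thr.lnc_p_max


def _best_passing_site(pred: TargetPrediction) -> SeedSite | None:
    passing = [s for s in pred.sites if s.pair_score is not None]
    return max(passing, key=lambda s: s.pair_score) if passing else None


def assemble_cerna_triplets(
    lnc_de: pd.DataFrame,
    mir_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    lnc_predictions: list[TargetPrediction],
    mrna_predictions: list[TargetPrediction],
    cnc_edges: list[CoexpressionEdge],
    thresholds: CeRNAThresholds = CeRNAThresholds(),
    phase: str = "",
) -> list[CeRNATriplet]:
    """Emit every (lncRNA, miRNA, mRNA) satisfying the sponge criteria.

    Inputs must all derive from the same contrast/phase.  Duplicates (same
    triple reached via several sites) are de-duplicated by triple identity.
    """
    lnc_idx = _de_index(lnc_de)
    mir_idx = _de_index(mir_de)
    mrna_idx = _de_index(mrna_de)
    reg_edges = mirna_mrna_network(mir_de, mrna_de, mrna_predictions)
    lnc_by_mir: dict[str, list[TargetPrediction]] = {}
    for pred in lnc_predictions:
        if pred.passed:
            lnc_by_mir.setdefault(pred.mirna_id, []).append(pred)
    cnc_idx = {(e.ncrna_id, e.coding_id): e for e in cnc_edges}
    seen: set[tuple[str, str, str]] = set()
    triplets: list[CeRNATriplet] = []
    for edge in reg_edges:
        for lnc_pred in lnc_by_mir.get(edge.mirna_id, []):
            lnc_id = lnc_pred.target_id
            if lnc_id not in lnc_idx:
                log.warning("lncRNA %s has predictions but no DE record; skipped", lnc_id)
                continue
            lrow = lnc_idx[lnc_id]
            if not _lnc_passes(lrow, thresholds):
                continue
            ce = cnc_idx.get((lnc_id, edge.target_id))
            if ce is None:
                continue
            if thresholds.require_positive_corr and ce.r <= 0:
                continue
            if thresholds.require_direction and lrow["direction"] != edge.target_direction:
                continue
            key = (lnc_id, edge.mirna_id, edge.target_id)
            if key in seen:
                continue
            seen.add(key)
            triplets.append(CeRNATriplet(
                lncrna_id=lnc_id, mirna_id=edge.mirna_id, mrna_id=edge.target_id,
                phase=phase, lnc_de=lrow,
                mir_de=mir_idx[edge.mirna_id],
                mrna_de=mrna_idx[edge.target_id],
                lnc_mre=_best_passing_site(lnc_pred),
                mrna_mre=_best_passing_site(edge.prediction),
                coexpr=ce,
            ))
    triplets.sort(key=lambda t: t.key)
    return triplets


def audit_triplet(
    triplet: CeRNATriplet,
    lnc_de: pd.DataFrame,
    mir_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    lnc_predictions: list[TargetPrediction],
    mrna_predictions: list[TargetPrediction],
    cnc_edges: list[CoexpressionEdge],
    thresholds: CeRNAThresholds = CeRNAThresholds(),
) -> bool:
    """Re-verify every criterion of an emitted triplet from the raw inputs."""
    lnc_idx = _de_index(lnc_de)
    mir_idx = _de_index(mir_de)
    mrna_idx = _de_index(mrna_de)
    if triplet.lncrna_id not in lnc_idx:
        return False
    lrow = lnc_idx[triplet.lncrna_id]
    mrow = mir_idx.get(triplet.mirna_id)
    trow = mrna_idx.get(triplet.mrna_id)
    if mrow is None or trow is None:
        return False
    if not _lnc_passes(lrow, thresholds):
        return False
    if not (mrow["significant"] and trow["significant"]):
        return False
    if {mrow["direction"], trow["direction"]} != {"up", "down"}:
        return False
    if thresholds.require_direction and lrow["direction"] != trow["direction"]:
        return False
    mrna_ok = any(
        p.passed and p.mirna_id == triplet.mirna_id and p.target_id == triplet.mrna_id
        for p in mrna_predictions
    )
    lnc_ok = any(
        p.passed and p.mirna_id == triplet.mirna_id and p.target_id == triplet.lncrna_id
        for p in lnc_predictions
    )
    ce = next((e for e in cnc_edges
               if e.ncrna_id == triplet.lncrna_id and e.coding_id == triplet.mrna_id), None)
    if ce is None:
        return False
    if thresholds.require_positive_corr and ce.r <= 0:
        return False
    return mrna_ok and lnc_ok


def build_graph(
    edges: list[RegulatoryEdge] | None = None,
    triplets: list[CeRNATriplet] | None = None,
) -> nx.Graph:
    """Undirected evidence graph over miRNA/lncRNA/mRNA nodes.

    Node attributes: ``rna_class`` and ``direction``; edge attributes:
    ``evidence`` ('regulatory', 'mre' or 'coexpression') plus the relevant
    scores.
    """
    g = nx.Graph()
    for e in edges or []:
        g.add_node(e.mirna_id, rna_class="miRNA", direction=e.mirna_direction)
        g.add_node(e.target_id, rna_class="mRNA", direction=e.target_direction)
        g.add_edge(e.mirna_id, e.target_id, evidence="regulatory",
                   pair_score=float(e.prediction.best_pair_score),
                   energy=float(e.prediction.best_energy))
    for t in triplets or []:
        g.add_node(t.mirna_id, rna_class="miRNA", direction=t.mir_de.get("direction", ""))
        g.add_node(t.lncrna_id, rna_class="lncRNA", direction=t.lnc_de.get("direction", ""))
        g.add_node(t.mrna_id, rna_class="mRNA", direction=t.mrna_de.get("direction", ""))
        if t.mrna_mre is not None:
            g.add_edge(t.mirna_id, t.mrna_id, evidence="regulatory",
                       pair_score=float(t.mrna_mre.pair_score),
                       energy=float(t.mrna_mre.energy))
        else:
            g.add_edge(t.mirna_id, t.mrna_id, evidence="regulatory")
        if t.lnc_mre is not None:
            g.add_edge(t.mirna_id, t.lncrna_id, evidence="mre",
                       pair_score=float(t.lnc_mre.pair_score),
                       energy=float(t.lnc_mre.energy))
        else:
            g.add_edge(t.mirna_id, t.lncrna_id, evidence="mre")
        if t.coexpr is not None:
            g.add_edge(t.lncrna_id, t.mrna_id, evidence="coexpression",
                       r=float(t.coexpr.r), q=float(t.coexpr.q))
        else:
            g.add_edge(t.lncrna_id, t.mrna_id, evidence="coexpression")
    return g


def export_network(
    path,
    edges: list[RegulatoryEdge] | None = None,
    triplets: list[CeRNATriplet] | None = None,
    fmt: str = "graphml",
) -> nx.Graph:
    """Write the evidence graph as GraphML or a TSV edge list; returns it."""
    g = build_graph(edges, triplets)
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "tsv":
        rows = []
        for u, v, data in sorted(g.edges(data=True)):
            rows.append({"source": u, "target": v, **data})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'tsv')")
    return g


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """Tabular summary of a triplet list (one row per triple)."""
    rows = []
    for t in triplets:
        rows.append({
            "lncrna_id": t.lncrna_id,
            "mirna_id": t.mirna_id,
            "mrna_id": t.mrna_id,
            "phase": t.phase,
            "lnc_direction": t.lnc_de.get("direction", ""),
            "mir_direction": t.mir_de.get("direction", ""),
            "mrna_direction": t.mrna_de.get("direction", ""),
            "lnc_fc": t.lnc_de.get("fc"),
            "mir_fc": t.mir_de.get("fc"),
            "mrna_fc": t.mrna_de.get("fc"),
            "coexpr_r": t.coexpr.r if t.coexpr else None,
            "lnc_site_score": t.lnc_mre.pair_score if t.lnc_mre else None,
            "mrna_site_score": t.mrna_mre.pair_score if t.mrna_mre else None,
        })
    cols = ["lncrna_id", "mirna_id", "mrna_id", "phase", "lnc_direction",
            "mir_direction", "mrna_direction", "lnc_fc", "mir_fc", "mrna_fc",
            "coexpr_r", "lnc_site_score", "mrna_site_score"]
    return pd.DataFrame(rows, columns=cols)
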