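"""End-to-end orchestration: simulate/ingest -> normalize -> DE -> scan -> CNC -> networks.

One TOML config drives the whole run; every intermediate table is written to
the output directory and a JSON manifest records parameters, input digests
and per-stage counts, so identical config + seed reproduce identical
manifests.  Stage order: expression matrices (simulated or read from TSV)
are normalized per class (quantile for long transcripts, median for short
RNAs), detection-filtered, tested per contrast, then the scanner, the
co-expression screen, and the network assembly run per phase.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cerna_net import (CeRNAThresholds, assemble_cerna_triplets, export_network,
                        mirna_mrna_network, triplets_to_frame)
from .coexpr import cnc_network, edges_to_records
from .diffexpr import DEFAULT_THRESHOLDS, DEThresholds, call_differential, de_counts
from .enrichment import hypergeometric_enrichment, read_gmt
from .mre_scan import ScanParams, predict_targets
from .normio import (ExpressionMatrix, filter_detected, median_normalize,
                     quantile_normalize, read_expression_table)
from .synthdata import (RNA_CLASSES, SimConfig, TripletSpec, simulate,
                        write_fasta, write_truth)

log = logging.getLogger(__name__)

#: normalization scheme per RNA class (platform convention)
DEFAULT_NORMALIZATION = {"mirna": "median", "lncrna": "quantile", "mrna": "quantile"}

DEFAULT_CONTRASTS = {"elicitation": ("A", "B"), "remission": ("A", "C")}


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    simulate: SimConfig | None = None
    input_tables: dict[str, dict[str, str]] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, DEThresholds] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    cerna_thresholds: CeRNAThresholds = field(default_factory=CeRNAThresholds)
    scan: ScanParams = field(default_factory=ScanParams)
    pcc_min: float = 0.995
    fdr_max: float = 0.05
    normalization: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_NORMALIZATION))
    min_flagged_samples: int = 3
    contrasts: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    use_fdr: bool = False
    gmt: str | None = None

    def validate(self) -> None:
        if self.simulate is None and not self.input_tables:
            raise ValueError("config needs either a [simulate] section or input tables")
        for name, (ref, test) in self.contrasts.items():
            if ref == test:
                raise ValueError(f"contrast {name!r} compares a group with itself")
        for rna_class, method in self.normalization.items():
            if method not in ("quantile", "median", "none"):
                raise ValueError(f"unknown normalization {method!r} for {rna_class}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        base = base_dir or Path.cwd()
        cfg = cls(out_dir=Path(raw.get("out_dir", "run_out")), seed=int(raw.get("seed", 0)))
        if not cfg.out_dir.is_absolute():
            cfg.out_dir = base / cfg.out_dir
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            trip = [TripletSpec(**t) for t in sim.pop("triplet_spec", [])]
            de_spec = {
                c: [tuple(e) for e in entries]
                for c, entries in sim.pop("de_spec", {}).items()
            }
            sim.setdefault("rng_seed", cfg.seed)
            cfg.simulate = SimConfig(de_spec=de_spec, triplet_spec=trip, **sim)
        if "inputs" in raw:
            cfg.input_tables = {c: dict(v) for c, v in raw["inputs"].items()
                                if c in RNA_CLASSES}
            cfg.sequences = dict(raw["inputs"].get("sequences", {}))
        for rna_class, thr in raw.get("thresholds", {}).items():
            cfg.thresholds[rna_class] = DEThresholds(**thr)
        if "cerna" in raw:
            cfg.cerna_thresholds = CeRNAThresholds(**raw["cerna"])
        if "scan" in raw:
            cfg.scan = ScanParams(**raw["scan"])
        cnc = raw.get("cnc", {})
        cfg.pcc_min = float(cnc.get("pcc_min", cfg.pcc_min))
        cfg.fdr_max = float(cnc.get("fdr_max", cfg.fdr_max))
        cfg.normalization.update(raw.get("normalization", {}))
        cfg.min_flagged_samples = int(raw.get("min_flagged_samples", 3))
        if "contrasts" in raw:
            cfg.contrasts = {k: tuple(v) for k, v in raw["contrasts"].items()}
        cfg.use_fdr = bool(raw.get("use_fdr", False))
        cfg.gmt = raw.get("gmt")
        cfg.validate()
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "thresholds": {c: vars(t) for c, t in config.thresholds.items()},
            "scan": vars(config.scan),
            "cnc": {"pcc_min": config.pcc_min, "fdr_max": config.fdr_max},
            "cerna": vars(config.cerna_thresholds),
            "normalization": dict(config.normalization),
            "min_flagged_samples": config.min_flagged_samples,
            "use_fdr": config.use_fdr,
        },
        "inputs": {},
        "counts": {},
    }

    # ---- stage: acquire matrices and sequences -------------------------
    try:
        if config.simulate is not None:
            matrices, seqs, truth = simulate(config.simulate)
            for rna_class, m in matrices.items():
                m.write_tsv(out / f"{rna_class}_raw.tsv",
                            flags_path=out / f"{rna_class}_flags.tsv")
            for rna_class in RNA_CLASSES:
                write_fasta(seqs[rna_class], out / f"{rna_class}.fa")
            write_truth(truth, out / "truth")
            mirna_seqs = seqs["mirna"]
            lnc_seqs = seqs["lncrna"]
            mrna_seqs = seqs["mrna"]
        else:
            matrices = {}
            for rna_class, paths in config.input_tables.items():
                matrices[rna_class] = read_expression_table(
                    paths["values"], paths.get("flags"))
            from .mre_scan import read_fasta_rna

            mirna_seqs = read_fasta_rna(config.sequences["mirna"])
            lnc_seqs = read_fasta_rna(config.sequences["lncrna"])
            mrna_seqs = read_fasta_rna(config.sequences["mrna"])
        for rna_class in RNA_CLASSES:
            path = out / f"{rna_class}_raw.tsv"
            if config.simulate is not None:
                manifest["inputs"][rna_class] = _digest(path)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("ingest", str(exc)) from exc

    # ---- stage: normalization + detection filtering --------------------
    try:
        normed: dict[str, ExpressionMatrix] = {}
        for rna_class, m in matrices.items():
            method = config.normalization.get(rna_class, "none")
            if method == "quantile":
                m = quantile_normalize(m)
            elif method == "median":
                m = median_normalize(m)
            if m.flags is not None:
                m = filter_detected(m, config.min_flagged_samples)
            normed[rna_class] = m
            m.write_tsv(out / f"{rna_class}_normalized.tsv")
            manifest["counts"].setdefault("genes_after_filter", {})[rna_class] = m.n_genes
            log.info("normalize[%s]: %s, %d genes retained", rna_class, method, m.n_genes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalize", str(exc)) from exc

    # ---- stage: differential expression per class per contrast ---------
    de_tables: dict[tuple[str, str], object] = {}
    try:
        for phase, contrast in config.contrasts.items():
            for rna_class, m in normed.items():
                thr = config.thresholds.get(rna_class, DEThresholds())
                table = call_differential(m, contrast, thr, use_fdr=config.use_fdr)
                de_tables[(phase, rna_class)] = table
                table.to_csv(out / f"de_{rna_class}_{phase}.tsv", sep="\t", index=False)
                counts = de_counts(table)
                manifest["counts"].setdefault("de", {}).setdefault(phase, {})[rna_class] = counts
                log.info("de[%s/%s]: %d up, %d down", phase, rna_class,
                         counts["up"], counts["down"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diffexpr", str(exc)) from exc

    # ---- stage: MRE scanning -------------------------------------------
    try:
        mrna_predictions = predict_targets(mirna_seqs, mrna_seqs, config.scan)
        lnc_predictions = predict_targets(mirna_seqs, lnc_seqs, config.scan)
        _write_site_table(out / "sites_mrna.tsv", mrna_predictions)
        _write_site_table(out / "sites_lncrna.tsv", lnc_predictions)
        manifest["counts"]["predictions"] = {
            "mrna_pairs": len(mrna_predictions),
            "mrna_passed": sum(p.passed for p in mrna_predictions),
            "lncrna_pairs": len(lnc_predictions),
            "lncrna_passed": sum(p.passed for p in lnc_predictions),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("scan", str(exc)) from exc

    # ---- stage: CNC -----------------------------------------------------
    try:
        cnc_edges = cnc_network(normed["lncrna"], normed["mrna"],
                                pcc_min=config.pcc_min, fdr_max=config.fdr_max)
        pd.DataFrame(edges_to_records(cnc_edges)).to_csv(
            out / "cnc_edges.tsv", sep="\t", index=False)
        manifest["counts"]["cnc_edges"] = len(cnc_edges)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cnc", str(exc)) from exc

    # ---- stage: networks per phase --------------------------------------
    try:
        manifest["counts"]["networks"] = {}
        for phase in config.contrasts:
            reg = mirna_mrna_network(de_tables[(phase, "mirna")],
                                     de_tables[(phase, "mrna")], mrna_predictions)
            triplets = assemble_cerna_triplets(
                de_tables[(phase, "lncrna")], de_tables[(phase, "mirna")],
                de_tables[(phase, "mrna")], lnc_predictions, mrna_predictions,
                cnc_edges, config.cerna_thresholds, phase=phase)
            export_network(out / f"network_{phase}.graphml", edges=reg, triplets=triplets)
            export_network(out / f"network_{phase}.tsv", edges=reg, triplets=triplets,
                           fmt="tsv")
            triplets_to_frame(triplets).to_csv(out / f"triplets_{phase}.tsv",
                                               sep="\t", index=False)
            manifest["counts"]["networks"][phase] = {
                "regulatory_edges": len(reg),
                "triplets": len(triplets),
            }
            log.info("network[%s]: %d edges, %d triplets", phase, len(reg), len(triplets))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cerna", str(exc)) from exc

    # ---- stage: optional enrichment --------------------------------------
    if config.gmt:
        try:
            sets = read_gmt(config.gmt)
            universe = normed["mrna"].gene_ids
            for phase in config.contrasts:
                table = de_tables[(phase, "mrna")]
                for direction in ("up", "down"):
                    query = table.loc[table["significant"]
                                      & (table["direction"] == direction), "gene_id"]
                    res = hypergeometric_enrichment(query, universe, sets)
                    res.to_csv(out / f"enrichment_mrna_{phase}_{direction}.tsv",
                               sep="\t", index=False)
                    manifest["counts"].setdefault("enrichment", {})[
                        f"{phase}_{direction}"] = int((res["p"] <= 0.05).sum())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrichment", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_site_table(path, predictions) -> None:
    rows = []
    for p in predictions:
        for s in p.sites:
            rows.append({
                "mirna_id": s.mirna_id, "target_id": s.target_id,
                "start": s.start, "end": s.end, "site_type": s.site_type,
                "pair_score": s.pair_score, "energy": s.energy,
                "passed": p.passed,
            })
    pd.DataFrame(rows, columns=["mirna_id", "target_id", "start", "end",
                                "site_type", "pair_score", "energy",
                                "passed"]).to_csv(path, sep="\t", index=False)
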