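"""Planted-truth simulator for the three-class, three-phase expression study.

The generator emulates a small single-channel microarray experiment with a
control group (A), an elicitation group (B) and a remission group (C), few
replicates per group, and three RNA classes measured on separate platforms
(miRNA, lncRNA, mRNA).  Log2 intensities are drawn as

    log2 x[g, s] = baseline[g] + effect[g, group(s)] + coupling[g, s] + noise

and exponentiated, so planted linear fold changes are exact at zero noise.
Sponge triplets are planted with one shared latent Normal factor per
triplet, loaded -k on the miRNA and +k on the lncRNA and mRNA within the
triplet's phase group: this induces the ceRNA sign pattern (miRNA
anti-correlated with both partners, partners positively co-expressed) with
a single coupling parameter.  Matching miRNA response elements are written
into both partner sequences so the scanner and network stages can recover
the planted triples.

Everything is driven by one integer seed; each stage derives its own
deterministic stream, so matrices and sequences are byte-identical across
runs with equal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mre_scan import revcomp
from .normio import ExpressionMatrix

RNA_CLASSES = ("mirna", "lncrna", "mrna")
GROUPS = ("A", "B", "C")

_ID_PREFIX = {"mirna": "miR", "lncrna": "lnc", "mrna": "mRNA"}


def gene_ids(rna_class: str, n: int) -> list[str]:
    """Deterministic gene identifiers for one RNA class."""
    return [f"{_ID_PREFIX[rna_class]}-{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class TripletSpec:
    """One planted sponge triplet.

    ``coupling`` (k) is the loading of the shared latent factor; the three
    log2 effects place the members' differential expression in ``group``
    (miRNA up, partners down by default, the canonical elicitation-phase
    sponge signature).
    """

    lncrna: str
    mirna: str
    mrna: str
    coupling: float = 1.0
    group: str = "B"
    mir_log2fc: float = 2.5
    lnc_log2fc: float = -2.5
    mrna_log2fc: float = -2.5


@dataclass
class SimConfig:
    """Full description of one simulated study.

    ``de_spec`` maps RNA class -> list of (gene_id, group, log2 effect)
    entries relative to the control group; ``triplet_spec`` lists planted
    sponge triplets (whose DE effects are added on top of ``de_spec``).
    """

    n_per_group: int = 4
    n_mirna: int = 30
    n_lncrna: int = 100
    n_mrna: int = 300
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    de_spec: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    triplet_spec: list[TripletSpec] = field(default_factory=list)
    mirna_len_range: tuple[int, int] = (19, 24)
    lncrna_len: int = 400
    utr_len: int = 300
    detection_floor: float = 30.0
    rng_seed: int = 0

    def gene_ids(self, rna_class: str) -> list[str]:
        n = {"mirna": self.n_mirna, "lncrna": self.n_lncrna, "mrna": self.n_mrna}[rna_class]
        return gene_ids(rna_class, n)

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        for attr in ("n_mirna", "n_lncrna", "n_mrna"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.mirna_len_range
        if not (19 <= lo <= hi <= 24):
            raise ValueError("miRNA lengths must lie within 19-24 nt")
        if min(self.lncrna_len, self.utr_len) < 30:
            raise ValueError("transcript lengths must be >= 30 nt")
        known = {c: set(self.gene_ids(c)) for c in RNA_CLASSES}
        for rna_class, entries in self.de_spec.items():
            if rna_class not in known:
                raise ValueError(f"unknown RNA class {rna_class!r} in de_spec")
            for gid, group, _ in entries:
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r} in de_spec")
                if gid not in known[rna_class]:
                    raise ValueError(f"planted gene {gid!r} not in class {rna_class!r}")
        for t in self.triplet_spec:
            if t.group not in GROUPS:
                raise ValueError(f"unknown group {t.group!r} in triplet spec")
            if t.mirna not in known["mirna"]:
                raise ValueError(f"planted miRNA {t.mirna!r} out of range")
            if t.lncrna not in known["lncrna"]:
                raise ValueError(f"planted lncRNA {t.lncrna!r} out of range")
            if t.mrna not in known["mrna"]:
                raise ValueError(f"planted mRNA {t.mrna!r} out of range")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated data.

    ``de_truth``: class -> group -> gene -> (direction, log2FC);
    ``site_truth``: (mirna_id, transcript_id) -> (start, end), 0-based
    half-open coordinates of the planted 8mer;
    ``triplet_truth``: planted (lncRNA, miRNA, mRNA) triples.
    """

    de_truth: dict[str, dict[str, dict[str, tuple[str, float]]]] = field(default_factory=dict)
    site_truth: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    triplet_truth: list[tuple[str, str, str]] = field(default_factory=list)


def _collect_effects(config: SimConfig) -> dict[str, dict[str, dict[str, float]]]:
    """class -> gene -> group -> summed log2 effect."""
    eff: dict[str, dict[str, dict[str, float]]] = {c: {} for c in RNA_CLASSES}
    for rna_class, entries in config.de_spec.items():
        for gid, group, lfc in entries:
            eff[rna_class].setdefault(gid, {}).setdefault(group, 0.0)
            eff[rna_class][gid][group] += lfc
    for t in config.triplet_spec:
        for rna_class, gid, lfc in (
            ("mirna", t.mirna, t.mir_log2fc),
            ("lncrna", t.lncrna, t.lnc_log2fc),
            ("mrna", t.mrna, t.mrna_log2fc),
        ):
            eff[rna_class].setdefault(gid, {}).setdefault(t.group, 0.0)
            eff[rna_class][gid][t.group] += lfc
    return eff


def simulate_expression(config: SimConfig) -> tuple[dict[str, ExpressionMatrix], SimTruth]:
    """Generate the three class matrices and the ground-truth tables."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 0])
    n = config.n_per_group
    sample_ids = [f"{g}{i}" for g in GROUPS for i in range(1, n + 1)]
    group_of = pd.Series([s[0] for s in sample_ids], index=sample_ids)
    effects = _collect_effects(config)

    log2_by_class: dict[str, np.ndarray] = {}
    ids_by_class: dict[str, list[str]] = {}
    for rna_class in RNA_CLASSES:
        ids = config.gene_ids(rna_class)
        ids_by_class[rna_class] = ids
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(ids))
        log2 = np.tile(baseline[:, None], (1, len(sample_ids)))
        index = {gid: i for i, gid in enumerate(ids)}
        for gid, per_group in effects[rna_class].items():
            for group, lfc in per_group.items():
                cols = [j for j, s in enumerate(sample_ids) if s[0] == group]
                log2[index[gid], cols] += lfc
        log2_by_class[rna_class] = log2

    # shared latent factor per triplet, confined to the triplet's phase group
    for t in config.triplet_spec:
        cols = [j for j, s in enumerate(sample_ids) if s[0] == t.group]
        z = rng.normal(0.0, 1.0, size=len(cols))
        for rna_class, gid, loading in (
            ("mirna", t.mirna, -t.coupling),
            ("lncrna", t.lncrna, +t.coupling),
            ("mrna", t.mrna, +t.coupling),
        ):
            row = ids_by_class[rna_class].index(gid)
            log2_by_class[rna_class][row, cols] += loading * z

    matrices: dict[str, ExpressionMatrix] = {}
    for rna_class in RNA_CLASSES:
        log2 = log2_by_class[rna_class]
        if config.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)
        values = pd.DataFrame(np.exp2(log2), index=ids_by_class[rna_class],
                              columns=sample_ids)
        flags = pd.DataFrame(
            np.where(values.to_numpy() >= config.detection_floor, "P", "A"),
            index=values.index, columns=values.columns,
        )
        matrices[rna_class] = ExpressionMatrix(values, group_of.copy(), flags)

    truth = SimTruth()
    for rna_class in RNA_CLASSES:
        per_class: dict[str, dict[str, tuple[str, float]]] = {}
        for gid, per_group in effects[rna_class].items():
            for group, lfc in per_group.items():
                if lfc == 0.0:
                    continue
                direction = "up" if lfc > 0 else "down"
                per_class.setdefault(group, {})[gid] = (direction, lfc)
        truth.de_truth[rna_class] = per_class
    truth.triplet_truth = [(t.lncrna, t.mirna, t.mrna) for t in config.triplet_spec]
    return matrices, truth


# ------------------------------------------------------------------ sequences

def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def plant_8mer(sequence: str, mirna_seq: str, offset: int) -> tuple[str, tuple[int, int]]:
    """Overwrite an exact 8mer site at ``offset``; returns (sequence, span).

    The written substring is the reverse complement of miRNA positions 2-8
    followed by a 3' A (the base facing miRNA position 1).
    """
    site = revcomp(mirna_seq[1:8]) + "A"
    if offset < 0 or offset + len(site) > len(sequence):
        raise ValueError(f"8mer at offset {offset} does not fit a "
                         f"{len(sequence)}-nt sequence")
    new = sequence[:offset] + site + sequence[offset + len(site):]
    return new, (offset, offset + len(site))


def plant_full_site(sequence: str, mirna_seq: str, region_start: int) -> tuple[str, tuple[int, int]]:
    """Plant an 8mer with full 3'-supplementary complementarity.

    Writes the reverse complement of miRNA positions 2..L followed by a 3'
    A (one region of length L); the terminal 8 nt form the canonical 8mer
    whose span is returned.  The extended pairing gives the site a duplex
    alignment score of at least 5*(L-1), so planted sites clear the default
    intersection thresholds of the scanner.
    """
    region = revcomp(mirna_seq[1:]) + "A"
    if region_start < 0 or region_start + len(region) > len(sequence):
        raise ValueError(f"planted site of length {len(region)} at {region_start} "
                         f"does not fit a {len(sequence)}-nt sequence")
    new = sequence[:region_start] + region + sequence[region_start + len(region):]
    end = region_start + len(region)
    return new, (end - 8, end)


def simulate_sequences(
    config: SimConfig, truth: SimTruth
) -> tuple[dict[str, dict[str, str]], SimTruth]:
    """Random RNA sequences with planted MREs for every sponge triplet.

    miRNA lengths are uniform over ``mirna_len_range``; lncRNAs and mRNA
    3'UTRs have fixed lengths.  For each planted triplet, a fully
    complementary 8mer site of its miRNA is written into both the lncRNA
    and the mRNA 3'UTR at deterministic random offsets; the recorded
    ``site_truth`` spans point at the 8mer.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 1])
    lo, hi = config.mirna_len_range
    seqs: dict[str, dict[str, str]] = {
        "mirna": {gid: random_rna(rng, int(rng.integers(lo, hi + 1)))
                  for gid in config.gene_ids("mirna")},
        "lncrna": {gid: random_rna(rng, config.lncrna_len)
                   for gid in config.gene_ids("lncrna")},
        "mrna": {gid: random_rna(rng, config.utr_len)
                 for gid in config.gene_ids("mrna")},
    }
    occupied: dict[str, list[tuple[int, int]]] = {}
    for t in config.triplet_spec:
        mseq = seqs["mirna"][t.mirna]
        for rna_class, tid in (("lncrna", t.lncrna), ("mrna", t.mrna)):
            host = seqs[rna_class][tid]
            if len(mseq) > len(host):
                raise ValueError(f"planted site longer than host sequence {tid!r}")
            span = None
            for _ in range(100):
                start = int(rng.integers(0, len(host) - len(mseq) + 1))
                cand = (start, start + len(mseq))
                if all(cand[1] <= a or cand[0] >= b for a, b in occupied.get(tid, [])):
                    span = cand
                    break
            if span is None:
                raise ValueError(f"could not place a site in {tid!r} without overlap")
            host, site_span = plant_full_site(host, mseq, span[0])
            seqs[rna_class][tid] = host
            occupied.setdefault(tid, []).append(span)
            truth.site_truth[(t.mirna, tid)] = site_span
    return seqs, truth


def simulate(config: SimConfig):
    """Run both simulation stages; returns (matrices, sequences, truth)."""
    matrices, truth = simulate_expression(config)
    seqs, truth = simulate_sequences(config, truth)
    return matrices, seqs, truth


def make_study_config(
    n_per_group: int = 4,
    n_mirna: int = 30,
    n_lncrna: int = 100,
    n_mrna: int = 300,
    n_triplets: int = 10,
    coupling: float = 0.5,
    noise_sd: float = 0.25,
    de_frac_elicitation: float = 0.15,
    de_frac_remission: float = 0.02,
    effect_log2: float = 2.5,
    seed: int = 0,
) -> SimConfig:
    """Convenience builder mirroring the study design.

    Triplets occupy the first ``n_triplets`` genes of each class (distinct
    miRNAs).  Background differential expression is planted on the
    following genes: a large fraction in the elicitation phase (B) and a
    sparse fraction in remission (C), alternating up/down, emulating the
    massive-elicitation / sparse-remission asymmetry of the study design.
    """
    if n_triplets > min(n_mirna, n_lncrna, n_mrna):
        raise ValueError("more triplets than genes in some class")
    mir_ids = gene_ids("mirna", n_mirna)
    lnc_ids = gene_ids("lncrna", n_lncrna)
    mrna_ids = gene_ids("mrna", n_mrna)
    triplets = [
        TripletSpec(lncrna=lnc_ids[i], mirna=mir_ids[i], mrna=mrna_ids[i],
                    coupling=coupling)
        for i in range(n_triplets)
    ]
    de_spec: dict[str, list[tuple[str, str, float]]] = {c: [] for c in RNA_CLASSES}
    for rna_class, ids in (("mirna", mir_ids), ("lncrna", lnc_ids), ("mrna", mrna_ids)):
        free = ids[n_triplets:]
        n_b = int(round(de_frac_elicitation * len(ids)))
        n_c = int(round(de_frac_remission * len(ids)))
        for k, gid in enumerate(free[:n_b]):
            sign = 1.0 if k % 2 == 0 else -1.0
            de_spec[rna_class].append((gid, "B", sign * effect_log2))
        for k, gid in enumerate(free[n_b:n_b + n_c]):
            sign = 1.0 if k % 2 == 0 else -1.0
            de_spec[rna_class].append((gid, "C", sign * effect_log2))
    return SimConfig(
        n_per_group=n_per_group, n_mirna=n_mirna, n_lncrna=n_lncrna,
        n_mrna=n_mrna, noise_sd=noise_sd, de_spec=de_spec,
        triplet_spec=triplets, rng_seed=seed,
    )


# ----------------------------------------------------------------------- I/O

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth(truth: SimTruth, out_dir) -> None:
    """Write de_truth.tsv, site_truth.tsv and triplet_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    de_rows = [
        {"rna_class": c, "group": g, "gene_id": gid, "direction": d, "log2fc": lfc}
        for c, per_class in truth.de_truth.items()
        for g, per_group in per_class.items()
        for gid, (d, lfc) in sorted(per_group.items())
    ]
    pd.DataFrame(de_rows, columns=["rna_class", "group", "gene_id", "direction",
                                   "log2fc"]).to_csv(out / "de_truth.tsv", sep="\t",
                                                     index=False)
    site_rows = [
        {"mirna_id": m, "target_id": t, "start": s, "end": e}
        for (m, t), (s, e) in sorted(truth.site_truth.items())
    ]
    pd.DataFrame(site_rows, columns=["mirna_id", "target_id", "start", "end"]).to_csv(
        out / "site_truth.tsv", sep="\t", index=False)
    pd.DataFrame(truth.triplet_truth,
                 columns=["lncrna_id", "mirna_id", "mrna_id"]).to_csv(
        out / "triplet_truth.tsv", sep="\t", index=False)
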