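"""Bespoke miRNA response element (MRE) prediction.

A target site is anchored by complementarity to the miRNA *seed*
(nucleotides 2-7 from the miRNA 5' end).  Each anchor is classified into the
canonical site taxonomy:

* ``8mer``     seed match + match to miRNA position 8 + an A opposite position 1
* ``7mer-m8``  seed match + match to position 8
* ``7mer-A1``  seed match + an A opposite position 1
* ``6mer``     seed match only

On top of the seed anchor, a miRanda-style local duplex alignment between
the whole miRNA (3'->5') and the target window upstream of the site scores
overall complementarity (Watson-Crick +5, G:U wobble +2, mismatch -3, linear
gap -8), and a per-base-pair additive proxy scores duplex stability
(G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol).  A prediction *passes* when a
single site satisfies the seed criterion and both score thresholds — the
intersection-of-methods rule used when combining seed-based and
alignment-based predictors.

Coordinates are 0-based half-open on the given transcript, 5'->3'.  Input
sequences may use T or U; they are handled as single-stranded RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_RANK = {t: r for r, t in enumerate(reversed(SITE_TYPES))}

#: duplex-stability proxy per closed base pair, kcal/mol
PAIR_ENERGY = {
    frozenset({"G", "C"}): -3.0,
    frozenset({"A", "U"}): -2.0,
    frozenset({"G", "U"}): -1.0,
}


def normalize_rna(seq: str, what: str = "sequence") -> str:
    """Upper-case, map T->U, and validate the RNA alphabet."""
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC_PAIRS


def pairs_with(a: str, b: str) -> bool:
    """True for Watson-Crick or G:U wobble pairing."""
    return (a, b) in _WC_PAIRS or (a, b) in _WOBBLE_PAIRS


@dataclass
class SeedSite:
    """A predicted MRE on a target transcript.

    ``start``/``end`` delimit the classified site span (0-based half-open,
    target 5'->3'); ``pair_score`` and ``energy`` are filled in once the
    duplex alignment has been run.
    """

    mirna_id: str
    target_id: str
    start: int
    end: int
    site_type: str
    pair_score: float | None = None
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.site_type not in _SITE_RANK:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} span must have length {expected}, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TargetPrediction:
    """All sites of one (miRNA, transcript) pair plus the pass/fail verdict."""

    mirna_id: str
    target_id: str
    sites: list[SeedSite] = field(default_factory=list)
    best_pair_score: float | None = None
    best_energy: float | None = None
    passed: bool = False


@dataclass(frozen=True)
class ScanParams:
    """Thresholds of the intersection rule plus the alignment window length."""

    s_min: float = 80.0
    e_max: float = -14.0
    window: int = 30


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap: float = -8.0


DEFAULT_SCORING = AlignmentScoring()


def find_seed_sites(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "",
    target_id: str = "",
) -> list[SeedSite]:
    """All seed-anchored sites of a miRNA on a target, best type per anchor.

    Scans every target window for the reverse complement of miRNA positions
    2-7 (the 6mer core), then upgrades the anchor by a Watson-Crick match to
    position 8 (m8, one base 5' on the target) and/or an A opposite position
    1 (one base 3' on the target).  Anchors at distinct positions are all
    reported; within one anchor only the highest-ranking type is kept
    (8mer > 7mer-m8 > 7mer-A1 > 6mer).  Sites are returned 5'->3' by span
    start; scores are left unset.
    """
    m = normalize_rna(mirna_seq, "miRNA")
    t = normalize_rna(target_seq, "target")
    if len(m) < 8:
        raise ValueError(f"miRNA must be >= 8 nt, got {len(m)}")
    if len(t) < 6:
        return []
    core = revcomp(m[1:7])  # matches the target 5'->3'
    pos8 = m[7]
    sites: list[SeedSite] = []
    for s in range(len(t) - 5):
        if t[s:s + 6] != core:
            continue
        has_m8 = s > 0 and is_wc(t[s - 1], pos8)
        has_a1 = s + 6 < len(t) and t[s + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna_id, target_id, s - 1, s + 7, "8mer")
        elif has_m8:
            site = SeedSite(mirna_id, target_id, s - 1, s + 6, "7mer-m8")
        elif has_a1:
            site = SeedSite(mirna_id, target_id, s, s + 7, "7mer-A1")
        else:
            site = SeedSite(mirna_id, target_id, s, s + 6, "6mer")
        sites.append(site)
    sites.sort(key=lambda x: (x.start, -_SITE_RANK[x.site_type]))
    return sites


@dataclass
class DuplexAlignment:
    """Best local alignment of a miRNA against a target window."""

    score: float
    #: closed base pairs (mirna_base, target_base) of the best alignment,
    #: miRNA 3'->5' order; mismatched aligned positions are excluded
    pairs: list[tuple[str, str]]


def align_duplex(
    mirna_seq: str,
    target_window: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> DuplexAlignment:
    """Smith-Waterman local alignment of miRNA (3'->5') vs target (5'->3').

    Antiparallel hybridization geometry: the miRNA is reversed so that its
    3' end faces the window's 5' end.  Linear gap penalty; score floored at
    0.  Traceback is deterministic (earliest maximal cell; diagonal over
    vertical over horizontal moves).
    """
    q = normalize_rna(mirna_seq, "miRNA")[::-1]  # 3'->5'
    t = normalize_rna(target_window, "target window")
    nq, nt = len(q), len(t)
    H = np.zeros((nq + 1, nt + 1))
    for i in range(1, nq + 1):
        qi = q[i - 1]
        for j in range(1, nt + 1):
            tj = t[j - 1]
            if (qi, tj) in _WC_PAIRS:
                s = scoring.match
            elif (qi, tj) in _WOBBLE_PAIRS:
                s = scoring.wobble
            else:
                s = scoring.mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + scoring.gap,
                          H[i, j - 1] + scoring.gap)
    best = float(H.max())
    if best == 0.0:
        return DuplexAlignment(0.0, [])
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    pairs_rev: list[tuple[str, str]] = []
    while H[i, j] > 0:
        qi, tj = q[i - 1], t[j - 1]
        if (qi, tj) in _WC_PAIRS:
            s = scoring.match
        elif (qi, tj) in _WOBBLE_PAIRS:
            s = scoring.wobble
        else:
            s = scoring.mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            if pairs_with(qi, tj):
                pairs_rev.append((qi, tj))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + scoring.gap:
            i -= 1
        else:
            j -= 1
    return DuplexAlignment(best, pairs_rev[::-1])


def duplex_energy(paired_positions) -> float:
    """Additive duplex-stability proxy over closed base pairs (kcal/mol).

    G:C contributes -3.0, A:U -2.0, G:U -1.0; anything else is rejected.
    An empty pair list scores 0.
    """
    total = 0.0
    for a, b in paired_positions:
        key = frozenset({a, b})
        if key not in PAIR_ENERGY:
            raise ValueError(f"invalid base pair {a}:{b}")
        total += PAIR_ENERGY[key]
    return total


def _site_window(target: str, site: SeedSite, window: int) -> str:
    """Window of ``window`` nt ending at the site's 3' edge (clipped at 0)."""
    return target[max(0, site.end - window):site.end]


def pair_score(
    mirna_seq: str,
    target_seq: str,
    site: SeedSite,
    window: int = 30,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> float:
    """Local-alignment complementarity score of the miRNA over a site window."""
    m = normalize_rna(mirna_seq, "miRNA")
    t = normalize_rna(target_seq, "target")
    if not (0 <= site.start < site.end <= len(t)):
        raise ValueError(f"site span {site.span} outside target of length {len(t)}")
    if window < 6:
        raise ValueError("window must cover at least the seed region (>= 6 nt)")
    return align_duplex(m, _site_window(t, site, window), scoring).score


def score_site(
    mirna_seq: str,
    target_seq: str,
    site: SeedSite,
    window: int = 30,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> SeedSite:
    """Return a copy of ``site`` with pair_score and energy filled in."""
    t = normalize_rna(target_seq, "target")
    aln = align_duplex(mirna_seq, _site_window(t, site, window), scoring)
    return replace(site, pair_score=aln.score, energy=duplex_energy(aln.pairs))


def read_fasta_rna(path) -> dict[str, str]:
    """Read a FASTA file into an id -> RNA-sequence mapping (T mapped to U)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = normalize_rna(rec.seq, rec.id)
    return seqs


def predict_targets(
    mirnas: dict[str, str] | str | Path,
    transcripts: dict[str, str] | str | Path,
    params: ScanParams = ScanParams(),
) -> list[TargetPrediction]:
    """Scan every (miRNA, transcript) pair; emit predictions with >= 1 site.

    A prediction passes when a single site both anchors a seed match and
    clears the alignment thresholds: pair_score >= s_min and
    energy <= e_max.
    """
    mir = read_fasta_rna(mirnas) if not isinstance(mirnas, dict) else {
        k: normalize_rna(v, k) for k, v in mirnas.items()}
    tx = read_fasta_rna(transcripts) if not isinstance(transcripts, dict) else {
        k: normalize_rna(v, k) for k, v in transcripts.items()}
    if not mir or not tx:
        raise ValueError("both miRNA and transcript inputs must be non-empty")
    clash = set(mir) & set(tx)
    if clash:
        raise ValueError(f"id collision between miRNA and transcript files: {sorted(clash)[:5]}")
    out: list[TargetPrediction] = []
    for mid, mseq in mir.items():
        for tid, tseq in tx.items():
            sites = find_seed_sites(mseq, tseq, mid, tid)
            if not sites:
                continue
            scored = [score_site(mseq, tseq, s, params.window) for s in sites]
            passed = any(
                s.pair_score >= params.s_min and s.energy <= params.e_max for s in scored
            )
            out.append(TargetPrediction(
                mirna_id=mid, target_id=tid, sites=scored,
                best_pair_score=max(s.pair_score for s in scored),
                best_energy=min(s.energy for s in scored),
                passed=passed,
            ))
    return out
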