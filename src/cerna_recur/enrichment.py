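"""Gene-set over-representation analysis (GO/KEGG-style term lists).

The statistic is the upper-tail hypergeometric probability
P(X >= k) with population size |universe|, |set ∩ universe| successes,
|query| draws and k = |query ∩ set| observed, BH-adjusted across terms.
Term collections are supplied as GMT files; no ontology graph propagation
is performed — the caller decides what the background universe is (by
default, all genes surviving detection filtering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DOMAINS = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    domain: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


def read_gmt(path, default_domain: str = "pathway") -> list[GeneSet]:
    """Parse a GMT file (term, description, member genes, tab-separated).

    If the description field equals one of BP/CC/MF/pathway it is taken as
    the term's domain; otherwise ``default_domain`` applies and the
    description becomes the term name.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term_id, desc = parts[0], parts[1]
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id!r}")
            seen.add(term_id)
            domain = desc if desc in DOMAINS else default_domain
            name = term_id if desc in DOMAINS else desc
            members = frozenset(g for g in parts[2:] if g)
            sets.append(GeneSet(term_id, name, domain, members))
    return sets


def hypergeometric_enrichment(
    query,
    universe,
    sets: list[GeneSet],
    p_max: float | None = None,
) -> pd.DataFrame:
    """Per-term over-representation table, ordered by (p, term_id).

    Columns: term_id, name, domain, set_size, overlap, p, q, score where
    score = -log10(p).  Terms with no member in the universe are dropped.
    ``p_max`` (e.g. 0.05) optionally filters the output after q is computed
    over all tested terms.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(query)
    rows = []
    for gs in sets:
        members = gs.members & universe
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append({
            "term_id": gs.term_id, "name": gs.term_name, "domain": gs.domain,
            "set_size": K, "overlap": k, "p": min(p, 1.0),
        })
    table = pd.DataFrame(rows, columns=["term_id", "name", "domain",
                                        "set_size", "overlap", "p"])
    if len(table):
        from .diffexpr import bh_fdr

        table["q"] = bh_fdr(table["p"].to_numpy())
        with np.errstate(divide="ignore"):
            table["score"] = -np.log10(table["p"])
        table = table.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
        if p_max is not None:
            table = table[table["p"] <= p_max].reset_index(drop=True)
    else:
        table["q"] = []
        table["score"] = []
    return table
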