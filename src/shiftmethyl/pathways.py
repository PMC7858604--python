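"""Gene-set enrichment and pathway-level DMP scoring.

Gene ranking takes the best (smallest) probe p-value per gene from an EWAS
result table; over-representation of a ranked gene list in a GMT library is
tested with the hypergeometric upper tail against a methylation-aware
background (by default, every gene with at least one tested probe).  Pathway
DMP scores follow the two-percentage convention:

* enrichment score = 100 x n_DMPs / n_pathway_CpGs,
* hypomethylation score = 100 x n_hypo_DMPs / n_DMPs (undefined without DMPs),

reported to one decimal (half-up) for table-style output and as rounded
integer percents for prose-style summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .ewas import HYPO_AT_WORK, bh_adjust

logger = logging.getLogger(__name__)

_EPS = 1e-9


def normalize_symbol(symbol: str) -> str:
    """Case/whitespace normalization for gene symbols (no alias resolution)."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSetLibrary:
    """A named collection of gene sets (GMT semantics)."""

    sets: Mapping
    descriptions: Mapping = field(default_factory=dict)

    @classmethod
    def from_dict(cls, sets: Mapping, descriptions: Mapping | None = None) -> "GeneSetLibrary":
        clean = {}
        for term, genes in sets.items():
            genes = tuple(dict.fromkeys(normalize_symbol(g) for g in genes))
            if not genes:
                raise ContractError(f"gene set {term!r} is empty")
            clean[str(term)] = genes
        return cls(sets=clean, descriptions=dict(descriptions or {}))

    @property
    def terms(self) -> tuple:
        return tuple(self.sets)

    def genes(self, term: str) -> frozenset:
        if term not in self.sets:
            raise KeyError(f"unknown gene-set term {term!r}")
        return frozenset(self.sets[term])

    def all_genes(self) -> frozenset:
        return frozenset(g for genes in self.sets.values() for g in genes)

    def __contains__(self, term) -> bool:
        return term in self.sets

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# annotation helpers
# ---------------------------------------------------------------------------

def probe_gene_map(annotation: pd.DataFrame) -> dict:
    """probe_id -> tuple of normalized gene symbols (may be empty)."""
    out = {}
    for pid, symbols in zip(annotation["probe_id"], annotation["gene_symbols"]):
        if pd.isna(symbols):
            out[str(pid)] = ()
            continue
        out[str(pid)] = tuple(
            normalize_symbol(s) for s in str(symbols).split(";") if s.strip()
        )
    return out


def gene_probe_map(annotation: pd.DataFrame) -> dict:
    """gene symbol -> set of probe ids annotated to it."""
    out: dict = {}
    for pid, genes in probe_gene_map(annotation).items():
        for g in genes:
            out.setdefault(g, set()).add(pid)
    return out


# ---------------------------------------------------------------------------
# gene ranking and over-representation
# ---------------------------------------------------------------------------

def rank_top_genes(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    group: str = "swd",
    n_top: int | None = 30,
    p_cut: float = 1e-5,
) -> list:
    """Rank genes by their best probe p-value in the chosen hypothesis.

    Each gene is scored by the minimum p among its probes present in the
    EWAS table (genes deduplicated by that best probe), filtered to
    ``p < p_cut``, ordered by ascending p with lexicographic tie-break, and
    truncated to ``n_top`` (``None`` keeps all).
    """
    p_col = f"p_{group}"
    if p_col not in table.columns:
        raise ContractError(f"result table lacks column {p_col!r}")
    pvals = table[p_col]
    best: dict = {}
    for pid, genes in probe_gene_map(annotation).items():
        if pid not in pvals.index or not genes:
            continue
        p = float(pvals.loc[pid])
        for g in genes:
            if g not in best or p < best[g]:
                best[g] = p
    ranked = sorted((p, g) for g, p in best.items() if p < p_cut)
    if not ranked:
        logger.warning("no gene passes p < %g for hypothesis %r", p_cut, group)
        return []
    if n_top is not None:
        ranked = ranked[:n_top]
    return [g for _, g in ranked]


def background_genes(table: pd.DataFrame, annotation: pd.DataFrame) -> frozenset:
    """All genes with at least one tested probe — the default universe."""
    tested = set(map(str, table.index))
    return frozenset(
        g for pid, genes in probe_gene_map(annotation).items() if pid in tested
        for g in genes
    )


def enrich_terms(
    gene_list: Sequence[str],
    library: GeneSetLibrary,
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list per term.

    Returns a DataFrame sorted by p with columns
    ``term, n_term_genes, overlap, overlap_genes, p, q``; q-values are BH
    across terms.  Term gene sets are intersected with the background before
    testing.
    """
    bg = frozenset(normalize_symbol(g) for g in background)
    if not bg:
        raise ContractError("background gene universe is empty")
    query = tuple(dict.fromkeys(normalize_symbol(g) for g in gene_list))
    stray = sorted(set(query) - bg)
    if stray:
        raise ContractError(f"query genes missing from background: {stray}")
    M, n = len(bg), len(query)
    rows = []
    for term in library.terms:
        term_genes = library.genes(term) & bg
        K = len(term_genes)
        overlap = sorted(term_genes & set(query))
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({
            "term": term,
            "n_term_genes": K,
            "overlap": k,
            "overlap_genes": ";".join(overlap),
            "p": min(p, 1.0),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# pathway CpG universes and scores
# ---------------------------------------------------------------------------

def pathway_cpg_universe(
    term: str,
    library: GeneSetLibrary,
    annotation: pd.DataFrame,
) -> frozenset:
    """All probes annotated to any member gene of a term (deduplicated)."""
    member_genes = library.genes(term)  # KeyError for unknown terms
    by_gene = gene_probe_map(annotation)
    universe: set = set()
    for g in member_genes:
        universe |= by_gene.get(g, set())
    return frozenset(universe)


def score_one_decimal(numerator: float, denominator: float):
    """Percentage rounded half-up to one decimal; ``None`` for 0 denominator."""
    if denominator == 0:
        return None
    return math.floor(1000.0 * numerator / denominator + 0.5 + _EPS) / 10.0


def score_integer(numerator: float, denominator: float):
    """Percentage rounded half-up to an integer; ``None`` for 0 denominator."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5 + _EPS))


def enrichment_score(n_dmps: int, n_cpgs: int):
    """Table-style DMP enrichment score: 100 x n_dmps / n_cpgs, one decimal."""
    return score_one_decimal(n_dmps, n_cpgs)


def hypomethylation_score(n_hypo_dmps: int, n_dmps: int):
    """Table-style hypomethylation score: 100 x n_hypo / n_dmps, one decimal.

    Undefined (``None``) when there are no DMPs.
    """
    return score_one_decimal(n_hypo_dmps, n_dmps)


def pathway_scores(
    term: str,
    library: GeneSetLibrary,
    annotation: pd.DataFrame,
    table: pd.DataFrame,
    group: str = "swd",
    alpha: float = 0.05,
) -> dict:
    """DMP enrichment and hypomethylation scores of one pathway in one group.

    A DMP is a universe probe with the group's unadjusted p below ``alpha``;
    hypomethylation follows the direction label.  Probes of the universe not
    present in the EWAS table contribute to ``n_cpgs`` but cannot be DMPs.
    """
    universe = pathway_cpg_universe(term, library, annotation)
    if not universe:
        raise ContractError(f"pathway {term!r} has an empty CpG universe")
    suffix = "swd" if group == "swd" else "ctrl" if group in ("ctrl", "control") else None
    if suffix is None:
        raise ContractError(f"unknown group {group!r}")
    present = table.loc[table.index.intersection(universe)]
    dmp = present[f"p_{suffix}"] < alpha
    hypo = present[f"direction_{suffix}"] == HYPO_AT_WORK
    n_cpgs = len(universe)
    n_dmps = int(dmp.sum())
    n_hypo = int((dmp & hypo).sum())
    return {
        "term": term,
        "group": "swd" if suffix == "swd" else "control",
        "n_cpgs": n_cpgs,
        "n_genes": len(library.genes(term)),
        "n_dmps": n_dmps,
        "enrichment_pct": enrichment_score(n_dmps, n_cpgs),
        "enrichment_pct_int": score_integer(n_dmps, n_cpgs),
        "n_hypo_dmps": n_hypo,
        "hypo_pct": hypomethylation_score(n_hypo, n_dmps),
        "hypo_pct_int": score_integer(n_hypo, n_dmps),
    }


def pathway_score_table(
    library: GeneSetLibrary,
    annotation: pd.DataFrame,
    table: pd.DataFrame,
    groups: Sequence[str] = ("swd", "control"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every term of a library for each group (long format)."""
    rows = []
    for term in library.terms:
        for group in groups:
            rows.append(pathway_scores(term, library, annotation, table, group, alpha))
    return pd.DataFrame(rows)


def volcano_points(
    table: pd.DataFrame,
    universe: Iterable[str],
    group: str = "swd",
) -> pd.DataFrame:
    """Effect size vs -log10 p triples for the probes of one pathway."""
    universe = [str(u) for u in universe]
    missing = sorted(set(universe) - set(map(str, table.index)))
    if missing:
        raise ContractError(f"universe probes absent from result table: {missing[:5]}")
    suffix = "swd" if group == "swd" else "ctrl"
    sub = table.loc[universe]
    return pd.DataFrame({
        "probe_id": universe,
        "effect": sub[f"beta_vacation_{suffix}"].to_numpy(),
        "neglog10_p": -np.log10(sub[f"p_{suffix}"].to_numpy()),
        "dmp": sub[f"dmp_{suffix}"].to_numpy(),
    })
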