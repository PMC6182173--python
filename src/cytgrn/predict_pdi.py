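"""Prediction of novel TF-cytokine interactions.

For each TF with at least two known targets, candidate cytokines are the
members of the cytokine universe ranked among the top 100 genes
co-expressed with the TF's known targets.  Candidates are retained when
the TF's motif occurs at least once in the candidate's 2 kb promoter
(log-odds threshold 10) and tiered by motif-site count and presence of the
orthologous interaction in the mouse network:

* high   -- >= 2 binding sites and present in mouse
* medium -- >= 2 sites without mouse evidence, or exactly 1 site with it
* low    -- exactly 1 site and absent from mouse
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .grn_model import CytokineGRN
from .motif_scan import DEFAULT_THRESHOLD, PWM, count_sites

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 100


@dataclass
class PredictionRecord:
    tf_symbol: str
    cytokine_symbol: str
    coexpr_rank: int
    n_sites: int
    in_mouse: bool
    confidence: str


class CoexpressionProvider(Protocol):
    """Query gene set -> ranked gene list (best first), deterministic."""

    def rank(self, query_genes: set[str]) -> list[str]: ...


class CorrelationProvider:
    """Rank genes by mean Pearson correlation to a query set.

    Correlations of each candidate to each query gene across the supplied
    expression compendium (genes x samples) are Fisher-z averaged; query
    genes are excluded from the output, ties broken by symbol.  With
    ``aggregate="rank"``, per-query-gene rank lists are averaged instead of
    correlations (mean-rank aggregation).
    """

    def __init__(self, compendium: pd.DataFrame, aggregate: str = "correlation"):
        if aggregate not in {"correlation", "rank"}:
            raise ValueError("aggregate must be 'correlation' or 'rank'")
        self.aggregate = aggregate
        X = compendium.astype(float)
        centered = X.sub(X.mean(axis=1), axis=0)
        norms = np.sqrt((centered ** 2).sum(axis=1))
        self._flat = norms == 0
        norms = norms.replace(0, 1.0)
        self._Z = centered.div(norms, axis=0)  # unit-norm rows
        self.genes = list(X.index)

    def _correlations(self, query: str) -> pd.Series:
        r = self._Z @ self._Z.loc[query]
        r[self._flat | self._flat[query]] = 0.0
        return r.clip(-0.999999, 0.999999)

    def rank(self, query_genes: set[str]) -> list[str]:
        query = sorted(q for q in query_genes if q in self._Z.index)
        if not query:
            raise ValueError("no query gene present in the compendium")
        if self.aggregate == "correlation":
            zsum = sum(np.arctanh(self._correlations(q)) for q in query)
            score = np.tanh(zsum / len(query))
            ordered = score.sort_index().sort_values(ascending=False, kind="stable")
        else:
            ranks = sum(
                (-self._correlations(q)).sort_index().rank(method="average")
                for q in query) / len(query)
            ordered = ranks.sort_index().sort_values(kind="stable")
        return [g for g in ordered.index if g not in query_genes]


def rank_coexpressed(provider: CoexpressionProvider,
                     known_targets: set[str],
                     top_n: int = DEFAULT_TOP_N) -> list[str]:
    """Top ``top_n`` genes co-expressed with a TF's known targets."""
    if len(known_targets) < 2:
        raise ValueError("need at least two known targets to query")
    ranked = provider.rank(set(known_targets))
    if len(ranked) < top_n:
        logger.warning("provider returned only %d genes (top_n=%d)",
                       len(ranked), top_n)
    return ranked[:top_n]


def confidence_tier(n_sites: int, in_mouse: bool) -> str:
    """Total, exclusive tier rule for retained predictions (n_sites >= 1)."""
    if n_sites < 1:
        raise ValueError("retained predictions require n_sites >= 1")
    if n_sites >= 2:
        return "high" if in_mouse else "medium"
    return "medium" if in_mouse else "low"


def predict(grn_human: CytokineGRN,
            grn_mouse: CytokineGRN,
            provider: CoexpressionProvider,
            pwms: Mapping[str, PWM],
            promoters: Mapping[str, str],
            cytokine_universe: set[str],
            threshold: float = DEFAULT_THRESHOLD,
            top_n: int = DEFAULT_TOP_N,
            ortholog_map: Mapping[str, str] | None = None,
            ) -> list[PredictionRecord]:
    """Run the full prediction pipeline over every eligible TF.

    TFs need >= 2 known human targets and an available PWM (others are
    skipped and logged).  Candidates already interacting with the TF in
    human are excluded; retained candidates need >= 1 motif site.
    """
    omap = {k.upper(): v.upper() for k, v in (ortholog_map or {}).items()}

    def translate(sym: str) -> str:
        return omap.get(sym.upper(), sym.upper())

    mouse_pairs = {(translate(t), translate(c)) for t, c in grn_mouse.pairs}
    predictions: list[PredictionRecord] = []
    for tf in sorted(grn_human.tfs):
        targets = grn_human.targets_of(tf)
        if len(targets) < 2:
            continue
        if tf not in pwms:
            logger.info("skipping TF %s without a PWM", tf)
            continue
        ranked = rank_coexpressed(provider, targets, top_n=top_n)
        candidates = [(rank, g) for rank, g in enumerate(ranked, start=1)
                      if g in cytokine_universe and (tf, g) not in grn_human.pairs]
        if not candidates:
            continue
        site_counts = count_sites(pwms[tf],
                                  {g: promoters[g] for _, g in candidates
                                   if g in promoters},
                                  threshold=threshold)
        for rank, g in candidates:
            n_sites = site_counts.get(g, 0)
            if n_sites < 1:
                continue
            in_mouse = (translate(tf), translate(g)) in mouse_pairs
            predictions.append(PredictionRecord(
                tf_symbol=tf, cytokine_symbol=g, coexpr_rank=rank,
                n_sites=n_sites, in_mouse=in_mouse,
                confidence=confidence_tier(n_sites, in_mouse)))
    return predictions


def mouse_enrichment(predictions: Sequence[PredictionRecord],
                     grn_human: CytokineGRN,
                     grn_mouse: CytokineGRN,
                     cytokine_universe: set[str],
                     tested_tfs: Sequence[str] | None = None,
                     ortholog_map: Mapping[str, str] | None = None,
                     correction: bool = False) -> tuple[float, float]:
    """Odds ratio and chi-square p for predictions being present in mouse.

    The candidate universe is every (TF, cytokine) pair over the tested TFs
    and the cytokine universe, minus known human PDIs.  ``tested_tfs``
    defaults to the TFs appearing in the predictions.
    """
    omap = {k.upper(): v.upper() for k, v in (ortholog_map or {}).items()}

    def translate(sym: str) -> str:
        return omap.get(sym.upper(), sym.upper())

    mouse_pairs = {(translate(t), translate(c)) for t, c in grn_mouse.pairs}
    tfs = sorted(set(tested_tfs) if tested_tfs is not None
                 else {p.tf_symbol for p in predictions})
    predicted = {(p.tf_symbol, p.cytokine_symbol) for p in predictions}
    a = b = c = d = 0
    for tf in tfs:
        for cyt in cytokine_universe:
            if (tf, cyt) in grn_human.pairs:
                continue
            in_mouse = (translate(tf), translate(cyt)) in mouse_pairs
            if (tf, cyt) in predicted:
                a += in_mouse
                b += not in_mouse
            else:
                c += in_mouse
                d += not in_mouse
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"odds ratio undefined, zero margin in table {table.tolist()}")
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    _, p, _, _ = scipy.stats.chi2_contingency(table, correction=correction)
    return odds, float(p)


def predictions_to_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tf": p.tf_symbol, "cytokine": p.cytokine_symbol,
          "rank": p.coexpr_rank, "n_sites": p.n_sites,
          "in_mouse": p.in_mouse, "confidence": p.confidence}
         for p in predictions],
        columns=["tf", "cytokine", "rank", "n_sites", "in_mouse", "confidence"])
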