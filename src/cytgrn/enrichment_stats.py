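"""Enrichment and association statistics over the cytokine GRN.

Per-TF cell-type enrichment uses a pooled two-proportion z-test comparing a
TF's share of targets expressed in a cell type against all other TFs'
targets; TF-disease enrichment uses a one-sided Fisher's exact test over
the cytokine universe.  Families of tests are Benjamini-Hochberg adjusted,
significant at FDR 0.1 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .grn_model import CytokineGRN

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.1


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class EnrichmentResult:
    unit: tuple[str, str]
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    Degenerate pooled proportions (0 or 1) yield (0.0, 1.0) with a warning.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= x <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; returning p = 1")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def fisher_exact(table: ContingencyTable2x2,
                 sided: str = "two") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (odds ratio, p).

    The odds ratio is the sample estimate ad/bc (infinite when bc = 0 and
    ad > 0).
    """
    alternative = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    _, p = scipy.stats.fisher_exact(table.as_array, alternative=alternative)
    return table.odds_ratio, float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(results: list[EnrichmentResult], fdr: float) -> list[EnrichmentResult]:
    if not results:
        return results
    adj = bh_adjust([r.p_value for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.significant = bool(pa < fdr)
    return results


def celltype_enrichment(grn: CytokineGRN,
                        cyt_celltypes: Mapping[str, set[str]],
                        fdr: float = DEFAULT_FDR) -> list[EnrichmentResult]:
    """Per (TF, cell type): is the TF's share of targets expressed in the
    cell type higher than the share among all other TFs' targets?

    TFs with fewer than two targets are skipped.  BH adjustment is applied
    across the full (TF, cell type) family.
    """
    missing = grn.cytokines - set(cyt_celltypes)
    if missing:
        raise ValueError(f"cytokines without cell-type annotation: {sorted(missing)[:5]}")
    celltypes = sorted({ct for s in cyt_celltypes.values() for ct in s})
    if not celltypes:
        logger.warning("empty cell-type annotation; no tests performed")
        return []
    results = []
    pairs = list(grn.pairs)
    for tf in sorted(grn.tfs):
        targets = grn.targets_of(tf)
        if len(targets) < 2:
            logger.info("skipping TF %s with < 2 targets", tf)
            continue
        others = [(t, c) for t, c in pairs if t != tf]
        for ct in celltypes:
            x1 = sum(1 for c in targets if ct in cyt_celltypes[c])
            x2 = sum(1 for _, c in others if ct in cyt_celltypes[c])
            z, p = proportion_test(x1, len(targets), x2, len(others))
            results.append(EnrichmentResult(unit=(tf, ct), statistic=z, p_value=p))
    return _finalize(results, fdr)


def disease_enrichment(grn: CytokineGRN,
                       disease_sets: Mapping[str, set[str]],
                       cytokine_universe: set[str],
                       fdr: float = DEFAULT_FDR) -> list[EnrichmentResult]:
    """Per (TF, disease) one-sided Fisher enrichment of the TF's targets
    among the cytokines upregulated in the disease, over the full cytokine
    universe; BH across all pairs, significant at adjusted p < ``fdr``.
    """
    universe = set(cytokine_universe)
    results = []
    for disease, up in sorted(disease_sets.items()):
        up = set(up) & universe
        if not up:
            logger.warning("skipping disease %s with empty cytokine set", disease)
            continue
        for tf in sorted(grn.tfs):
            targets = grn.targets_of(tf) & universe
            a = len(targets & up)
            b = len(up) - a
            c = len(targets) - a
            d = len(universe) - a - b - c
            table = ContingencyTable2x2(a, b, c, d)
            or_, p = fisher_exact(table, sided="greater")
            results.append(EnrichmentResult(unit=(tf, disease),
                                            statistic=or_, p_value=p))
    return _finalize(results, fdr)


def family_comparison(grn: CytokineGRN,
                      reference_pdi_counts: Mapping[str, int],
                      groups: Mapping[str, str],
                      ) -> tuple[pd.DataFrame, float]:
    """Percent of PDIs per TF group in the cytokine GRN vs a reference GRN.

    Returns (per-group table, Pearson r across groups).
    """
    total_ref = sum(reference_pdi_counts.values())
    if total_ref == 0:
        raise ValueError("reference GRN is empty")
    total_grn = grn.n_edges
    deg = grn.tf_degree
    group_names = sorted(set(groups.values()))
    rows = []
    for g in group_names:
        members = {tf for tf, gg in groups.items() if gg == g}
        pct_grn = 100 * sum(deg.get(tf, 0) for tf in members) / total_grn
        pct_ref = 100 * sum(reference_pdi_counts.get(tf, 0) for tf in members) / total_ref
        rows.append({"group": g, "pct_grn": pct_grn, "pct_reference": pct_ref})
    df = pd.DataFrame(rows)
    if len(df) >= 2 and df["pct_grn"].std() > 0 and df["pct_reference"].std() > 0:
        r = float(scipy.stats.pearsonr(df["pct_grn"], df["pct_reference"])[0])
    else:
        r = float("nan")
    return df, r


def connectivity_phenotype(grn: CytokineGRN,
                           tf_flags: Mapping[str, bool],
                           bins: Sequence[tuple[int, float]] | None = None,
                           tf_universe: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Fraction of TFs carrying a phenotype flag, per degree bin.

    TFs in ``tf_universe`` but absent from the GRN populate the degree-0
    bin; TFs without a flag entry are treated as unflagged and logged.
    """
    from .tf_scores import DEFAULT_DEGREE_BINS, assign_degree_bin
    bins = tuple(bins or DEFAULT_DEGREE_BINS)
    deg = grn.tf_degree
    tfs = set(deg) | set(tf_universe or ())
    unflagged = [tf for tf in tfs if tf not in tf_flags]
    if unflagged:
        logger.warning("%d TFs without phenotype flag treated as False",
                       len(unflagged))
    rows = []
    for tf in sorted(tfs):
        d = deg.get(tf, 0)
        rows.append({"tf": tf, "degree": d, "bin": assign_degree_bin(d, bins),
                     "flag": bool(tf_flags.get(tf, False))})
    df = pd.DataFrame(rows)
    order = [assign_degree_bin(int(lo if lo != 0 else 0), bins) for lo, _ in bins]
    out = (df.groupby("bin")["flag"].agg(["mean", "count"])
             .reindex([b for b in dict.fromkeys(order)]).dropna()
             .rename(columns={"mean": "fraction_flagged", "count": "n_tfs"})
             .reset_index())
    return out


def cofactor_usage(grn: CytokineGRN,
                   tf_cofactor: Sequence[tuple[str, str]],
                   tf_class: Mapping[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cofactor recruitment summaries.

    Returns (per-(cytokine, cofactor) distinct-TF counts, per-cofactor
    PSA/TS partner fractions among classified TFs).
    """
    cof_partners: dict[str, set[str]] = {}
    for tf, cof in tf_cofactor:
        cof_partners.setdefault(cof, set()).add(tf)
    rows = []
    for cyt in sorted(grn.cytokines):
        tfs = grn.tfs_of(cyt)
        for cof, partners in sorted(cof_partners.items()):
            n = len(tfs & partners)
            if n:
                rows.append({"cytokine": cyt, "cofactor": cof, "n_tfs": n})
    counts = pd.DataFrame(rows, columns=["cytokine", "cofactor", "n_tfs"])

    frac_rows = []
    tf_class = dict(tf_class or {})
    for cof, partners in sorted(cof_partners.items()):
        classified = [tf for tf in partners if tf_class.get(tf) in {"PSA", "TS"}]
        if not classified:
            continue
        n_psa = sum(tf_class[tf] == "PSA" for tf in classified)
        frac_rows.append({"cofactor": cof,
                          "frac_psa": n_psa / len(classified),
                          "frac_ts": 1 - n_psa / len(classified),
                          "n_classified": len(classified)})
    fractions = pd.DataFrame(frac_rows,
                             columns=["cofactor", "frac_psa", "frac_ts",
                                      "n_classified"])
    return counts, fractions


def drug_targetability(grn: CytokineGRN,
                       tf_drugs: Sequence[tuple[str, str, str]],
                       ) -> pd.DataFrame:
    """Per cytokine, distinct TFs targetable by agonists / antagonists.

    ``tf_drugs`` rows are (tf, drug, action); agonists and activators group
    as agonists, antagonists and inhibitors as antagonists.  A TF with both
    modes counts in both columns.
    """
    grouping = {"agonist": "agonist", "activator": "agonist",
                "antagonist": "antagonist", "inhibitor": "antagonist"}
    modes: dict[str, set[str]] = {}
    for tf, _drug, action in tf_drugs:
        mode = grouping.get(action.strip().lower())
        if mode is None:
            logger.warning("unknown drug action %r for %s; treated as other",
                           action, tf)
            continue
        modes.setdefault(tf, set()).add(mode)
    rows = []
    for cyt in sorted(grn.cytokines):
        tfs = grn.tfs_of(cyt)
        rows.append({
            "cytokine": cyt,
            "n_agonist_tfs": sum("agonist" in modes.get(tf, ()) for tf in tfs),
            "n_antagonist_tfs": sum("antagonist" in modes.get(tf, ()) for tf in tfs),
        })
    return pd.DataFrame(rows, columns=["cytokine", "n_agonist_tfs",
                                       "n_antagonist_tfs"])
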