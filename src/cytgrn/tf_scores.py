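"""Per-TF scores derived from the cytokine GRN and expression data.

* TSPS -- tissue-specificity score: the Kullback-Leibler divergence (in
  bits) between a gene's expression ratios across tissues and the uniform
  distribution; 0 for uniformly expressed genes, log2(T) when expression is
  confined to a single of T tissues.  Genes with TSPS >= 0.7 are classed
  tissue-specific (TS).
* EES -- expression enrichment score: pseudocounted expression in a tissue
  divided by the gene's pseudocounted mean across tissues, averaged over
  immune and over non-immune tissues.
* IS -- inflammatory score: the fraction of a TF's PDIs with canonical
  pro-inflammatory cytokines minus the fraction with anti-inflammatory
  cytokines, in [-1, 1]; bands at +/-0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grn_model import CytokineGRN

logger = logging.getLogger(__name__)

TSPS_DEFAULT_THRESHOLD = 0.7

#: Canonical pro-inflammatory cytokines.
PRO_INFLAMMATORY = frozenset({
    "IL1A", "IL1B", "IL12A", "IL12B", "IL18", "TNF", "IFNG", "CSF2",
    "CXCL8", "IL6",
})

#: Anti-inflammatory cytokines.
ANTI_INFLAMMATORY = frozenset({
    "IL10", "IL11", "IL13", "IL19", "IL1RN", "IL24", "IL37", "IL4", "IL5",
    "CXCL17", "TGFB1", "TGFB2", "TGFB3",
})

#: Default degree bins (lo, hi) inclusive, used for degree-stratified plots.
DEFAULT_DEGREE_BINS: tuple[tuple[int, float], ...] = (
    (0, 0), (1, 1), (2, 4), (5, 9), (10, float("inf")),
)


class ExpressionMatrix:
    """Non-negative gene x tissue expression values (TPM or equivalent)."""

    def __init__(self, values: pd.DataFrame,
                 tissue_flags: Mapping[str, str] | None = None):
        if (values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if values.shape[1] == 0:
            raise ValueError("tissue set must be non-empty")
        self.values = values.astype(float)
        self.tissue_flags = dict(tissue_flags or {})
        for t, flag in self.tissue_flags.items():
            if flag not in {"immune", "non_immune"}:
                raise ValueError(f"bad tissue flag {flag!r} for {t}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> pd.Series:
        return self.values.loc[gene]

    @classmethod
    def read(cls, path: str | Path,
             flags_path: str | Path | None = None) -> "ExpressionMatrix":
        """TSV with first column gene, header row tissues; flags as
        two-column TSV (tissue, immune|non_immune)."""
        values = pd.read_csv(path, sep="\t", index_col=0)
        flags = None
        if flags_path is not None:
            fdf = pd.read_csv(flags_path, sep="\t", header=None,
                              names=["tissue", "flag"], dtype=str)
            flags = dict(zip(fdf["tissue"], fdf["flag"]))
        return cls(values, flags)

    def write(self, path: str | Path,
              flags_path: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t")
        if flags_path is not None:
            pd.DataFrame(sorted(self.tissue_flags.items())).to_csv(
                flags_path, sep="\t", header=False, index=False)


@dataclass
class TSPSResult:
    tsps: float
    p_i: np.ndarray
    p: float
    is_ts: bool


@dataclass
class InflammatoryScore:
    is_value: float
    n_pro: int
    n_anti: int
    n_total: int

    @property
    def band(self) -> str | None:
        if self.is_value >= 0.5:
            return "pro"
        if self.is_value <= -0.5:
            return "anti"
        return None


def tsps(profile: Sequence[float] | pd.Series,
         threshold: float = TSPS_DEFAULT_THRESHOLD) -> TSPSResult:
    """Tissue-specificity score TSPS = sum_i p_i * log2(p_i / p).

    ``p_i`` is the expression share of tissue i and ``p = 1/T`` the share
    expected under uniform expression; terms with p_i = 0 contribute 0.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector over at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("TSPS undefined for an all-zero profile")
    p_i = x / total
    p = 1.0 / x.size
    nz = p_i > 0
    score = float(np.sum(p_i[nz] * np.log2(p_i[nz] / p)))
    return TSPSResult(tsps=score, p_i=p_i, p=p, is_ts=score >= threshold)


def expression_enrichment(profile: pd.Series,
                          tissue_flags: Mapping[str, str]) -> tuple[float, float]:
    """Mean expression-enrichment score over immune and non-immune tissues.

    A pseudocount of 1 is added to every value; each tissue's enrichment is
    the pseudocounted value divided by the gene's pseudocounted mean across
    all tissues.
    """
    missing = [t for t in profile.index if t not in tissue_flags]
    if missing:
        raise ValueError(f"no immune flag for tissue(s) {missing}")
    flags = pd.Series({t: tissue_flags[t] for t in profile.index})
    if not (flags == "immune").any() or not (flags == "non_immune").any():
        raise ValueError("need at least one immune and one non-immune tissue")
    shifted = profile.astype(float) + 1.0
    enrichment = shifted / shifted.mean()
    return (float(enrichment[flags == "immune"].mean()),
            float(enrichment[flags == "non_immune"].mean()))


def inflammatory_score(grn: CytokineGRN, tf: str,
                       pro_list: frozenset[str] | set[str] = PRO_INFLAMMATORY,
                       anti_list: frozenset[str] | set[str] = ANTI_INFLAMMATORY,
                       ) -> InflammatoryScore:
    """Inflammatory score of one TF over its distinct cytokine targets."""
    pro, anti = set(pro_list), set(anti_list)
    if pro & anti:
        raise ValueError(f"pro/anti lists overlap: {sorted(pro & anti)}")
    targets = grn.targets_of(tf)
    if not targets:
        raise ValueError(f"TF {tf!r} not present in the network")
    n_pro = len(targets & pro)
    n_anti = len(targets & anti)
    n_total = len(targets)
    return InflammatoryScore(is_value=(n_pro - n_anti) / n_total,
                             n_pro=n_pro, n_anti=n_anti, n_total=n_total)


def assign_degree_bin(degree: int,
                      bins: Sequence[tuple[int, float]] = DEFAULT_DEGREE_BINS,
                      ) -> str:
    for lo, hi in bins:
        if lo <= degree <= hi:
            return f"{lo}" if lo == hi else (
                f">={lo}" if hi == float("inf") else f"{lo}-{int(hi)}")
    raise ValueError(f"degree {degree} not covered by bins {bins}")


def expression_by_degree(grn: CytokineGRN, expr: ExpressionMatrix,
                         bins: Sequence[tuple[int, float]] = DEFAULT_DEGREE_BINS,
                         tf_universe: Sequence[str] | None = None,
                         ) -> pd.DataFrame:
    """Median immune-cell expression per TF, grouped by cytokine-target bin.

    ``tf_universe`` adds TFs absent from the GRN (degree 0); TFs without
    expression data are skipped and counted in the log.  Returns a tidy
    frame with columns tf, degree, bin, median_expression.
    """
    if not bins:
        raise ValueError("empty bin set")
    immune = [t for t in expr.tissues
              if expr.tissue_flags.get(t) == "immune"] or expr.tissues
    deg = grn.tf_degree
    tfs = set(deg) | set(tf_universe or ())
    rows, skipped = [], 0
    for tf in sorted(tfs):
        if tf not in expr.values.index:
            skipped += 1
            continue
        d = deg.get(tf, 0)
        rows.append({
            "tf": tf, "degree": d, "bin": assign_degree_bin(d, bins),
            "median_expression": float(expr.values.loc[tf, immune].median()),
        })
    if skipped:
        logger.warning("%d TFs absent from the expression matrix", skipped)
    return pd.DataFrame(rows, columns=["tf", "degree", "bin", "median_expression"])
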