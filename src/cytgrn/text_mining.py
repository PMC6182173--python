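"""Desk-scale article triage: flag abstracts co-mentioning a cytokine, a TF,
and an experimental assay.

Alias lexicons are expanded for the spelling variants common in the
immunology literature -- hyphen vs space vs fused tokens, and Greek letters
vs their spelled-out names (IFN-gamma / IFN-g(amma) / IFNG...).  Matching is
case-insensitive at word boundaries so that gene symbols embedded in longer
tokens never match.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GREEK_LETTERS = {
    "α": "alpha", "β": "beta", "γ": "gamma", "κ": "kappa",
    "δ": "delta", "ε": "epsilon", "λ": "lambda",
}

_SEP_RUN = re.compile(r"[-\s]+")


@dataclass
class Lexicon:
    """Surface term -> canonical symbol dictionary for one category."""

    category: str  # one of {"tf", "cytokine", "assay"}
    entries: dict[str, str] = field(default_factory=dict)

    def add(self, surface: str, symbol: str) -> None:
        surface = surface.lower()
        existing = self.entries.get(surface)
        if existing is not None and existing != symbol:
            # ambiguous alias: keep neither mapping
            logger.warning("alias collision %r: %s vs %s; dropping term",
                           surface, existing, symbol)
            del self.entries[surface]
            return
        self.entries[surface] = symbol

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ArticleRecord:
    article_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("article text must be non-empty")


@dataclass
class TriageHit:
    article_id: str
    matched_cytokines: list[tuple[str, str]]
    matched_tfs: list[tuple[str, str]]
    matched_assays: list[tuple[str, str]]


def _separator_variants(term: str) -> set[str]:
    """hyphen <-> space <-> fused variants at each separator run."""
    parts = _SEP_RUN.split(term)
    gaps = len(parts) - 1
    if gaps == 0:
        return {term}
    if gaps <= 4:
        out = set()
        for seps in itertools.product(("-", " ", ""), repeat=gaps):
            s = parts[0]
            for sep, nxt in zip(seps, parts[1:]):
                s += sep + nxt
            out.add(s)
        return out
    # degenerate many-separator term: uniform replacement only
    return {_SEP_RUN.sub(sep, term) for sep in ("-", " ", "")}


def _greek_variants(term: str) -> set[str]:
    out = {term}
    for letter, name in GREEK_LETTERS.items():
        out |= {t.replace(name, letter) for t in out if name in t}
        out |= {t.replace(letter, name) for t in out if letter in t}
    return out


def expand_aliases(symbol: str, aliases: Iterable[str]) -> dict[str, str]:
    """Expand surface aliases into the full spelling-variant set.

    Returns lexicon entries (lowercased surface term -> canonical symbol)
    covering hyphen/space/fused separators and Greek-letter substitutions.
    """
    if not symbol:
        raise ValueError("symbol must be non-empty")
    variants: set[str] = set()
    for alias in aliases:
        base = alias.strip().lower()
        if not base:
            continue
        seps = _separator_variants(base)
        greek: set[str] = set()
        for v in seps:
            greek |= _greek_variants(v)
        for g in greek:
            variants |= _separator_variants(g)
    return {v: symbol.upper() for v in variants if v}


def build_lexicon(category: str,
                  alias_table: Mapping[str, Iterable[str]]) -> Lexicon:
    """Build a lexicon from symbol -> aliases, expanding variants."""
    lex = Lexicon(category=category)
    for symbol, aliases in alias_table.items():
        for surface, canon in expand_aliases(symbol, list(aliases) + [symbol]).items():
            lex.add(surface, canon)
    return lex


def read_lexicon(path: str | Path, category: str) -> Lexicon:
    """Two-column TSV (term, symbol) -> expanded Lexicon."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     names=["term", "symbol"]).dropna()
    table: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        table.setdefault(row["symbol"], []).append(row["term"])
    return build_lexicon(category, table)


def read_articles(path: str | Path) -> list[ArticleRecord]:
    """TSV with columns id, title, abstract -> article records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        text = " ".join(filter(None, [row.get(cols.get("title", ""), ""),
                                      row.get(cols.get("abstract", ""), "")]))
        out.append(ArticleRecord(str(row[cols["id"]]), text))
    return out


def _compile(lex: Lexicon) -> re.Pattern:
    # longest-first alternation; boundaries = non-alphanumeric context
    terms = sorted(lex.entries, key=len, reverse=True)
    alt = "|".join(re.escape(t) for t in terms)
    return re.compile(rf"(?<![a-z0-9])(?:{alt})(?![a-z0-9])", re.IGNORECASE)


def triage_articles(articles: Sequence[ArticleRecord],
                    tf_lexicon: Lexicon,
                    cytokine_lexicon: Lexicon,
                    assay_lexicon: Lexicon) -> list[TriageHit]:
    """Flag articles mentioning at least one term from every lexicon."""
    for lex in (tf_lexicon, cytokine_lexicon, assay_lexicon):
        if len(lex) == 0:
            raise ValueError(f"empty {lex.category} lexicon")
    patterns = {
        "tf": (_compile(tf_lexicon), tf_lexicon),
        "cytokine": (_compile(cytokine_lexicon), cytokine_lexicon),
        "assay": (_compile(assay_lexicon), assay_lexicon),
    }
    hits = []
    for art in articles:
        text = art.text.lower()
        matched: dict[str, list[tuple[str, str]]] = {}
        for cat, (pat, lex) in patterns.items():
            found = []
            seen = set()
            for m in pat.finditer(text):
                surface = m.group(0).lower()
                canon = lex.entries[surface]
                if (surface, canon) not in seen:
                    seen.add((surface, canon))
                    found.append((surface, canon))
            if not found:
                break
            matched[cat] = found
        else:
            hits.append(TriageHit(
                article_id=art.article_id,
                matched_cytokines=matched["cytokine"],
                matched_tfs=matched["tf"],
                matched_assays=matched["assay"],
            ))
    return hits


#: Editable default assay lexicon covering the three curation categories.
DEFAULT_ASSAY_TERMS: dict[str, list[str]] = {
    "CHIP": ["ChIP", "chromatin immunoprecipitation", "ChIP-seq"],
    "BINDING_IN_VITRO": ["EMSA", "gel shift", "electrophoretic mobility shift",
                         "pull down"],
    "FUNCTIONAL": ["reporter assay", "luciferase", "knockdown", "knockout",
                   "siRNA"],
}
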