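"""Data model for the literature-curated cytokine gene regulatory network.

The network is bipartite: transcription factors (TFs) on one side, cytokine
genes on the other, with one edge per curated protein-DNA interaction (PDI).
Each PDI carries the experimental assay categories that support it, the
regulatory activity observed (activating / repressing / bifunctional), and
the articles reporting it.  Duplicate reports of the same (TF, cytokine,
species) triple are merged; assay categories and article ids accumulate, so
node degree counts distinct partners, not citations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The three broad assay categories used during curation.
ASSAY_CATEGORIES = frozenset({"binding_in_vitro", "chip", "functional"})

ACTIVITIES = frozenset({"activating", "repressing", "bifunctional", "unknown"})

#: Free-text assay names (lowercased) mapped onto the three categories.
#: Users can extend this mapping via the ``assay_synonyms`` argument of
#: :func:`read_interaction_table`.
DEFAULT_ASSAY_SYNONYMS: dict[str, str] = {
    "chip": "chip",
    "chip-seq": "chip",
    "chip-qpcr": "chip",
    "chromatin immunoprecipitation": "chip",
    "emsa": "binding_in_vitro",
    "gel shift": "binding_in_vitro",
    "gel-shift": "binding_in_vitro",
    "pull down": "binding_in_vitro",
    "pull-down": "binding_in_vitro",
    "binding": "binding_in_vitro",
    "in vitro binding": "binding_in_vitro",
    "binding_in_vitro": "binding_in_vitro",
    "functional": "functional",
    "reporter": "functional",
    "luciferase": "functional",
    "knockdown": "functional",
    "knockout": "functional",
    "sirna": "functional",
    "overexpression": "functional",
}

_CANONICAL_COLUMNS = ("TF", "Cytokine", "Species", "Assay", "Activity", "PMID")


class SchemaError(ValueError):
    """A mandatory column is missing or malformed in an input table."""


def classify_evidence(assay_categories: Iterable[str]) -> str:
    """Classify a PDI as ``high`` or ``low`` evidence of direct regulation.

    A PDI is high evidence when it is supported by a functional assay
    (reporter, knockdown, ...) *and* an assay measuring direct binding
    (ChIP or an in vitro binding assay).  A PDI seen by only one type of
    assay -- and, by the same conjunction, one seen by ChIP plus in vitro
    binding without any functional read-out -- is low evidence.
    """
    cats = set(assay_categories)
    if not cats:
        raise ValueError("assay_categories must be non-empty")
    unknown = cats - ASSAY_CATEGORIES
    if unknown:
        raise ValueError(f"unknown assay categories: {sorted(unknown)}")
    if "functional" in cats and cats & {"chip", "binding_in_vitro"}:
        return "high"
    return "low"


@dataclass(frozen=True)
class InteractionRecord:
    """One curated TF -> cytokine interaction in one species."""

    tf_symbol: str
    cytokine_symbol: str
    species: str
    assay_categories: frozenset[str]
    regulatory_activity: str = "unknown"
    article_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tf_symbol or not self.cytokine_symbol:
            raise ValueError("gene symbols must be non-empty")
        if not self.assay_categories:
            raise ValueError("assay_categories must be non-empty")
        if self.regulatory_activity not in ACTIVITIES:
            raise ValueError(f"bad activity {self.regulatory_activity!r}")
        if not self.article_ids:
            raise ValueError("article_ids must be non-empty")

    @property
    def evidence_level(self) -> str:
        return classify_evidence(self.assay_categories)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf_symbol, self.cytokine_symbol)


class CytokineGRN:
    """Bipartite TF-cytokine network for one species.

    Holds the distinct (TF, cytokine) pairs and, when built from curated
    records, the records themselves.  Randomized networks produced by the
    null model carry topology only (``records`` empty).
    """

    def __init__(self, species: str, records: Sequence[InteractionRecord] = (),
                 pairs: Iterable[tuple[str, str]] | None = None):
        self.species = species
        self.records: tuple[InteractionRecord, ...] = tuple(records)
        if pairs is None:
            pairs = [r.pair for r in self.records]
        self.pairs: frozenset[tuple[str, str]] = frozenset(pairs)
        if not all(len(p) == 2 for p in self.pairs):
            raise ValueError("pairs must be (tf, cytokine) tuples")

    @classmethod
    def from_edges(cls, species: str, edges: Iterable[tuple[str, str]]) -> "CytokineGRN":
        return cls(species, records=(), pairs=edges)

    @property
    def tfs(self) -> set[str]:
        return {t for t, _ in self.pairs}

    @property
    def cytokines(self) -> set[str]:
        return {c for _, c in self.pairs}

    @property
    def n_edges(self) -> int:
        return len(self.pairs)

    @property
    def tf_degree(self) -> Counter:
        return Counter(t for t, _ in self.pairs)

    @property
    def cytokine_degree(self) -> Counter:
        return Counter(c for _, c in self.pairs)

    def targets_of(self, tf: str) -> set[str]:
        return {c for t, c in self.pairs if t == tf}

    def tfs_of(self, cytokine: str) -> set[str]:
        return {t for t, c in self.pairs if c == cytokine}

    def __len__(self) -> int:
        return len(self.pairs)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CytokineGRN(species={self.species!r}, "
                f"tfs={len(self.tfs)}, cytokines={len(self.cytokines)}, "
                f"pdis={self.n_edges})")


@dataclass
class SpeciesOverlap:
    shared_pairs: frozenset[tuple[str, str]]
    frac_specific_a: float
    frac_specific_b: float


def _canonical_symbol(raw: object) -> str:
    return str(raw).strip().upper()


def _normalize_species(raw: object) -> str:
    s = str(raw).strip().lower()
    if s in {"human", "h. sapiens", "homo sapiens", "hs"}:
        return "human"
    if s in {"mouse", "m. musculus", "mus musculus", "mm"}:
        return "mouse"
    return f"other:{s}" if not s.startswith("other:") else s


def _map_assay(raw: str, synonyms: Mapping[str, str]) -> str | None:
    key = raw.strip().lower()
    if key in synonyms:
        return synonyms[key]
    # substring fallback for free-text assay descriptions
    for name, cat in synonyms.items():
        if name in key:
            return cat
    return None


def read_interaction_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    assay_synonyms: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[InteractionRecord]:
    """Read a curated interaction table into merged records.

    Parameters
    ----------
    path:
        Delimited text file, one row per reported PDI.
    dialect:
        Mapping from canonical column names (``TF``, ``Cytokine``,
        ``Species``, ``Assay``, ``Activity``, ``PMID``) to the column names
        actually present in the file.  Defaults to identity.
    assay_synonyms:
        Extra free-text assay name -> category entries, merged over
        :data:`DEFAULT_ASSAY_SYNONYMS`.
    sep:
        Field separator; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).

    One record is returned per distinct (TF, cytokine, species) after
    canonicalization; assay categories and article ids are unioned across
    duplicate rows.  Rows with a blank TF or cytokine symbol are rejected
    and logged.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    colmap = dict(dialect or {})
    synonyms = dict(DEFAULT_ASSAY_SYNONYMS)
    if assay_synonyms:
        synonyms.update({k.lower(): v for k, v in assay_synonyms.items()})

    def col(name: str, required: bool = True) -> str | None:
        actual = colmap.get(name, name)
        if actual not in df.columns:
            if required:
                raise SchemaError(f"missing mandatory column {actual!r} (for {name})")
            return None
        return actual

    c_tf, c_cyt, c_sp, c_assay = col("TF"), col("Cytokine"), col("Species"), col("Assay")
    c_act = col("Activity", required=False)
    c_pmid = col("PMID", required=False)

    if df.empty:
        logger.warning("interaction table %s is empty", path)
        return []

    merged: dict[tuple[str, str, str], dict] = {}
    n_rejected = 0
    for _, row in df.iterrows():
        tf = _canonical_symbol(row[c_tf])
        cyt = _canonical_symbol(row[c_cyt])
        if not tf or not cyt:
            n_rejected += 1
            logger.warning("rejected row with blank symbol: %s", row.to_dict())
            continue
        species = _normalize_species(row[c_sp])
        cats: set[str] = set()
        for token in str(row[c_assay]).replace(";", ",").split(","):
            token = token.strip()
            if not token:
                continue
            cat = _map_assay(token, synonyms)
            if cat is None:
                logger.warning("unmapped assay name %r (row %s-%s)", token, tf, cyt)
            else:
                cats.add(cat)
        if not cats:
            n_rejected += 1
            logger.warning("rejected row with no mappable assay: %s-%s", tf, cyt)
            continue
        activity = str(row[c_act]).strip().lower() if c_act else ""
        if activity not in ACTIVITIES:
            activity = "unknown"
        pmids = []
        if c_pmid:
            pmids = [p.strip() for p in str(row[c_pmid]).replace(";", ",").split(",")
                     if p.strip()]
        if not pmids:
            pmids = ["NA"]

        key = (tf, cyt, species)
        slot = merged.setdefault(key, {"cats": set(), "pmids": [], "acts": set()})
        slot["cats"] |= cats
        for p in pmids:
            if p not in slot["pmids"]:
                slot["pmids"].append(p)
        if activity != "unknown":
            slot["acts"].add(activity)

    if n_rejected:
        logger.warning("%d rows rejected while reading %s", n_rejected, path)

    records = []
    for (tf, cyt, species), slot in merged.items():
        acts = slot["acts"]
        if not acts:
            activity = "unknown"
        elif acts == {"activating"}:
            activity = "activating"
        elif acts == {"repressing"}:
            activity = "repressing"
        else:
            activity = "bifunctional"
        records.append(InteractionRecord(
            tf_symbol=tf, cytokine_symbol=cyt, species=species,
            assay_categories=frozenset(slot["cats"]),
            regulatory_activity=activity,
            article_ids=tuple(slot["pmids"]),
        ))
    return records


def write_interaction_table(records: Sequence[InteractionRecord],
                            path: str | Path) -> None:
    """Write records as the canonical six-column TSV."""
    rows = [{
        "TF": r.tf_symbol,
        "Cytokine": r.cytokine_symbol,
        "Species": r.species,
        "Assay": ";".join(sorted(r.assay_categories)),
        "Activity": r.regulatory_activity,
        "PMID": ";".join(r.article_ids),
    } for r in records]
    pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def build_grns(records: Sequence[InteractionRecord]) -> dict[str, CytokineGRN]:
    """Split merged records by species into one network each."""
    by_species: dict[str, list[InteractionRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    return {sp: CytokineGRN(sp, recs) for sp, recs in by_species.items()}


def degree_rank_coverage(grn: CytokineGRN, side: str = "tf",
                         coverage: float = 0.5) -> float:
    """Minimal fraction of top-degree nodes covering > ``coverage`` of PDIs.

    Nodes are ranked by decreasing degree, ties broken lexicographically;
    returns k/N for the smallest k whose cumulative distinct-pair count
    strictly exceeds ``coverage`` times the total.
    """
    if grn.n_edges == 0:
        raise ValueError("empty network")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    deg = grn.tf_degree if side == "tf" else grn.cytokine_degree
    if side not in {"tf", "cytokine"}:
        raise ValueError("side must be 'tf' or 'cytokine'")
    ordered = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    total = grn.n_edges
    cum = 0
    for k, (_, d) in enumerate(ordered, start=1):
        cum += d
        if cum > coverage * total:
            return k / len(ordered)
    return 1.0


def species_overlap(grn_a: CytokineGRN, grn_b: CytokineGRN,
                    ortholog_map: Mapping[str, str] | None = None) -> SpeciesOverlap:
    """Fraction of species-specific PDIs in each of two networks.

    ``grn_b`` symbols are passed through ``ortholog_map`` (default:
    case-insensitive symbol identity); genes without a counterpart stay
    species-specific.
    """
    if grn_a.n_edges == 0 or grn_b.n_edges == 0:
        raise ValueError("both networks must be non-empty")
    omap = {k.upper(): v.upper() for k, v in (ortholog_map or {}).items()}

    def translate(sym: str) -> str:
        return omap.get(sym.upper(), sym.upper())

    pairs_a = {(t.upper(), c.upper()) for t, c in grn_a.pairs}
    mapped_b = {(translate(t), translate(c)) for t, c in grn_b.pairs}
    shared = pairs_a & mapped_b
    n_shared_b = sum(1 for t, c in grn_b.pairs
                     if (translate(t), translate(c)) in pairs_a)
    return SpeciesOverlap(
        shared_pairs=frozenset(shared),
        frac_specific_a=1.0 - len(shared) / grn_a.n_edges,
        frac_specific_b=1.0 - n_shared_b / grn_b.n_edges,
    )


def activity_fraction(grn: CytokineGRN, activity: str) -> float:
    """Fraction of activity-annotated PDIs with the given activity."""
    if activity not in ACTIVITIES - {"unknown"}:
        raise ValueError(f"bad activity {activity!r}")
    annotated = [r for r in grn.records if r.regulatory_activity != "unknown"]
    if not annotated:
        raise ValueError("no records with annotated regulatory activity")
    return sum(r.regulatory_activity == activity for r in annotated) / len(annotated)
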