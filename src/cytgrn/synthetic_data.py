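"""Seeded generators for every input the pipeline consumes.

The generated "world" emulates the shape of the real inputs -- a curated
bipartite GRN with heavy-tailed TF degrees, tissue expression with planted
tissue-specific genes, a co-expression compendium with planted modules,
promoters with planted motif sites, annotation tables, and an abstract
corpus with planted co-mentions -- while recording the ground truth of
every planted structure so downstream stages can be scored exactly.

Gene identities are synthetic labels (TF001, CYT001, ...); a master seed
fans out to per-generator child seeds so each piece can be regenerated
independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grn_model import CytokineGRN, InteractionRecord
from .motif_scan import BASES, PWM, PromoterSet
from .text_mining import ArticleRecord

#: Offsets added to the master seed for each sub-generator.
_CHILD = {"grn": 1, "mouse": 2, "expression": 3, "compendium": 4,
          "pwms": 5, "promoters": 6, "annotations": 7, "corpus": 8}


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(_CHILD[name],))


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def generate_grn(n_tfs: int = 60, n_cytokines: int = 60,
                 degree_exponent: float = 2.0, seed: int = 0,
                 p_activating: float = 0.8,
                 species: str = "human",
                 rng: np.random.Generator | None = None) -> CytokineGRN:
    """Bipartite GRN with truncated power-law TF degrees.

    TF degrees follow P(k) ~ k^-gamma on 1..n_cytokines; targets are drawn
    without replacement with rank-weighted cytokine attractiveness so the
    cytokine side is heavy-tailed as well.  Activity labels are activating
    with probability ``p_activating`` (else repressing); assay categories
    are random non-empty subsets of the three curation classes.
    """
    if n_tfs < 2 or n_cytokines < 2:
        raise ValueError("need at least 2 TFs and 2 cytokines")
    rng = rng or np.random.default_rng(child_seed(seed, "grn"))
    tfs = _gene_names("TF", n_tfs)
    cytokines = _gene_names("CYT", n_cytokines)
    ks = np.arange(1, n_cytokines + 1, dtype=float)
    degree_pmf = ks ** (-degree_exponent)
    degree_pmf /= degree_pmf.sum()
    cyt_weight = 1.0 / np.arange(1, n_cytokines + 1) ** 0.8
    cyt_weight /= cyt_weight.sum()
    records = []
    assay_choices = [frozenset({"functional"}), frozenset({"chip"}),
                     frozenset({"binding_in_vitro"}),
                     frozenset({"functional", "chip"}),
                     frozenset({"functional", "binding_in_vitro"}),
                     frozenset({"chip", "binding_in_vitro"}),
                     frozenset({"functional", "chip", "binding_in_vitro"})]
    for tf in tfs:
        k = int(rng.choice(ks, p=degree_pmf))
        targets = rng.choice(n_cytokines, size=k, replace=False, p=cyt_weight)
        for j in targets:
            activity = ("activating" if rng.random() < p_activating
                        else "repressing")
            records.append(InteractionRecord(
                tf_symbol=tf, cytokine_symbol=cytokines[j], species=species,
                assay_categories=assay_choices[rng.integers(len(assay_choices))],
                regulatory_activity=activity,
                article_ids=(f"PM{rng.integers(10**6, 10**7)}",)))
    return CytokineGRN(species, records)


def generate_expression(genes: Sequence[str], n_tissues: int = 34,
                        ts_genes: Sequence[str] = (), seed: int = 0,
                        ts_share: float = 0.95,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Gene x tissue TPM-like matrix with planted tissue-specific genes.

    Background is log-normal; each planted TS gene is concentrated in one
    "home" tissue so that its TSPS clears the 0.7 cut-off by construction
    (a share ``ts_share`` of its total expression in one of T tissues gives
    TSPS of roughly ts_share * log2(ts_share * T), about 4.4 bits at the
    defaults).  Returns (matrix, tissue immune flags, TS gene -> home
    tissue).
    """
    ts_genes = list(ts_genes)
    unknown = set(ts_genes) - set(genes)
    if unknown:
        raise ValueError(f"ts_genes not in genes: {sorted(unknown)}")
    rng = rng or np.random.default_rng(child_seed(seed, "expression"))
    tissues = [f"tissue{i:02d}" for i in range(1, n_tissues + 1)]
    n_immune = max(2, round(n_tissues * 5 / 32))
    flags = {t: ("immune" if i < n_immune else "non_immune")
             for i, t in enumerate(tissues)}
    values = rng.lognormal(mean=1.0, sigma=0.4, size=(len(genes), n_tissues))
    df = pd.DataFrame(values, index=list(genes), columns=tissues)
    homes: dict[str, str] = {}
    for g in ts_genes:
        home = tissues[rng.integers(n_tissues)]
        rest = df.loc[g].drop(home).sum()
        df.loc[g, home] = rest * ts_share / (1 - ts_share)
        homes[g] = home
    return df, flags, homes


def generate_compendium(genes: Sequence[str],
                        modules: Mapping[str, Sequence[str]],
                        n_samples: int = 60, seed: int = 0,
                        loading: float = 3.0,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Expression compendium (genes x samples) with planted co-expression.

    Members of each module share a latent sample factor with the given
    loading over unit noise, so module members are strongly mutually
    correlated and rank first for each other under the correlation
    provider.
    """
    rng = rng or np.random.default_rng(child_seed(seed, "compendium"))
    samples = [f"sample{i:03d}" for i in range(1, n_samples + 1)]
    X = rng.normal(size=(len(genes), n_samples))
    df = pd.DataFrame(X, index=list(genes), columns=samples)
    for module_genes in modules.values():
        factor = rng.normal(size=n_samples)
        for g in module_genes:
            df.loc[g] = df.loc[g] + loading * factor
    return df


def generate_pwm(tf_symbol: str, length: int = 14, seed: int = 0,
                 dominant: float = 0.97,
                 rng: np.random.Generator | None = None) -> PWM:
    """Information-rich synthetic PWM (one dominant base per position).

    At the defaults the consensus scores ~1.96 bits per position (27 bits
    over 14 positions) against a uniform background, well above the
    stringent site threshold of 10, while random 2 kb sequence rarely
    reaches it.
    """
    rng = rng or np.random.default_rng(child_seed(seed, "pwms"))
    mat = np.full((length, 4), (1 - dominant) / 3)
    mat[np.arange(length), rng.integers(0, 4, size=length)] = dominant
    return PWM(matrix=mat, motif_id=f"M_{tf_symbol}", tf_symbol=tf_symbol)


def generate_promoters(genes: Sequence[str], length: int = 2000,
                       planted_sites: Mapping[str, Sequence[tuple[PWM, int]]] | None = None,
                       seed: int = 0, gc: float = 0.5,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[PromoterSet, dict[str, list[dict]]]:
    """Random promoters with consensus motif instances planted.

    Sites are inserted at non-overlapping random offsets on random strands;
    the returned truth maps gene -> list of planted site descriptions.
    """
    planted_sites = dict(planted_sites or {})
    rng = rng or np.random.default_rng(child_seed(seed, "promoters"))
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    promoters = PromoterSet()
    truth: dict[str, list[dict]] = {}
    from .motif_scan import reverse_complement
    for gene in genes:
        seq = list(rng.choice(list(BASES), size=length, p=base_p))
        placed: list[tuple[int, int]] = []
        sites = []
        for pwm, count in planted_sites.get(gene, ()):  # plant each requested site
            L = len(pwm)
            if L > length:
                raise ValueError("motif longer than promoter")
            for _ in range(count):
                for _attempt in range(200):
                    off = int(rng.integers(0, length - L + 1))
                    if all(off + L <= s or off >= e for s, e in placed):
                        break
                else:
                    raise ValueError(f"cannot place {count} sites of "
                                     f"{pwm.motif_id} in {gene} without overlap")
                strand = "+" if rng.random() < 0.5 else "-"
                motif = pwm.consensus if strand == "+" else \
                    reverse_complement(pwm.consensus)
                seq[off:off + L] = list(motif)
                placed.append((off, off + L))
                sites.append({"pwm": pwm.motif_id, "offset": off,
                              "strand": strand})
        promoters[gene] = "".join(seq)
        if sites:
            truth[gene] = sites
    return promoters, truth


def generate_annotations(grn: CytokineGRN, seed: int = 0,
                         n_diseases: int = 4,
                         rng: np.random.Generator | None = None) -> dict:
    """Annotation tables keyed to the generated GRN.

    PSA and immune-phenotype flags are drawn with probability increasing
    in TF degree (logistic in log2 degree), mirroring the association the
    analyses are meant to detect.  Disease cytokine sets are built from the
    targets of high-degree TFs (planted enrichment); pro/anti lists are
    disjoint random cytokine subsets; cofactor and drug tables are random.
    """
    rng = rng or np.random.default_rng(child_seed(seed, "annotations"))
    deg = grn.tf_degree
    psa_flags, phen_flags = {}, {}
    for tf, d in deg.items():
        p = 1 / (1 + np.exp(-(np.log2(d) - 1.5)))
        psa_flags[tf] = bool(rng.random() < p)
        phen_flags[tf] = bool(rng.random() < p)
    cytokines = sorted(grn.cytokines)
    perm = list(rng.permutation(cytokines))
    n_pro = max(3, len(cytokines) // 8)
    pro = set(perm[:n_pro])
    anti = set(perm[n_pro:2 * n_pro])
    hubs = [tf for tf, _ in sorted(deg.items(), key=lambda kv: -kv[1])]
    disease_sets: dict[str, set[str]] = {}
    enriched_pairs = []
    for i in range(n_diseases):
        tf = hubs[i % len(hubs)]
        targets = sorted(grn.targets_of(tf))
        take = max(3, int(0.8 * len(targets)))
        chosen = set(rng.choice(targets, size=min(take, len(targets)),
                                replace=False))
        extra = [c for c in perm if c not in chosen][:2]
        disease_sets[f"disease{i + 1}"] = chosen | set(extra)
        enriched_pairs.append((tf, f"disease{i + 1}"))
    celltypes = [f"celltype{i}" for i in range(1, 6)]
    cyt_celltypes = {c: {ct for ct in celltypes if rng.random() < 0.25}
                     for c in cytokines}
    # plant one cell-type enrichment: a mid-degree TF (the hub's targets
    # are everyone's targets, which dilutes the contrast) whose targets
    # all share a dedicated cell type that no other cytokine carries
    planted_tf = min((tf for tf, d in deg.items() if d >= 4),
                     key=lambda tf: (abs(deg[tf] - 6), tf))
    for c in grn.targets_of(planted_tf):
        cyt_celltypes[c].add("celltype_planted")
    cofactors = [f"COF{i:02d}" for i in range(1, 9)]
    tf_cofactor = [(tf, cof) for tf in deg for cof in cofactors
                   if rng.random() < 0.2]
    actions = ["agonist", "activator", "antagonist", "inhibitor"]
    tf_drugs = [(tf, f"DRUG{rng.integers(100):02d}", actions[rng.integers(4)])
                for tf in deg if rng.random() < 0.3]
    return {"psa_flags": psa_flags, "phenotype_flags": phen_flags,
            "pro_list": pro, "anti_list": anti,
            "disease_sets": disease_sets, "enriched_pairs": enriched_pairs,
            "cyt_celltypes": cyt_celltypes,
            "celltype_planted": (planted_tf, "celltype_planted"),
            "tf_cofactor": tf_cofactor, "tf_drugs": tf_drugs}


_BG_WORDS = ("cells signaling pathway receptor expression analysis binding "
             "protein immune response results methods study patients levels "
             "observed increased decreased treatment control samples").split()


def generate_corpus(tf_aliases: Mapping[str, Sequence[str]],
                    cytokine_aliases: Mapping[str, Sequence[str]],
                    assay_terms: Mapping[str, Sequence[str]],
                    n_articles: int = 100, n_planted: int = 20,
                    seed: int = 0,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[ArticleRecord], list[str]]:
    """Abstract corpus with planted TF+cytokine+assay co-mentions.

    Background articles are built from a lexicon-free word soup; planted
    articles embed one alias from each of the three lexicons.  Returns
    (articles, planted article ids).
    """
    if n_planted > n_articles:
        raise ValueError("cannot plant more articles than the corpus size")
    rng = rng or np.random.default_rng(child_seed(seed, "corpus"))
    planted_idx = set(rng.choice(n_articles, size=n_planted, replace=False))
    articles, planted_ids = [], []
    tf_syms = sorted(tf_aliases)
    cyt_syms = sorted(cytokine_aliases)
    assay_cats = sorted(assay_terms)
    for i in range(n_articles):
        art_id = f"ART{i + 1:04d}"
        words = list(rng.choice(_BG_WORDS, size=40))
        if i in planted_idx:
            tf = tf_syms[rng.integers(len(tf_syms))]
            cyt = cyt_syms[rng.integers(len(cyt_syms))]
            cat = assay_cats[rng.integers(len(assay_cats))]
            for term in (
                    list(tf_aliases[tf])[rng.integers(len(tf_aliases[tf]))],
                    list(cytokine_aliases[cyt])[rng.integers(len(cytokine_aliases[cyt]))],
                    list(assay_terms[cat])[rng.integers(len(assay_terms[cat]))]):
                words.insert(int(rng.integers(len(words))), term)
            planted_ids.append(art_id)
        articles.append(ArticleRecord(art_id, " ".join(words)))
    return articles, planted_ids


@dataclass
class SyntheticWorld:
    seed: int
    grn_human: CytokineGRN
    grn_mouse: CytokineGRN
    expression: pd.DataFrame
    tissue_flags: dict[str, str]
    compendium: pd.DataFrame
    pwms: dict[str, PWM]
    promoters: PromoterSet
    annotations: dict
    corpus: list[ArticleRecord]
    truth: dict = field(default_factory=dict)


def generate_world(seed: int = 0, n_tfs: int = 40, n_cytokines: int = 60,
                   n_pred_tfs: int = 8, n_candidates_per_tf: int = 2,
                   n_ts_tfs: int = 10) -> SyntheticWorld:
    """Generate a complete, internally consistent input bundle.

    Plants, and records in ``truth``:

    * ``ts_tfs`` -- TFs whose tissue profile is concentrated in one tissue
      (TSPS >= 0.7 by construction);
    * ``planted_pdis`` -- unobserved (TF, cytokine) pairs supported by a
      co-expression module with the TF's known targets, two promoter motif
      sites, and an orthologous mouse edge (the high-confidence route);
    * ``planted_sites`` -- motif placements per promoter;
    * ``enriched_pairs`` -- (TF, disease) pairs whose disease set was built
      from the TF's targets;
    * ``planted_articles`` -- corpus articles with a TF+cytokine+assay
      co-mention.
    """
    grn_human = generate_grn(n_tfs=n_tfs, n_cytokines=n_cytokines,
                             degree_exponent=2.0, seed=seed, species="human")
    # mouse network: thinned copy of the human one (shared core) plus the
    # planted orthologous edges added below
    rng_mouse = np.random.default_rng(child_seed(seed, "mouse"))
    mouse_edges = {e for e in grn_human.pairs if rng_mouse.random() < 0.5}
    # mouse-specific PDIs absent from the human network (and, with motif-free
    # promoters, almost never predicted): keep the mouse-enrichment table
    # away from zero margins
    all_tf_names = _gene_names("TF", n_tfs)
    all_cyt_names = _gene_names("CYT", n_cytokines)
    while len(mouse_edges) < len(grn_human.pairs):
        e = (all_tf_names[rng_mouse.integers(n_tfs)],
             all_cyt_names[rng_mouse.integers(n_cytokines)])
        if e not in grn_human.pairs:
            mouse_edges.add(e)

    eligible = sorted(tf for tf, d in grn_human.tf_degree.items() if d >= 2)
    rng_grn = np.random.default_rng(child_seed(seed, "grn"))
    pred_tfs = [str(t) for t in rng_grn.choice(
        eligible, size=min(n_pred_tfs, len(eligible)), replace=False)]
    cytokines = sorted(grn_human.cytokines)
    all_cytokines = _gene_names("CYT", n_cytokines)

    planted_pdis: list[tuple[str, str]] = []
    modules: dict[str, list[str]] = {}
    pwms: dict[str, PWM] = {}
    planted_sites: dict[str, list[tuple[PWM, int]]] = {}
    rng_pwm = np.random.default_rng(child_seed(seed, "pwms"))
    for tf in pred_tfs:
        targets = sorted(grn_human.targets_of(tf))
        free = [c for c in all_cytokines if c not in targets]
        cands = [str(c) for c in rng_grn.choice(free, size=n_candidates_per_tf,
                                                replace=False)]
        pwm = generate_pwm(tf, rng=rng_pwm)
        pwms[tf] = pwm
        for c in cands:
            planted_pdis.append((tf, c))
            planted_sites.setdefault(c, []).append((pwm, 2))
            mouse_edges.add((tf, c))
        modules[tf] = targets + cands

    grn_mouse = CytokineGRN.from_edges("mouse", mouse_edges)

    tfs = _gene_names("TF", n_tfs)
    ts_tfs = [str(t) for t in np.random.default_rng(
        child_seed(seed, "expression")).choice(
            [t for t in tfs if t not in pred_tfs], size=n_ts_tfs,
            replace=False)]
    expression, tissue_flags, homes = generate_expression(
        tfs, n_tissues=34, ts_genes=ts_tfs, seed=seed)

    compendium = generate_compendium(all_cytokines, modules, seed=seed)
    promoters, site_truth = generate_promoters(
        all_cytokines, length=2000, planted_sites=planted_sites, seed=seed)
    annotations = generate_annotations(grn_human, seed=seed)
    corpus, planted_articles = generate_corpus(
        {"TFA1": ["TF-alpha 1"], "NFKB1": ["NF-kappa B"]},
        {"IL6": ["IL-6"], "IFNG": ["IFN-gamma"]},
        {"FUNCTIONAL": ["luciferase"], "CHIP": ["chromatin immunoprecipitation"]},
        seed=seed)

    truth = {"ts_tfs": ts_tfs, "ts_homes": homes,
             "planted_pdis": planted_pdis, "planted_sites": site_truth,
             "modules": modules,
             "enriched_pairs": annotations["enriched_pairs"],
             "planted_articles": planted_articles,
             "pred_tfs": pred_tfs}
    return SyntheticWorld(seed=seed, grn_human=grn_human, grn_mouse=grn_mouse,
                          expression=expression, tissue_flags=tissue_flags,
                          compendium=compendium, pwms=pwms,
                          promoters=promoters, annotations=annotations,
                          corpus=corpus, truth=truth)


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Write the bundle in the text formats the CLI commands read."""
    from .grn_model import write_interaction_table
    from .motif_scan import write_pwm
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_interaction_table(world.grn_human.records, out / "interactions_human.tsv")
    pd.DataFrame(sorted(world.grn_mouse.pairs),
                 columns=["TF", "Cytokine"]).to_csv(
        out / "interactions_mouse_pairs.tsv", sep="\t", index=False)
    world.expression.to_csv(out / "expression_tissues.tsv", sep="\t")
    pd.DataFrame(sorted(world.tissue_flags.items())).to_csv(
        out / "tissue_flags.tsv", sep="\t", header=False, index=False)
    world.compendium.to_csv(out / "expression_compendium.tsv", sep="\t")
    world.promoters.write_fasta(out / "promoters.fasta")
    pwm_dir = out / "pwms"
    pwm_dir.mkdir(exist_ok=True)
    for tf, pwm in world.pwms.items():
        write_pwm(pwm, pwm_dir / f"{tf}.txt")
    pd.DataFrame([{"id": a.article_id, "title": "", "abstract": a.text}
                  for a in world.corpus]).to_csv(
        out / "articles.tsv", sep="\t", index=False)
    ann = world.annotations
    serializable = {
        "psa_flags": ann["psa_flags"],
        "phenotype_flags": ann["phenotype_flags"],
        "pro_list": sorted(ann["pro_list"]),
        "anti_list": sorted(ann["anti_list"]),
        "disease_sets": {k: sorted(v) for k, v in ann["disease_sets"].items()},
        "cyt_celltypes": {k: sorted(v)
                          for k, v in ann["cyt_celltypes"].items()},
        "tf_cofactor": ann["tf_cofactor"],
        "tf_drugs": ann["tf_drugs"],
    }
    (out / "annotations.json").write_text(json.dumps(serializable, indent=1))
    (out / "truth.json").write_text(
        json.dumps(world.truth, indent=1, default=str))
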