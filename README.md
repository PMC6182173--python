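# cytgrn

Tools for building and analyzing a literature-curated cytokine gene
regulatory network (GRN): a bipartite network of transcription factors
(TFs) and cytokine genes, one edge per curated protein–DNA interaction
(PDI). The package is aimed at computational immunologists and systems
biologists who want to triage the literature for candidate interactions,
derive network-level and per-TF statistics from a curated interaction
table, test TF associations with cell types and diseases, and predict
novel TF–cytokine interactions from co-expression and promoter motif
evidence.

## What it computes

**Curation layer.** Articles are triaged by co-mention of a cytokine, a TF,
and an experimental assay term, using alias lexicons expanded for
hyphen/space/fused spellings and Greek-letter variants (IFN-γ ↔
IFN-gamma ↔ IFNgamma). Curated rows are merged into one record per
(TF, cytokine, species), carrying assay categories (ChIP, in vitro
binding, functional), regulatory activity, and article ids. A PDI is
*high evidence* when supported by a functional assay **and** a direct
binding assay; otherwise *low evidence*.

**Per-TF scores.**

- Tissue-specificity score, for expression shares *pᵢ* over *T* tissues
  against the uniform expectation *p* = 1/*T*:

  TSPS = Σᵢ pᵢ · log₂(pᵢ / p)   (bits; 0 = uniform, log₂ T = single tissue)

  TFs with TSPS ≥ 0.7 are classed tissue-specific (TS).
- Expression enrichment score (EES): with a pseudocount of 1, a tissue's
  enrichment is (x+1) / mean(x+1) across tissues, averaged over immune and
  over non-immune tissues.
- Inflammatory score: IS = (fraction of the TF's PDIs with canonical
  pro-inflammatory cytokines) − (fraction with anti-inflammatory
  cytokines), banded pro at IS ≥ 0.5 and anti at IS ≤ −0.5.

**Association statistics.** Pooled two-proportion z-tests for per-cell-type
TF enrichment; one-sided Fisher's exact tests over the cytokine universe
for TF–disease enrichment; Benjamini–Hochberg adjustment at FDR 0.1. The
count of shared TF–cytokine–disease triplets is tested against 1000
degree-preserving edge-switch randomizations of the bipartite network
(z-score, upper-tail p).

**Prediction.** For each TF with ≥ 2 known targets, candidate cytokines
are ranked by co-expression with the known targets (mean Fisher-z-averaged
Pearson correlation across a compendium), filtered by the presence of the
TF's motif in the candidate's 2 kb promoter (PWM log-odds ≥ 10 bits, both
strands), and tiered: *high* = ≥ 2 sites + mouse-orthologous interaction,
*medium* = ≥ 2 sites without mouse evidence or 1 site with it, *low* =
1 site without it. Enrichment of predictions among mouse-only interactions
is reported as an odds ratio with a chi-square p.

Every input the pipeline consumes can be generated synthetically with known
ground truth (`cytgrn.synthetic_data`), so all stages are testable without
downloads.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline over a
seeded synthetic world and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/07_predict_pdis.py
```

prints

```
seed 7: wrote synthetic bundle to .../results/synthetic_inputs
  human GRN: 137 PDIs, 40 TFs, 55 cytokines
  mouse GRN: 152 PDIs
  planted: 16 novel PDIs, 10 TS TFs, 20 triage articles
28 predictions ({'high': 16, 'low': 12})
planted PDIs recovered as high confidence: 16/16
mouse-evidence enrichment: OR = 38.0, chi-square p = 8.12e-28
```

i.e. every planted-but-unobserved interaction (co-expression module + two
promoter sites + mouse edge) is recovered at high confidence, and the
prediction set is strongly enriched for interactions with mouse evidence.
`analysis/06_disease_null.py` shows the network-null machinery: disease
sets built from hub-TF targets give an observed triplet count of 62
against a null of 42.2 ± 2.3 (z = 8.5).

The same statistics run on a real curation release through the CLI:

```bash
cytgrn stats --interactions interactions.tsv --species human
cytgrn predict --interactions-human human.tsv --interactions-mouse mouse.tsv \
    --expression compendium.tsv --pwms pwms/ --promoters promoters.fasta \
    --universe cytokines.txt --out predictions.tsv
```

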