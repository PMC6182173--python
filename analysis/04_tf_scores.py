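#!/usr/bin/env python
"""Per-TF scores: tissue specificity (TSPS), immune expression enrichment
(EES), and inflammatory score (IS), with recovery of planted TS TFs."""

from pathlib import Path

import pandas as pd

from cytgrn.synthetic_data import generate_world
from cytgrn.tf_scores import expression_enrichment, inflammatory_score, tsps

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    world = generate_world(seed=SEED)
    grn = world.grn_human
    ann = world.annotations
    rows = []
    for tf in sorted(set(world.expression.index) | grn.tfs):
        row = {"tf": tf, "degree": grn.tf_degree.get(tf, 0)}
        if tf in world.expression.index:
            res = tsps(world.expression.loc[tf])
            imm, non = expression_enrichment(world.expression.loc[tf],
                                             world.tissue_flags)
            row.update(tsps=round(res.tsps, 4), is_ts=res.is_ts,
                       ees_immune=round(imm, 4), ees_non_immune=round(non, 4))
        if tf in grn.tfs:
            s = inflammatory_score(grn, tf, pro_list=ann["pro_list"],
                                   anti_list=ann["anti_list"])
            row.update(inflammatory_score=round(s.is_value, 4),
                       is_band=s.band or "")
        rows.append(row)
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "tf_scores.tsv", sep="\t", index=False)

    ts_truth = set(world.truth["ts_tfs"])
    called = set(df.loc[df["is_ts"] == True, "tf"])  # noqa: E712
    print(f"TS TFs called at TSPS >= 0.7: {len(called)}; "
          f"planted: {len(ts_truth)}; recovered: {len(called & ts_truth)}")
    print(f"median immune EES: {df['ees_immune'].median():.3f}, "
          f"non-immune: {df['ees_non_immune'].median():.3f}")
    banded = df[df["is_band"].isin(["pro", "anti"])]
    print(f"TFs with |IS| >= 0.5: {len(banded)}")


if __name__ == "__main__":
    main()
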