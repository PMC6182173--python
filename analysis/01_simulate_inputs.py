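#!/usr/bin/env python
"""Generate the synthetic input bundle every downstream step reads.

Writes curated-style interaction tables, tissue expression with immune
flags, a co-expression compendium, promoters with planted motif sites,
PWMs, annotation tables, an abstract corpus, and truth.json recording all
planted structure, under results/synthetic_inputs/.
"""

from pathlib import Path

from cytgrn.synthetic_data import generate_world, write_world

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_inputs"


def main() -> None:
    world = generate_world(seed=SEED)
    write_world(world, OUT)
    print(f"seed {SEED}: wrote synthetic bundle to {OUT}")
    print(f"  human GRN: {world.grn_human.n_edges} PDIs, "
          f"{len(world.grn_human.tfs)} TFs, "
          f"{len(world.grn_human.cytokines)} cytokines")
    print(f"  mouse GRN: {world.grn_mouse.n_edges} PDIs")
    print(f"  planted: {len(world.truth['planted_pdis'])} novel PDIs, "
          f"{len(world.truth['ts_tfs'])} TS TFs, "
          f"{len(world.truth['planted_articles'])} triage articles")


if __name__ == "__main__":
    main()
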