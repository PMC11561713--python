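"""Regenerate the bundled test fixtures (pinned seeds; never hand-edit).

Writes, under tests/fixtures/:
  leaf_move_left.nwk / leaf_move_right.nwk
      the worked-example pair of rooted 4-taxon trees whose non-trivial
      clade sets are {{a,b},{a,b,c}} and {{b,c},{b,c,d}} — a single-leaf
      relocation that maximises Robinson-Foulds while the Matching
      Cluster distance stays at 4;
  exact50_model.nwk / exact50_sources.nwk / exact50_manifest.txt
      a 50-taxon exact-recovery instance (birth-death model tree,
      centroid-edge decomposition with max subset size 20, induced
      compatible source trees).

Run from the repository root:  python scripts/make_fixtures.py
"""

from pathlib import Path

from spectral_supertree import (
    BirthDeathConfig,
    ScalingConfig,
    decompose_taxa,
    make_exact_dataset,
    parse_newick,
    simulate_model_tree,
)

SEED = 2024
N_TAXA = 50
MAX_SIZE = 20

OUT = Path(__file__).resolve().parent.parent / "tests" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    left = parse_newick("(((a,b),c),d);")
    right = parse_newick("(a,((b,c),d));")
    (OUT / "leaf_move_left.nwk").write_text(left.newick() + "\n")
    (OUT / "leaf_move_right.nwk").write_text(right.newick() + "\n")

    model = simulate_model_tree(
        BirthDeathConfig(n_taxa=N_TAXA, seed=SEED), ScalingConfig(seed=SEED + 1)
    )
    plan = decompose_taxa(model, max_size=MAX_SIZE, seed=SEED)
    sources = make_exact_dataset(model, plan)
    (OUT / "exact50_model.nwk").write_text(model.newick() + "\n")
    (OUT / "exact50_sources.nwk").write_text(
        "".join(t.newick() + "\n" for t in sources)
    )
    (OUT / "exact50_manifest.txt").write_text(
        f"seed\t{SEED}\nn_taxa\t{N_TAXA}\nbirth_rate\t1.0\ndeath_rate\t0.2\n"
        f"max_size\t{MAX_SIZE}\nn_subsets\t{len(plan.subsets)}\n"
        f"subset_sizes\t{','.join(str(len(s)) for s in plan.subsets)}\n"
    )
    print(f"wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
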