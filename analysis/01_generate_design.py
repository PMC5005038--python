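#!/usr/bin/env python
"""Derive the task geometry and a counterbalanced trial design.

Builds the 18-building hexagonal layout, enumerates the 60 start->target
combinations on the 30-degree direction grid, applies the seeded exclusion
of the oversampled main-axis directions (48 remain, every direction sampled
four times) and generates the 96-trial, 4-block design.  Writes the layout,
combination, trial and pair-label tables under results/design/ and prints
the counts every downstream analysis conditions on.
"""

from pathlib import Path

from hexdir import city, io

OUT = Path("results/design")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = city.build_city_layout()
    combos = city.enumerate_combinations(layout)
    combos48 = city.apply_exclusions(combos, SEED)
    trials = city.generate_design(combos48, seed=SEED + 1)
    labels = city.label_pairs(trials, layout)

    layout.to_json(OUT / "city_layout.json")
    io.save_table(combos, OUT / "combinations60.tsv")
    io.save_table(combos48, OUT / "combinations48.tsv")
    io.save_table(trials, OUT / "trials.tsv")
    io.save_table(labels, OUT / "pair_labels.tsv")

    inner = labels.both_inner_target
    print(f"buildings: {len(layout.buildings)} ({len(layout.inner_ids)} inner starts)")
    print(f"combinations: {len(combos)} -> {len(combos48)} after exclusion")
    print(f"trials: {len(trials)} in {trials.block.nunique()} blocks; "
          f"violations: {city.validate_design(trials) or 'none'}")
    print(f"pairs: {len(labels)}; mod-60 split "
          f"{(labels.rem60 == 0).sum()}/{(labels.rem60 == 30).sum()}")
    print(f"both-inner-target pairs: {inner.sum()} "
          f"({100 * inner.sum() / (labels.rem60 == 0).sum():.2f}% of the 0-mod-60 "
          f"condition, {(inner & (labels.rem60 == 30)).sum()} in 30-mod-60)")


if __name__ == "__main__":
    main()
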