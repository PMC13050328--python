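"""Quantify the somatic niche around each germ-cell subtype.

The niche of a target pixel is its 8-neighborhood on the grid (Chebyshev
radius 1, center excluded). Neighborhoods are pooled over all targets of a
subtype, deduplicated, and tallied by cell type — targets themselves are
excluded from the tally, so the composition describes the surrounding
somatic microenvironment.
"""

from spatgonad import (
    CellLabelTable,
    default_blueprint,
    niche_composition,
    select_neighborhood,
    simulate_section,
)

blueprint = default_blueprint(seed=4)
sample, truth = simulate_section(blueprint, "E50", seed=4)
labels = CellLabelTable.from_truth(truth.pixels)

selections = []
for subtype in sorted(set(labels.df["germ_subtype"].dropna())):
    targets = labels.germ_pixels(subtype)
    sel = select_neighborhood(sample, targets, r=1, target_subtype=subtype)
    selections.append(sel)
    print(f"{subtype}: {len(targets)} targets, "
          f"{len(sel.tally_ids())} neighbor pixels")

table = niche_composition(selections, labels)
print("\nniche composition (proportion of neighbor pixels per cell type):")
for subtype in sorted(set(labels.df["germ_subtype"].dropna())):
    props = table.proportions(subtype, "E50").sort_values(ascending=False)
    desc = ", ".join(f"{ct} {p:.2f}" for ct, p in props.items())
    print(f"  {subtype}: {desc}")
# At E50 the germ cells sit near the cortex, so their niches are dominated
# by the cortical supporting cells (PreGC_II, OSEC).
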