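"""Measure a dendritic tree: parse an SWC file and compute its features.

Builds a small synthetic basal arbor, round-trips it through the SWC text
format, and prints the five per-tree features used throughout the package.
"""

from dendrofire import (
    BASAL,
    TreeRecipe,
    feature_vector,
    generate_tree,
    parse_swc_text,
    to_swc_text,
)

tree = generate_tree(TreeRecipe(n_stems=4, n_branches=12,
                                segment_length_mean=90.0, seed=11))
reparsed = parse_swc_text(to_swc_text(tree))  # identical point table

fv = feature_vector(reparsed, structure=BASAL)
for key, value in fv.as_dict().items():
    print(f"{key:20s} {value:10.3f}")

# total_length_um / volume_um3 / branch_number describe the tree's size,
# median_diameter_um its calibre, and mep its mean electrotonic path
# length: the average number of length constants between a dendritic tip
# and the soma (larger = electrically more remote tips).
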