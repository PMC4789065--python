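"""Enumerate HLAC templates and show how the count grows with order/window.

The 25-template set (order <= 2, 3 x 3) is the working set of the feature
extractor; proportional scaling extends its spatial reach without changing
the count.
"""

import histotex as ht

for max_order, window in [(0, 3), (1, 3), (2, 3), (8, 3), (2, 5)]:
    ms = ht.enumerate_masks(max_order, window)
    print(f"order <= {max_order}, window {window}x{window}: {len(ms):4d} templates")

masks = ht.default_masks()
print("\nfirst five canonical templates of the 25-mask set:")
for name, mask in zip(masks.names()[:5], masks):
    print(f"  {name}: {mask}")

ext = ht.scale_masks(masks, 5)
print(f"\nextended to radius 5: still {len(ext)} templates;"
      f" m02 offsets {masks.masks[1]} -> {ext.masks[1]}")
# The counts above are equivalence-class counts: translated copies of a
# template are merged because HLAC sums over all image positions.
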