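"""Threshold a suitability map and measure suitable river length.

Converts the averaged suitability map into a binary habitat mask using
the mean predicted probability at presence cells, polygonizes it, and
clips a synthetic dendritic river network (Strahler-ordered) to the
suitable polygons, summing great-circle lengths.
"""

import riversdm as r

geom = r.synthetic.default_geometry()
truth = r.synthetic.default_truth(seed=0)
bio = r.derive_bioclim(r.synthetic.make_climate(geom, seed=0))
stack = r.EnvStack({"bio_1": bio["bio_1"], "bio_12": bio["bio_12"]},
                   {"bio_1": "continuous", "bio_12": "continuous"}, geom)
occ = r.clean_occurrences(
    r.synthetic.sample_occurrences(stack, truth, n=200, seed=1), stack)
background = r.sample_background(stack, 2000, seed=2)

feats = r.build_features(stack, occ.cells, background)
model = r.fit(feats, occ.cells, background, stack)
smap = r.predict(model, stack)

t = r.mean_presence_threshold(smap, occ.cells)
mask = r.polygonize(r.binarize(smap, t))
print(f"threshold t = {t:.3f} (mean predicted probability at presences)")
print(f"suitable cells: {mask.suitable_count} of "
      f"{stack.validity_mask.sum()}; regions: {len(mask.polygons)}")

network, _ = r.synthetic.make_rivers(geom, seed=5)
print(f"river network: {len(network)} reaches, "
      f"{network.total_length_km():.0f} km, "
      f"orders up to {int(network.lines['order'].max())}")

result = r.suitable_river_length(network, mask, min_order=1)
print(f"suitable river length L = {result.total_km:.1f} km "
      "(order-filtered network clipped to habitat polygons)")
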