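"""Assemble the wet, dry and bi-seasonal feature stacks.

Each single-season stack carries, per band: reflectance plus 3x3 moving-window
mean/range/standard deviation, then NDVI, then the terrain model — 34
features; the bi-seasonal stack is their union with one shared terrain
feature — 67.
"""

from coastmap import (
    FeatureSetSpec,
    SimulationConfig,
    assemble,
    generate_class_map,
    generate_terrain,
    render_scene,
)

cfg = SimulationConfig(nrows=96, ncols=96, seed=3)
terrain = generate_terrain(cfg)
class_map = generate_class_map(terrain, cfg)
scenes = {s: render_scene(class_map, s, cfg) for s in ("wet", "dry")}

for name in ("wet", "dry", "biseasonal"):
    stack = assemble(FeatureSetSpec(name), scenes, terrain.elevation)
    print(f"{name:11s} -> {stack.n_features} features")

stack = assemble(FeatureSetSpec("wet"), scenes, terrain.elevation)
print("\nwet-season feature order (first 10):", ", ".join(stack.descriptors[:10]))
print("last:", stack.descriptors[-1])
# 34 / 34 / 67: the accounting a paired feature-set comparison relies on.
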