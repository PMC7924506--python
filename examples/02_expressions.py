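"""Derive model-ready layers with the map-calculator expression language.

Pre-processing expressions are stored as strings in case-study manifests and
evaluated safely by a tree-walking interpreter over named layers — the same
mechanism a case-study administrator uses to document how each raw dataset
was turned into a model input.
"""

import numpy as np

from mspkit import GridLayer, evaluate_expression, make_grid, parse_expression

grid = make_grid((0, 0, 5_000, 5_000), 500, "EPSG:3035")
rng = np.random.default_rng(0)

registry = {
    "shipping": GridLayer("shipping", rng.gamma(1.0, 2.0, grid.shape), grid),
    "ports": GridLayer("ports", (rng.uniform(size=grid.shape) > 0.9) * 5.0, grid),
}

# compress heavy-tailed traffic intensity, add port activity, rescale to [0, 1]
expr = parse_expression("norm(log1p(shipping + ports))")
layer = evaluate_expression(expr, registry)
print(f"'{expr.source_text}' -> range [{np.nanmin(layer.values):.3f}, "
      f"{np.nanmax(layer.values):.3f}]")

# comparisons yield 0/1 masks that compose with arithmetic
busy = evaluate_expression(parse_expression("where(shipping > 2, 1, 0)"), registry)
print(f"cells with heavy traffic: {int(busy.values.sum())} of {busy.values.size}")

# the whitelist is closed: anything else is rejected before evaluation
try:
    parse_expression("__import__(os)")
except Exception as exc:
    print(f"rejected unsafe expression: {exc}")
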