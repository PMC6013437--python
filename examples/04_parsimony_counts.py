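"""Count state changes, origins and reversals under Fitch parsimony.

The number of gains of a derived state versus reversals is not unique among
most-parsimonious reconstructions; bounds come from resolving equivocal
nodes all-derived vs all-ancestral.  The two bounds always satisfy
min_origins + max_reversals = max_origins + min_reversals = total changes.
"""

import mkhet

sizes = {f"P{i}": 60 for i in range(1, 6)}
cfg = mkhet.SimulationConfig(seed=23, partition_sizes=sizes)
bundle = mkhet.simulate_study(cfg)
scheme = mkhet.PartitionScheme.from_clades(bundle.tree, list(sizes))

for char in bundle.matrix.characters:
    column = bundle.matrix.column(char)
    res = mkhet.minmax_origins_reversals(bundle.index, column, derived_state=1)
    low, high = mkhet.origin_reversal_ratio_range(res)
    print(
        f"{char:16s} changes={res.length:3d}  origins {res.min_origins}-{res.max_origins}"
        f"  reversals {res.min_reversals}-{res.max_reversals}  ratio {low}-{high}"
    )

res = mkhet.minmax_origins_reversals(bundle.index, bundle.matrix.column("merism"), 1)
print("\nper-partition breakdown (merism, all-derived resolution):")
print(mkhet.partition_breakdown(res, scheme, "derived").to_string(index=False))
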