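"""Relationship measures between a training (full) set and a testing set.

Computes the eight optimal-design criteria — PEV mean/max, D-, G- and
A-optimality, CD mean/max and the negated marker distance — for one random
split of lines into a full set and sparse sets.
"""

import sparsemet as sm

cfg = sm.SimConfig(n_lines=60, n_markers=500, seed=7)
markers, _ = sm.filter_markers(sm.simulate_marker_matrix(cfg))
g = sm.condition_and_invert(sm.vanraden_g(markers))
P = sm.pca_scores(g)
Dst = sm.distance_matrix(markers)

spec = sm.SparseDesignSpec("DEMO", n_full=20, n_sparse_sets=5,
                           n_tested_env_per_ss=4, balanced=True, n_lines=60)
alloc = sm.allocate_lines(spec, list(g.line_ids), seed=1)
rm = sm.compute_all_rms(P, Dst, alloc, lam=1e-5)

print(f"full set: {len(alloc.full_set)} lines; "
      f"test set: {len(alloc.sparse_lines)} lines")
for name, value in rm.as_dict().items():
    print(f"  {name:8s} = {value:12.4f}")
# Smaller PEV/GOPTPEV/DOPT and larger CD/NDT mean the full set represents
# the sparse lines better; CD values live in [0, 1].
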