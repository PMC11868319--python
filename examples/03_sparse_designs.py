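"""The 14 built-in sparse phenotyping designs and their plot savings.

Each design splits 304 lines into a full set (tested in all 5 environments)
and sparse sets tested in 0-4 environments; the saved-plot percentage
follows directly from the design parameters.
"""

import sparsemet as sm

print(f"{'design':>7} {'full':>5} {'sets':>5} {'tested env':>10} "
      f"{'balanced':>9} {'% plots saved':>14}")
for spec in sm.builtin_designs():
    print(f"{spec.design_id:>7} {spec.n_full:>5} {spec.n_sparse_sets:>5} "
          f"{spec.n_tested_env_per_ss:>10} {str(spec.balanced):>9} "
          f"{sm.plots_saved_fraction(spec):>14.2f}")

alloc = sm.allocate_lines(sm.get_design("SP1"),
                          [f"L{i + 1:04d}" for i in range(304)], seed=3)
print("\nSP1 example allocation:")
print(f"  full set {len(alloc.full_set)} lines; "
      f"{len(alloc.sparse_sets)} sparse sets of "
      f"{len(alloc.sparse_sets[0])} lines")
for i, tested in enumerate(alloc.ss_env_map):
    untested = sorted(set(range(5)) - set(tested))
    print(f"  SS{i + 1}: untested environment index {untested}")
# Under the balanced SP1 design each environment is left untested by
# exactly one sparse set.
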