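"""How grid size and density change the number of identifiable motor units.

Runs the pairwise-NMSD identifiability analysis for a small ladder of grid
configurations (all derived from one shared 2-mm master lattice) and prints
the identifiable percentage and the mean depth of identifiable units per
configuration.  Larger and denser grids discriminate more units.
"""

import mugrid as mg
from mugrid.discriminability import sweep_shared_master

pool = mg.build_pool(count=200, seed=1)
df = sweep_shared_master(
    pool,
    lengths_cm=[4, 7, 10],
    ieds_mm=[2, 8, 36],
    fiber_subsample=100,
    seed=2,
)
table = df.pivot_table(index="ied_mm", columns="length_cm", values="pct_identifiable")
print("identifiable % (rows: IED mm, columns: grid length cm at 3.6-cm width)")
print(table.round(1).to_string())
print()
print("mean depth of identifiable units (mm):")
print(
    df.pivot_table(index="ied_mm", columns="length_cm", values="mean_depth_mm")
    .round(2)
    .to_string()
)
print()
print("Each percentage is the share of the 200 simulated units whose")
print("multichannel MUAP differs from every other unit's by at least 5%")
print("normalized mean-square difference after time alignment — the upper")
print("bound on what any decomposition algorithm could identify.")
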