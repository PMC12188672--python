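"""From published cone parameters to inter-node distances.

The packaged case-study tables give, per pair of atorvastatin species, the
interaction volume V (total significant transfer entropy) and the two
information-rate radii; the truncated-cone height
h = 3V / (pi (r_X^2 + r_X r_Y + r_Y^2)) turns them into a distance, and the
stated propagation formula yields its uncertainty.
"""

from latentgeo import cone_height, cone_height_error
from latentgeo.fixtures import distance_matrix_from_fixture, load_fixture

cones = load_fixture("cone_individual_1")
row = cones[(cones.X == "AS") & (cones.Y == "ASL")].iloc[0]
h = cone_height(row.V, row.r_x, row.r_y)
dh = cone_height_error(row.V, row.dV, row.r_x, row.dr_x, row.r_y, row.dr_y)
print(f"AS-ASL: V = {row.V} bits, r_X = {row.r_x}, r_Y = {row.r_y}")
print(f"  height h = {h:.6f}  (published 0.000166)")
print(f"  error  dh = {dh:.1e}  (published 3.7e-05)")

dm = distance_matrix_from_fixture(1)
print(f"\ndistance matrix over {dm.labels}:")
print("  zero (no interaction) at AS-ASoOH:", dm.entry("AS", "ASoOH"))
print("  largest distance:", dm.D.max(), "(ASLpOH-ASLoOH)")
# Distances grow when a given information volume must pass through narrow
# bases: weak emitters far apart are the candidate bottlenecks.
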