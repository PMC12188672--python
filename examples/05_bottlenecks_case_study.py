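"""Flag bottleneck reactions of the case-study network.

Over the five reactions of the simplified atorvastatin scheme, triangle
(Zack) thresholds split the information-rate radii into small/large and the
hyperbolically embedded distances into near/far; a reaction whose both
radii are small and whose embedded distance is large waits on a
low-propensity long-range link — a bottleneck.
"""

from latentgeo import classify_bottlenecks, hyperbolic_embed
from latentgeo.fixtures import (
    cone_models_from_fixture,
    distance_matrix_from_fixture,
    load_reaction_edges,
)

edges = load_reaction_edges()
cones = cone_models_from_fixture(1, pairs=edges)
embedding = hyperbolic_embed(distance_matrix_from_fixture(1), m=2, k=-1.0)

report = classify_bottlenecks(cones, embedding)
print(f"radius threshold    : {report.thresholds.r_threshold:.4f}")
print(f"distance threshold  : {report.thresholds.h_threshold:.4f}")
for rec in report.records:
    mark = "  <-- bottleneck" if rec.is_bottleneck else ""
    print(
        f"{rec.pair[0]:>5s}-{rec.pair[1]:<7s} r_X={rec.r_x:<9.5f} "
        f"r_Y={rec.r_y:<9.5f} h*={rec.h_star:.4f}{mark}"
    )
# The two CYP-mediated lactone hydroxylations (ASL -> ASLpOH, ASL -> ASLoOH)
# are the flagged bottlenecks: both partners emit information slowly and sit
# far apart in the latent metric space.
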