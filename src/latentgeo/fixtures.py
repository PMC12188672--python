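"""Packaged per-individual cone tables, heights and the reaction graph.

The case-study tables ship with the package as plain CSV: for each of
three individuals, the per-pair truncated-cone parameters (V, ΔV, r_X,
Δr_X, r_Y, Δr_Y) over the six atorvastatin species (AS, ASL, ASpOH,
ASoOH, ASLpOH, ASLoOH) and the corresponding heights (h, Δh) with their
no-interaction / high-SE flags, plus the five reaction edges of the
simplified metabolic scheme (lactonization of AS and the CYP-mediated
hydroxylations of AS and ASL).

One printed height (Individual 2, AS–ASoOH) is inconsistent with the cone
parameters of the same table (the volume rule yields ≈0.0022, not the
printed 0.000145); the row is flagged ``inconsistent_with_cone_table`` in
the packaged CSV and should be excluded from numerical cross-checks.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .cone import ConeModel, DistanceMatrix, assemble_distance_matrix

__all__ = [
    "SPECIES",
    "FIXTURE_NAMES",
    "load_fixture",
    "load_reaction_edges",
    "cone_models_from_fixture",
    "distance_matrix_from_fixture",
]

#: node labels of the case-study network, in canonical order
SPECIES = ["AS", "ASL", "ASpOH", "ASoOH", "ASLpOH", "ASLoOH"]

FIXTURE_NAMES = tuple(
    f"{kind}_individual_{i}" for kind in ("cone", "heights") for i in (1, 2, 3)
)


def _data_path(filename: str):
    return files("latentgeo.data").joinpath(filename)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by registry name.

    Names: ``cone_individual_{1,2,3}`` (V, ΔV, radii and their errors) and
    ``heights_individual_{1,2,3}`` (h, Δh, flag).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        )
    with _data_path(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    if "flag" in df.columns:
        df["flag"] = df["flag"].astype(str)
    return df


def load_reaction_edges() -> list[tuple[str, str]]:
    """The five reaction edges of the simplified metabolic scheme."""
    with _data_path("reaction_edges.csv").open() as fh:
        df = pd.read_csv(fh)
    return [tuple(r) for r in df[["X", "Y"]].itertuples(index=False)]


def cone_models_from_fixture(
    individual: int, pairs: list[tuple[str, str]] | None = None
) -> list[ConeModel]:
    """Per-pair :class:`ConeModel` objects from the packaged tables.

    Combines the cone table (volumes, radii) with the heights table
    (h, Δh, flags) of one individual; ``pairs`` restricts the result, e.g.
    to the reaction edges.
    """
    cones = load_fixture(f"cone_individual_{individual}")
    heights = load_fixture(f"heights_individual_{individual}")
    merged = cones.merge(heights, on=["X", "Y"], validate="one_to_one")
    wanted = None
    if pairs is not None:
        wanted = {frozenset(p) for p in pairs}
    models = []
    for row in merged.itertuples(index=False):
        if wanted is not None and frozenset((row.X, row.Y)) not in wanted:
            continue
        interacting = row.V > 0
        models.append(
            ConeModel(
                pair=(row.X, row.Y),
                V=row.V,
                dV=row.dV,
                r_x=row.r_x,
                dr_x=row.dr_x,
                r_y=row.r_y,
                dr_y=row.dr_y,
                h=row.h,
                dh=row.dh,
                interacting=bool(interacting),
                high_se="high_se" in row.flag,
            )
        )
    return models


def distance_matrix_from_fixture(individual: int) -> DistanceMatrix:
    """The 6×6 distance matrix D = {h_ij} of one individual.

    Zero diagonal; zeros with the no-interaction flag where the volume rule
    found no significant information flow.
    """
    models = cone_models_from_fixture(individual)
    return assemble_distance_matrix(models, SPECIES)
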