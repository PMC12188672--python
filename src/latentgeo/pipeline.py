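"""End-to-end orchestration: time series → TE → distances → geometry → bottlenecks.

The pipeline densifies each trajectory with the FMM spline, estimates
directed transfer entropy with surrogate significance for every pair under
study, converts each pair to a truncated-cone distance with propagated
uncertainty, assembles the distance matrix, embeds it into the requested
spaces, selects the minimum-stress geometry and classifies bottlenecks.
Every stage persists its artifact (delimited text or JSON) into the output
directory together with a run manifest recording package version, seeds
and a hash of the configuration, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bottlenecks import BottleneckReport, classify_bottlenecks
from .cone import (
    ConeConfig,
    ConeModel,
    DistanceMatrix,
    all_unordered_pairs,
    assemble_distance_matrix,
    estimate_pair,
)
from .embedding import (
    EmbeddingResult,
    cmds_embed,
    hyperbolic_embed,
    laplacian_spectral_embed,
    select_geometry,
    spherical_embed,
)
from .exceptions import EmbeddingError, PipelineError
from .timeseries import TimeSeriesSet, fmm_spline, read_timeseries, write_timeseries

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run."""

    input_path: str
    output_dir: str
    edges_path: str | None = None  # two-column edge list; None = all pairs
    time_column: str = "time"
    error_suffix: str = "_sd"
    n_out: int = 100  # spline grid size
    te: ConeConfig = field(default_factory=ConeConfig)
    spaces: tuple[str, ...] = ("euclidean", "hyperbolic", "spherical")
    k_hyperbolic: float = -1.0
    k_spherical: float = 1.0
    m: int = 2
    stress_convention: str = "ordered"
    euclidean_method: str = "laplacian"  # or "cmds"
    h_condition: str = "large"
    bottleneck_bins: int = 256
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        te_raw = raw.pop("te", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "te"})
        cfg.te = ConeConfig(**te_raw)
        if isinstance(cfg.spaces, list):
            cfg.spaces = tuple(cfg.spaces)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spaces"] = list(self.spaces)
        return d


@dataclass
class PipelineResult:
    """All artifacts of one run, in memory."""

    dense: TimeSeriesSet
    cones: list[ConeModel]
    distance_matrix: DistanceMatrix
    embeddings: list[EmbeddingResult]
    selected: EmbeddingResult
    bottlenecks: BottleneckReport
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_edges(path: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PipelineError("input", f"edge list {path} needs two columns")
    cols = df.columns[:2]
    return [tuple(r) for r in df[cols].itertuples(index=False)]


def write_distance_matrix(dm: DistanceMatrix, outdir: Path) -> None:
    """Square labeled matrix as CSV plus a JSON sidecar of flags and Δh."""
    pd.DataFrame(dm.D, index=dm.labels, columns=dm.labels).to_csv(
        outdir / "distance_matrix.csv"
    )
    sidecar = {
        "labels": dm.labels,
        "dD": None if dm.dD is None else dm.dD.tolist(),
        "no_interaction": dm.no_interaction.tolist(),
        "high_se": dm.high_se.tolist(),
    }
    (outdir / "distance_matrix_flags.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_distance_matrix(path: str) -> DistanceMatrix:
    """Inverse of :func:`write_distance_matrix` (sidecar optional)."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    dm = DistanceMatrix(labels, df.to_numpy(dtype=float))
    sidecar = Path(path).with_name("distance_matrix_flags.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if raw.get("dD") is not None:
            dm.dD = np.asarray(raw["dD"], dtype=float)
        dm.no_interaction = np.asarray(raw["no_interaction"], dtype=bool)
        dm.high_se = np.asarray(raw["high_se"], dtype=bool)
    return dm


def write_cone_table(cones: list[ConeModel], outdir: Path) -> None:
    rows = []
    for c in cones:
        rows.append(
            {
                "X": c.pair[0], "Y": c.pair[1], "V": c.V, "dV": c.dV,
                "r_x": c.r_x, "dr_x": c.dr_x, "r_y": c.r_y, "dr_y": c.dr_y,
                "h": c.h, "dh": c.dh,
                "flag": "no_interaction" if not c.interacting
                else ("high_se" if c.high_se else ""),
                "fallback_used": c.fallback_used,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "cone_table.csv", index=False)


def write_embedding(emb: EmbeddingResult, outdir: Path) -> None:
    cols = {f"x{i + 1}": emb.coords[:, i] for i in range(emb.coords.shape[1])}
    if emb.poincare is not None:
        cols["u1"] = emb.poincare[:, 0]
        if emb.poincare.shape[1] > 1:
            cols["u2"] = emb.poincare[:, 1]
    df = pd.DataFrame({"node": emb.labels, **cols})
    df.to_csv(outdir / f"embedding_{emb.space}.csv", index=False)


def embed_distance_matrix(
    dm: DistanceMatrix, config: PipelineConfig
) -> list[EmbeddingResult]:
    """All requested embeddings of a distance matrix.

    A space in which no embedding exists for this matrix (e.g. spherical
    when distances exceed pi/sqrt(k)) is skipped with a warning; at least
    one space must succeed.
    """
    results = []
    for space in config.spaces:
        try:
            if space == "euclidean":
                embedder = (
                    laplacian_spectral_embed
                    if config.euclidean_method == "laplacian"
                    else cmds_embed
                )
                results.append(
                    embedder(
                        dm, m=config.m, stress_convention=config.stress_convention
                    )
                )
            elif space == "hyperbolic":
                results.append(
                    hyperbolic_embed(
                        dm, m=config.m, k=config.k_hyperbolic,
                        stress_convention=config.stress_convention,
                    )
                )
            elif space == "spherical":
                results.append(
                    spherical_embed(
                        dm, m=config.m, k=config.k_spherical,
                        stress_convention=config.stress_convention,
                    )
                )
            else:
                raise PipelineError("embed", f"unknown space {space!r}")
        except EmbeddingError as err:
            logger.warning("no %s embedding for this matrix: %s", space, err)
    if not results:
        raise PipelineError("embed", "no requested space admits an embedding")
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and persist all artifacts.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts produced before the failure remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs ---------------------------------------------------
    if not Path(config.input_path).exists():
        raise PipelineError("input", f"missing input file {config.input_path}")
    edges = None
    if config.edges_path is not None:
        if not Path(config.edges_path).exists():
            raise PipelineError("input", f"missing edge list {config.edges_path}")
        edges = _read_edges(config.edges_path)

    if config.seed is not None and config.te.seed is None:
        config.te.seed = config.seed

    # -- stage 1: read + spline -------------------------------------------
    try:
        tss = read_timeseries(
            config.input_path,
            time_column=config.time_column,
            error_suffix=config.error_suffix,
        )
        curves = {s.label: fmm_spline(s, n_out=config.n_out) for s in tss}
    except Exception as err:
        raise PipelineError("interpolate", str(err)) from err
    dense = TimeSeriesSet([c.to_timeseries() for c in curves.values()])
    write_timeseries(dense, str(outdir / "dense_series.csv"))

    # -- stage 2: TE + cones ----------------------------------------------
    pairs = edges if edges is not None else all_unordered_pairs(dense.labels)
    cones: list[ConeModel] = []
    pair_seeds = np.random.SeedSequence(config.te.seed).spawn(len(pairs))
    try:
        for (a, b), seed in zip(pairs, pair_seeds):
            cfg = dataclasses.replace(config.te, seed=seed)
            cones.append(estimate_pair(curves[a], curves[b], config=cfg))
    except Exception as err:
        raise PipelineError("te", str(err)) from err
    write_cone_table(cones, outdir)

    # -- stage 3: distance matrix -----------------------------------------
    try:
        dm = assemble_distance_matrix(cones, dense.labels)
    except Exception as err:
        raise PipelineError("distances", str(err)) from err
    write_distance_matrix(dm, outdir)

    # -- stage 4: embeddings + geometry selection --------------------------
    try:
        embeddings = embed_distance_matrix(dm, config)
        selected = select_geometry(embeddings)
    except Exception as err:
        raise PipelineError("embed", str(err)) from err
    for emb in embeddings:
        write_embedding(emb, outdir)
    stress_table = {
        e.space: {"k": e.k, "m": e.m, "stress": e.stress} for e in embeddings
    }
    (outdir / "stress_summary.json").write_text(
        json.dumps({"stresses": stress_table, "selected": selected.space}, indent=1)
    )

    # -- stage 5: bottlenecks ---------------------------------------------
    try:
        report = classify_bottlenecks(
            cones,
            selected,
            h_condition=config.h_condition,
            n_bins=config.bottleneck_bins,
        )
    except Exception as err:
        raise PipelineError("bottlenecks", str(err)) from err
    (outdir / "bottleneck_report.json").write_text(
        json.dumps(report.to_dict(), indent=1)
    )

    manifest = {
        "package": "latentgeo",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "te_seed": None
        if config.te.seed is None
        else repr(config.te.seed),
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "n_pairs": len(pairs),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
    return PipelineResult(
        dense=dense,
        cones=cones,
        distance_matrix=dm,
        embeddings=embeddings,
        selected=selected,
        bottlenecks=report,
        manifest=manifest,
    )
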