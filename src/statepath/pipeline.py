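"""End-to-end pipeline wiring: preprocess -> landmarks -> network -> trim
-> (optional) ordering, signature scoring and pseudotime DE.

The declarative configuration (TOML on disk, :class:`PipelineConfig` in
memory) names the inputs, the landmark cutoffs, the path to order along and
the stochastic seeds.  Every stage's output is serialized to the output
directory and a JSON manifest records parameters and seeds, so any stage
can be re-run from its predecessors' files.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    ExpressionMatrix,
    filter_low_expression,
    log_transform,
    read_annotation,
    read_expression,
    read_signature,
    subset_genes,
    write_expression,
)
from .landmarks import LandmarkParams, LandmarkSet, find_landmarks, write_landmark_set
from .network import (
    NeighborhoodNetwork,
    StateTransitionNetwork,
    build_neighborhood_network,
    trim_network,
    write_graphml,
    write_network,
)
from .ordering import order_cells_along_path, write_ordering
from .pseudotime_de import cluster_waves, pseudotime_de_scan, write_de_results
from .scoring import (
    cmap_permutation_test,
    commitment_by_landmark,
    scores_to_frame,
)

log = logging.getLogger("statepath")


class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    expression: str
    annotation: str
    out_dir: str
    expression_format: str | None = None
    gene_sets: str | None = None
    signature_up: str | None = None
    signature_down: str | None = None
    genes: list[str] | None = None
    pseudocount: float = 1.0
    min_value: float = 1.0
    max_low_fraction: float = 0.95
    diversity_cut: float = 0.6
    size_cut: float = 0.05
    k: int | None = None
    k_min: int | None = None
    k_max: int | None = None
    paths: list[list[str]] = field(default_factory=list)
    rescue: bool = False
    n_perm: int = 1000
    cmap_alpha: float = 0.05
    cmap_seed: int | None = None
    de_df: int = 3
    de_alpha: float = 0.05
    k_waves: int | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        for label, p in (("expression", self.expression), ("annotation", self.annotation)):
            if not Path(p).exists():
                raise ConfigError(f"{label} file not found: {p}")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ConfigError(f"gene_sets file not found: {self.gene_sets}")
        if self.gene_sets is not None and (
            self.signature_up is None or self.signature_down is None
        ):
            raise ConfigError("gene_sets requires signature_up and signature_down")


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def infer_trajectory(
    expr_log: ExpressionMatrix,
    ann: pd.Series,
    params: LandmarkParams | None = None,
    k: int | None = None,
) -> tuple[LandmarkSet, NeighborhoodNetwork, StateTransitionNetwork]:
    """In-memory core pipeline: landmarks -> neighborhood network -> tree."""
    ls = find_landmarks(expr_log, ann, params=params, k=k)
    nn = build_neighborhood_network(expr_log, ls)
    stn = trim_network(nn)
    return ls, nn, stn


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; returns a mapping of output names to paths."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> Path:
        outputs[name] = str(path)
        return path

    @_stage("preprocess")
    def preprocess():
        m = read_expression(config.expression, config.expression_format)
        ann = read_annotation(config.annotation)
        m = filter_low_expression(m, ann, config.min_value, config.max_low_fraction)
        m_log = log_transform(m, config.pseudocount)
        if config.gene_sets is not None:
            sig = read_signature(
                config.gene_sets, config.signature_up, config.signature_down
            )
            work = subset_genes(m_log, sig.up_genes | sig.down_genes)
        else:
            sig = None
            work = m_log
        if config.genes:
            work = subset_genes(work, config.genes)
        write_expression(work, emit("log2_matrix", out_dir / "log2_matrix.tsv"))
        return m, m_log, work, ann, sig

    m_linear, m_log, work, ann, sig = preprocess()

    @_stage("landmarks")
    def landmarks():
        k_range = None
        if config.k_min is not None and config.k_max is not None:
            k_range = (config.k_min, config.k_max)
        params = LandmarkParams(
            diversity_cut=config.diversity_cut,
            size_cut=config.size_cut,
            k_range=k_range,
        )
        ls = find_landmarks(work, ann, params=params, k=config.k)
        write_landmark_set(
            ls,
            emit("landmark_membership", out_dir / "landmark_membership.tsv"),
            emit("landmark_centroids", out_dir / "landmark_centroids.tsv"),
        )
        if ls.curve is not None:
            ls.curve.to_csv(emit("landmark_curve", out_dir / "landmark_curve.tsv"), sep="\t")
        return ls

    ls = landmarks()

    @_stage("network")
    def network():
        nn = build_neighborhood_network(work, ls)
        stn = trim_network(nn)
        write_network(nn, stn, emit("network_edges", out_dir / "network_edges.tsv"))
        write_graphml(stn, emit("state_transition_graphml", out_dir / "state_transition.graphml"))
        return nn, stn

    nn, stn = network()

    orderings = {}

    @_stage("ordering")
    def ordering():
        for path_spec in config.paths:
            po = order_cells_along_path(work, ls, stn, path_spec, rescue=config.rescue)
            name = "-".join(path_spec)
            write_ordering(po, emit(f"ordering_{name}", out_dir / f"ordering_{name}.tsv"))
            orderings[name] = po

    if config.paths:
        ordering()

    @_stage("cmap")
    def cmap():
        if config.cmap_seed is None:
            raise ConfigError("cmap_seed is required when a signature is configured")
        scores = cmap_permutation_test(
            work, sig, n_perm=config.n_perm, seed=config.cmap_seed, alpha=config.cmap_alpha
        )
        scores_to_frame(scores).to_csv(
            emit("cmap_scores", out_dir / "cmap_scores.tsv"), sep="\t"
        )
        commitment_by_landmark(scores, ls.membership).to_csv(
            emit("cmap_commitment", out_dir / "cmap_commitment.tsv"), sep="\t"
        )

    if sig is not None:
        cmap()

    @_stage("de")
    def de():
        for name, po in orderings.items():
            res = pseudotime_de_scan(
                work, po, alpha=config.de_alpha, df=config.de_df
            )
            clusters = None
            if config.k_waves and len(res.significant_genes) >= config.k_waves:
                clusters = cluster_waves(res, config.k_waves)
            write_de_results(
                res,
                clusters,
                emit(f"de_{name}", out_dir / f"de_{name}.tsv"),
                emit(f"waves_{name}", out_dir / f"waves_{name}.tsv")
                if clusters is not None
                else None,
            )

    if orderings:
        de()

    manifest = {
        "package": "statepath",
        "version": __version__,
        "config": asdict(config),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs
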