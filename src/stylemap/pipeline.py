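"""End-to-end orchestration: map, values, and track runs.

``run_map`` is the full cross-sectional pipeline (clean -> featurize ->
pairwise AUC matrix -> classical MDS -> Ward + k-means); ``run_values``
adds the ten value regressions on the embedding; ``run_track`` embeds a
focal group's time slices against fixed anchors.  Every run records a
:class:`RunManifest` (config snapshot, master seed, derived stage seeds,
input fingerprints) and re-running with identical inputs and seed
reproduces identical outputs; CSV files are written with a fixed float
format so they are byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import KMeansResult, LinkageTree, cut_tree, kmeans_rows, ward_linkage, wss_curve
from .corpus_io import CleaningReport, CleaningRules, Comment, clean_comments
from .dissim import DissimConfig, DissimilarityMatrix, build_matrix
from .geometry import Embedding, classical_mds, stress
from .lexicon import CategoryLexicon, featurize_group, load_default_style_lexicon
from .seeds import derive_seed
from .temporal import SliceTrajectory, TrajectoryConfig, anchored_trajectory, slice_by_period
from .values import ValueScores, run_value_table, score_values, value_scores_frame

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class MapConfig:
    """Configuration of a cross-sectional mapping run."""

    seed: int = 0
    min_words: int = 50
    k_dims: int = 2
    k_clusters: int = 5
    restarts: int = 25
    wss_range: tuple[int, int] = (2, 9)
    n_estimators: int = 100
    max_per_class: int | None = None

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    stage: str
    master_seed: int
    config: dict
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_fingerprints: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _fingerprint_corpus(comments: Sequence[Comment]) -> str:
    h = hashlib.sha256()
    for c in comments:
        h.update(f"{c.id}\x00{c.created_utc}\x00{len(c.body)}\n".encode())
    return h.hexdigest()[:16]


@dataclass
class MapResult:
    matrix: DissimilarityMatrix
    embedding: Embedding
    linkage: LinkageTree
    ward_assignments: dict[str, int]
    kmeans: KMeansResult
    wss: list[tuple[int, float]]
    stress: float
    cleaning_reports: dict[str, CleaningReport]
    features: dict[str, np.ndarray]
    cleaned: dict[str, list[Comment]]
    manifest: RunManifest

    @property
    def coords_by_group(self) -> dict[str, np.ndarray]:
        return {lab: self.embedding.loc(lab) for lab in self.embedding.labels}

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []

        def _save(df: pd.DataFrame, name: str, **kw) -> None:
            p = outdir / name
            df.to_csv(p, float_format=_FLOAT_FMT, **kw)
            paths.append(p)

        _save(self.matrix.to_frame(), "dissimilarity.csv")
        _save(self.embedding.to_frame(), "coordinates.csv", index_label="group")
        eig = pd.DataFrame({"eigenvalue": self.embedding.eigenvalues})
        eig.index.name = "rank"
        _save(eig, "eigenvalues.csv")
        _save(self.linkage.to_frame(), "linkage.csv", index=False)
        assign = pd.DataFrame(
            {
                "ward": pd.Series(self.ward_assignments),
                "kmeans": pd.Series(self.kmeans.assignments),
            }
        )
        assign.index.name = "group"
        _save(assign, "assignments.csv")
        _save(pd.DataFrame(self.wss, columns=["k", "wss"]), "wss_curve.csv", index=False)
        mp = outdir / "manifest.json"
        self.manifest.outputs = [p.name for p in paths]
        mp.write_text(self.manifest.to_json())
        paths.append(mp)
        return paths


def featurize_groups(
    groups: Mapping[str, Sequence[Comment]],
    lexicon: CategoryLexicon,
    rules: CleaningRules,
) -> tuple[dict[str, list[Comment]], dict[str, np.ndarray], dict[str, CleaningReport]]:
    """Clean and featurize each group's corpus."""
    cleaned: dict[str, list[Comment]] = {}
    features: dict[str, np.ndarray] = {}
    reports: dict[str, CleaningReport] = {}
    for lab, comments in groups.items():
        kept, rep = clean_comments(comments, rules)
        cleaned[lab] = kept
        reports[lab] = rep
        features[lab] = featurize_group(kept, lexicon)
        logger.info("group %s: %d/%d comments survive cleaning", lab, len(kept), rep.input_count)
    return cleaned, features, reports


def run_map(
    groups: Mapping[str, Sequence[Comment]],
    config: MapConfig | None = None,
    lexicon: CategoryLexicon | None = None,
    rules: CleaningRules | None = None,
) -> MapResult:
    """Cross-sectional mapping of a set of group corpora.

    Cleans and featurizes every corpus, builds the pairwise AUC
    dissimilarity matrix, embeds it with classical MDS, and clusters it
    with Ward linkage and k-means on the matrix rows.
    """
    config = config or MapConfig()
    if len(groups) < 3:
        raise ValueError(f"need at least 3 groups, got {len(groups)}")
    lexicon = lexicon or load_default_style_lexicon()
    rules = rules or CleaningRules(min_words=config.min_words)

    manifest = RunManifest(stage="map", master_seed=config.seed, config=config.snapshot())
    for lab, comments in groups.items():
        manifest.input_fingerprints[lab] = _fingerprint_corpus(comments)

    cleaned, features, reports = featurize_groups(groups, lexicon, rules)

    dissim_seed = derive_seed(config.seed, "dissim")
    manifest.stage_seeds["dissim"] = dissim_seed
    dcfg = DissimConfig(
        seed=dissim_seed,
        n_estimators=config.n_estimators,
        max_per_class=config.max_per_class,
    )
    matrix = build_matrix(features, dcfg)

    embedding = classical_mds(matrix, k=config.k_dims)
    linkage = ward_linkage(matrix)
    ward_assign = cut_tree(linkage, config.k_clusters)
    km_seed = derive_seed(config.seed, "kmeans")
    manifest.stage_seeds["kmeans"] = km_seed
    km = kmeans_rows(matrix, config.k_clusters, restarts=config.restarts, seed=km_seed)
    wss = wss_curve(
        matrix,
        k_min=config.wss_range[0],
        k_max=min(config.wss_range[1], len(matrix.labels)),
        restarts=config.restarts,
        seed=km_seed,
    )
    return MapResult(
        matrix=matrix,
        embedding=embedding,
        linkage=linkage,
        ward_assignments=ward_assign,
        kmeans=km,
        wss=wss,
        stress=stress(matrix, embedding),
        cleaning_reports=reports,
        features=features,
        cleaned=cleaned,
        manifest=manifest,
    )


def run_values(
    map_result: MapResult, value_lexicon: CategoryLexicon
) -> tuple[list[ValueScores], pd.DataFrame]:
    """Ten value regressions on a two-dimensional map embedding.

    Scores every group's cleaned posts against the value lexicon,
    averages per group, and regresses each value on the two MDS
    coordinates.  Requires a k=2 embedding (the table schema has exactly
    two coordinate columns).
    """
    if map_result.embedding.k != 2:
        raise ValueError(
            f"value regressions require a 2-D embedding, got k={map_result.embedding.k}"
        )
    scores = score_values(map_result.cleaned, value_lexicon)
    table = run_value_table(scores, map_result.coords_by_group)
    return scores, table


def write_values(scores: list[ValueScores], table: pd.DataFrame, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / "value_scores.csv"
    value_scores_frame(scores).to_csv(p1, float_format=_FLOAT_FMT, index_label="group")
    p2 = outdir / "value_regressions.csv"
    table.to_csv(p2, float_format=_FLOAT_FMT)
    return [p1, p2]


def run_track(
    focal_comments: Sequence[Comment],
    anchors: Mapping[str, Sequence[Comment]],
    config: MapConfig | None = None,
    lexicon: CategoryLexicon | None = None,
    rules: CleaningRules | None = None,
    min_per_class: int = 100,
    exclude: Sequence | None = None,
) -> SliceTrajectory:
    """Track a focal corpus across years against fixed anchor groups.

    The focal corpus is cleaned, sliced by UTC calendar year and
    featurized per slice; anchors are cleaned and featurized whole.  Each
    slice is embedded against the anchors and aligned to the earliest
    slice; optional slice exclusions are applied to the trend statistics.
    """
    config = config or MapConfig()
    lexicon = lexicon or load_default_style_lexicon()
    rules = rules or CleaningRules(min_words=config.min_words)

    _, anchor_features, _ = featurize_groups(anchors, lexicon, rules)
    cleaned_focal, _ = clean_comments(focal_comments, rules)
    slices = slice_by_period(cleaned_focal)
    focal_features = {y: featurize_group(cs, lexicon) for y, cs in slices.items()}

    tcfg = TrajectoryConfig(
        seed=derive_seed(config.seed, "track"),
        dissim=DissimConfig(
            seed=derive_seed(config.seed, "track"),
            n_estimators=config.n_estimators,
            max_per_class=config.max_per_class,
        ),
        min_per_class=min_per_class,
        k=config.k_dims,
    )
    traj = anchored_trajectory(focal_features, anchor_features, tcfg)
    from .temporal import exclude_slice

    for s in exclude or []:
        traj = exclude_slice(traj, s)
    return traj


def write_trajectory(traj: SliceTrajectory, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / "trajectory.csv"
    traj.to_frame().to_csv(p1, float_format=_FLOAT_FMT)
    p2 = outdir / "trend.json"
    p2.write_text(traj.trend_json())
    return [p1, p2]
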