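"""End-to-end orchestration: ingest/simulate -> entropy features -> behavior
PLSC -> permutation -> seed PLSC -> connectivity graphs -> CSV/JSON bundle.

Also houses the analytic degrees-of-freedom calculator for the three-way
mixed design (two within-subject factors, one grouping factor) that frames
the feature matrix: dfs are fully determined by the design sizes, so they
are computable without any data.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import connectivity as conn
from .entropy import FeatureMatrix, MSEParams, feature_matrix
from .errors import PipelineError, ValidationError
from .io import (
    CONDITIONS,
    GROUPS,
    config_hash,
    read_behavior,
    read_eeg,
    write_tables,
)
from .plsc import (
    SAM_DIMENSIONS,
    behavior_matrix,
    behavior_plsc,
    permutation_test,
)
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Mixed-design degrees of freedom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedDesign:
    """Sizes of the channels x condition x group mixed design."""

    n_within_a: int = 14   # channels
    n_within_b: int = 2    # reasoning condition (valid / invalid)
    n_groups: int = 3
    n_per_group: int = 21

    def __post_init__(self):
        if self.n_within_a < 2 or self.n_groups < 2 or self.n_per_group < 2:
            raise ValidationError("design sizes must be >= 2 (n_within_b >= 1)")
        if self.n_within_b < 1:
            raise ValidationError("n_within_b must be >= 1")

    @property
    def n_subjects(self) -> int:
        return self.n_groups * self.n_per_group


def mixed_anova_dfs(design: MixedDesign = MixedDesign()) -> pd.DataFrame:
    """Sphericity-assumed df table (effect, df_effect, df_error) for the design.

    With a within-factor levels, b within-factor levels, g groups and s total
    subjects, the between-subject error has s - g dfs and each within effect
    uses the interaction of its factor(s) with subjects-within-groups as
    error.
    """
    a, b = design.n_within_a, design.n_within_b
    g, s = design.n_groups, design.n_subjects
    rows = [
        ("group", g - 1, s - g),
        ("channels", a - 1, (a - 1) * (s - g)),
        ("channels*group", (a - 1) * (g - 1), (a - 1) * (s - g)),
        ("syllogism", b - 1, (b - 1) * (s - g)),
        ("syllogism*group", (b - 1) * (g - 1), (b - 1) * (s - g)),
        ("channels*syllogism", (a - 1) * (b - 1), (a - 1) * (b - 1) * (s - g)),
        ("channels*syllogism*group",
         (a - 1) * (b - 1) * (g - 1), (a - 1) * (b - 1) * (s - g)),
    ]
    return pd.DataFrame(rows, columns=["effect", "df_effect", "df_error"]
                        ).set_index("effect")


# ---------------------------------------------------------------------------
# Feature matrix CSV round trip
# ---------------------------------------------------------------------------

def save_features(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = features.data.copy()
    df.insert(0, "group", features.groups)
    df.to_csv(path, float_format="%.17g")
    return path


def load_features(
    path: str | Path, condition: str, params: MSEParams = MSEParams()
) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    groups = df.pop("group")
    return FeatureMatrix(df, groups, condition, params)


# ---------------------------------------------------------------------------
# Pipeline configuration and run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration for a full analysis run."""

    out_dir: Path
    mode: Literal["synthetic", "files"] = "synthetic"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    eeg_dir: Path | None = None
    behavior_path: Path | None = None
    mse_params: MSEParams = field(default_factory=MSEParams)
    sam_subset: Sequence[str] = SAM_DIMENSIONS
    n_perm: int = 10_000
    perm_scope: Literal["within_group", "global"] = "within_group"
    seed: int = 42
    seeds: tuple[str, ...] = conn.DEFAULT_SEEDS
    threshold_mode: Literal["absolute", "proportional"] = "absolute"
    threshold_value: float = 0.20
    display_threshold: float = 0.3
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.mode == "files":
            if self.eeg_dir is None or self.behavior_path is None:
                raise ValidationError(
                    "files mode requires eeg_dir and behavior_path"
                )
        elif self.mode != "synthetic":
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r}")

    def manifest_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "mse_params": vars(self.mse_params).copy(),
            "sam_subset": list(self.sam_subset),
            "n_perm": self.n_perm,
            "perm_scope": self.perm_scope,
            "seed": self.seed,
            "seeds": list(self.seeds),
            "threshold_mode": self.threshold_mode,
            "threshold_value": self.threshold_value,
            "display_threshold": self.display_threshold,
            "conditions": list(self.conditions),
        }
        if self.mode == "synthetic":
            d["simulation"] = self.simulation.to_dict()
        else:
            d["eeg_dir"] = str(self.eeg_dir)
            d["behavior_path"] = str(self.behavior_path)
        return d


@dataclass
class ConditionResult:
    features: FeatureMatrix
    behavior: pd.DataFrame
    plsc: "object"
    permutation: "object"
    seed_plsc: "object"
    edges: pd.DataFrame
    graph: conn.WeightedGraph
    thresholded: conn.WeightedGraph
    metrics: conn.GraphMetrics
    hemisphere: pd.DataFrame


@dataclass
class PipelineReport:
    config: PipelineConfig
    results: dict[str, ConditionResult]
    manifest: dict
    written: list[Path]


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = round(dt, 4)
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage for each configured condition and write the bundle.

    All results are computed in memory first; files appear only after every
    stage has succeeded, so a failed run leaves no partial bundle.
    """
    timings: dict[str, float] = {}
    results: dict[str, ConditionResult] = {}

    with _stage("ingest", timings):
        if config.mode == "synthetic":
            dataset = simulate_cohort(config.simulation)
            recordings = dataset.recordings
            behavior_rows = dataset.behavior
        else:
            dataset = None
            paths = sorted(
                p for p in Path(config.eeg_dir).iterdir()
                if p.suffix.lower() in (".csv", ".edf") and p.stem != "behavior"
            )
            if not paths:
                raise ValidationError(f"no EEG files found in {config.eeg_dir}")
            recordings = [read_eeg(p) for p in paths]
            behavior_rows = read_behavior(config.behavior_path)

    for condition in config.conditions:
        with _stage(f"features[{condition}]", timings):
            if (
                dataset is not None
                and config.mse_params == config.simulation.mse_params
            ):
                # the generator already computed these features
                feats = _features_from_dataset(dataset, condition)
            else:
                feats = feature_matrix(recordings, condition, config.mse_params)

        with _stage(f"behavior[{condition}]", timings):
            Y = behavior_matrix(
                behavior_rows, condition, list(feats.data.index),
                sam_subset=config.sam_subset,
            )

        with _stage(f"plsc[{condition}]", timings):
            res = behavior_plsc(feats, Y)

        with _stage(f"permutation[{condition}]", timings):
            perm = permutation_test(
                feats.values, Y.to_numpy(float), res.design,
                n_perm=config.n_perm, seed=config.seed, scope=config.perm_scope,
            )

        with _stage(f"seed_plsc[{condition}]", timings):
            seed_res = conn.seed_plsc(feats, config.seeds)
            edges = conn.edges_from_saliences(
                seed_res.R_frame, config.display_threshold
            )

        with _stage(f"graph[{condition}]", timings):
            graph = conn.salience_to_weight_matrix(seed_res.R_frame.T)
            thresholded = conn.threshold_weights(
                graph, config.threshold_mode, config.threshold_value
            )
            metrics = conn.graph_metrics(thresholded)
            hemi = conn.hemisphere_summary(
                conn.edges_from_saliences(seed_res.R_frame, 0.0)
            )

        results[condition] = ConditionResult(
            features=feats, behavior=Y, plsc=res, permutation=perm,
            seed_plsc=seed_res, edges=edges, graph=graph,
            thresholded=thresholded, metrics=metrics, hemisphere=hemi,
        )

    manifest = {
        "config": config.manifest_dict(),
        "config_hash": config_hash(config.manifest_dict()),
        "timings_s": timings,
        "n_subjects": len({r.subject_id for r in recordings}),
    }

    written: list[Path] = []
    with _stage("write", timings):
        for condition, r in results.items():
            d = config.out_dir / condition
            feats_df = r.features.data.copy()
            feats_df.insert(0, "group", r.features.groups)
            tables = {
                "features": feats_df,
                "behavior_matrix": r.behavior,
                "singular_values": r.plsc.decomposition.singular_value_table(),
                "U": r.plsc.U_frame,
                "V": r.plsc.V_frame,
                "brain_scores": pd.DataFrame(
                    r.plsc.L_X, index=r.features.data.index,
                    columns=[f"LV{l}" for l in range(1, r.plsc.decomposition.rank + 1)],
                ),
                "behavior_scores": pd.DataFrame(
                    r.plsc.L_Y, index=r.features.data.index,
                    columns=[f"LV{l}" for l in range(1, r.plsc.decomposition.rank + 1)],
                ),
                "seed_singular_values":
                    r.seed_plsc.decomposition.singular_value_table(),
                "R_seed": r.seed_plsc.R_frame,
                "V_seed": r.seed_plsc.V_frame,
                "weight_matrix": r.thresholded.frame(),
                "graph_metrics": r.metrics.per_node,
                "hemisphere_summary": r.hemisphere,
            }
            if len(r.edges):
                tables["edges"] = r.edges.set_index(["group", "seed", "channel"])
            written += write_tables(tables, d)
            summary = {
                "condition": condition,
                "permutation": r.permutation.summary(),
                "inertia": r.plsc.decomposition.inertia,
                "graph_density": r.metrics.density,
                "n_edges_displayed": int(len(r.edges)),
            }
            p = d / "summary.json"
            p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
            written.append(p)
        mp = config.out_dir / "manifest.json"
        config.out_dir.mkdir(parents=True, exist_ok=True)
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(mp)

    return PipelineReport(config=config, results=results,
                          manifest=manifest, written=written)


def _features_from_dataset(dataset, condition: str) -> FeatureMatrix:
    """Wrap the generator's cached features in group-contiguous order."""
    group_of = {r.subject_id: r.group for r in dataset.recordings}
    df = dataset.features[condition]
    rank = {g: i for i, g in enumerate(GROUPS)}
    order = sorted(df.index, key=lambda s: (rank[group_of[s]], s))
    df = df.loc[order]
    groups = pd.Series([group_of[s] for s in order], index=df.index, name="group")
    return FeatureMatrix(df, groups, condition, dataset.config.mse_params)
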