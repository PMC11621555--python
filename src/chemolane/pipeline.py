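"""End-to-end orchestration, phenotype clustering, and group statistics.

Ties the stages together: synthetic (or ingested) inputs -> quantification
-> cohort statistics -> CSV outputs, with the run fully reproducible from
its configuration and seed.  Also hosts the strain-level operations that
sit above any single assay: Ward-linkage hierarchical clustering of
multi-assay phenotype tables (with k-means labels on the same standardized
matrix) and the two-sample Student's t-test used for group comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from . import cla, diffusion, synthetic, trajectory

logger = logging.getLogger("chemolane")

__all__ = [
    "PhenotypeTable",
    "RunConfig",
    "cluster_phenotypes",
    "group_ttest",
    "significance_stars",
    "run_end_to_end",
]


@dataclass
class PhenotypeTable:
    """Strain-by-phenotype matrix of group means, with optional replicates.

    ``data`` is indexed by strain/cohort name; columns are phenotype
    metrics (e.g. chemotaxis_index, photoshock_response, swim_speed,
    symmetric_incidences).  ``replicates`` may keep the per-replicate
    values behind each cell for significance tests.
    """

    data: pd.DataFrame
    replicates: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("phenotype table must have no missing cells")


@dataclass
class ClusterResult:
    """Ward linkage tree plus k-means labels on the standardized matrix."""

    linkage_matrix: np.ndarray
    ward_labels: np.ndarray
    kmeans_labels: np.ndarray
    row_names: list[str]
    columns_used: list[str]
    dropped_columns: list[str]

    def to_dict(self) -> dict:
        return {
            "linkage": self.linkage_matrix.tolist(),
            "ward_labels": self.ward_labels.tolist(),
            "kmeans_labels": self.kmeans_labels.tolist(),
            "rows": self.row_names,
            "columns": self.columns_used,
        }


def cluster_phenotypes(
    table: PhenotypeTable, k: int, random_state: int = 0
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of standardized phenotypes.

    Columns are z-scored before Euclidean distances (so no single
    mixed-unit phenotype dominates); constant columns are dropped with a
    warning.  Returns the linkage tree, the k-cluster cut, and k-means
    labels computed on the same standardized matrix (the coloring used on
    phenotype dendrograms).
    """
    df = table.data
    if len(df) < 3:
        raise ValueError("need at least 3 rows to cluster")
    sd = df.std(ddof=0)
    dropped = list(df.columns[sd == 0])
    if dropped:
        logger.warning("dropping constant column(s): %s", ", ".join(dropped))
    use = df.drop(columns=dropped)
    if use.shape[1] == 0:
        raise ValueError("no non-constant columns to cluster")
    z = (use - use.mean()) / use.std(ddof=0)
    X = z.to_numpy()
    Z = linkage(X, method="ward")
    ward_labels = fcluster(Z, t=k, criterion="maxclust") - 1
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(X)
    return ClusterResult(
        linkage_matrix=Z,
        ward_labels=ward_labels,
        kmeans_labels=km.labels_,
        row_names=list(df.index),
        columns_used=list(use.columns),
        dropped_columns=dropped,
    )


def group_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test (equal variance by default).

    Returns (t, p).  Degenerate input — both groups constant with equal
    means — raises rather than returning a silent NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("t-test undefined: both groups constant and equal")
        return float("inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Figure-style star annotation: * p<0.1, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return "ns"


@dataclass
class RunConfig:
    """Everything needed to reproduce an end-to-end demo run.

    Two swimming cohorts (a wild-type-like and a mutant-like one whose
    spontaneous switch rate differs by ``rate_fold_change``), one rendered
    lane stack, and one simulated dye-diffusion series; the master seed
    derives every stream.
    """

    seed: int = 0
    swim: synthetic.SwimConfig = field(default_factory=synthetic.SwimConfig)
    rate_fold_change: float = 1.6
    detector: trajectory.DetectorParams = field(default_factory=trajectory.DetectorParams)
    lane: synthetic.LaneImageConfig = field(default_factory=synthetic.LaneImageConfig)
    diffusion_D: float = 7.497e-5   # cm^2/s, BPB-like dye
    diffusion_c0: float = 200.0     # source concentration, mM
    diffusion_noise_frac: float = 0.02

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["swim"]["gradient_direction"] = list(d["swim"]["gradient_direction"])
        d["swim"]["arena"] = list(d["swim"]["arena"])
        d["lane"]["timepoints"] = np.asarray(d["lane"]["timepoints"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "swim" in d:
            sw = dict(d["swim"])
            for key in ("gradient_direction", "arena"):
                if key in sw:
                    sw[key] = tuple(sw[key])
            d["swim"] = synthetic.SwimConfig(**sw)
        if "detector" in d:
            d["detector"] = trajectory.DetectorParams(**d["detector"])
        if "lane" in d:
            ln = dict(d["lane"])
            if "timepoints" in ln:
                ln["timepoints"] = np.asarray(ln["timepoints"], dtype=float)
            d["lane"] = synthetic.LaneImageConfig(**ln)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_end_to_end(config: RunConfig, outdir) -> dict:
    """Execute the full synthetic demo pipeline and write the report bundle.

    Stages: simulate two cohorts and detect switches (rates and their
    fold-change), render and quantify a lane stack (Slope Index series and
    Chemotaxis Index), simulate and refit a dye-diffusion series.  Writes
    summary.csv, rates.csv, slope_index.csv, events.csv, diffusion_fit.json
    and the echoed config under ``outdir``.  Stage failures propagate with
    the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate-cohorts")
        base = dataclasses.replace(config.swim, rng_seed=config.seed)
        mutant = dataclasses.replace(
            config.swim,
            rng_seed=config.seed + 1,
            switch_rate_base=config.swim.switch_rate_base / config.rate_fold_change,
        )
        wt_set = synthetic.simulate_tracks(base)
        mu_set = synthetic.simulate_tracks(mutant)

        stage("detect-switches")
        wt_ann = trajectory.annotate_set(wt_set, config.detector)
        mu_ann = trajectory.annotate_set(mu_set, config.detector)
        wt_rate = trajectory.switch_rate(wt_set, config.detector, wt_ann)
        mu_rate = trajectory.switch_rate(mu_set, config.detector, mu_ann)
        fold = wt_rate.mean / mu_rate.mean if mu_rate.mean > 0 else float("nan")
        report["wt_rate_per_s"] = wt_rate.mean
        report["mutant_rate_per_s"] = mu_rate.mean
        report["rate_fold_change"] = fold
        pd.DataFrame(
            {
                "cohort": ["wild_type", "mutant"],
                "mean_rate_per_s": [wt_rate.mean, mu_rate.mean],
                "sd": [wt_rate.sd, mu_rate.sd],
                "n_tracks": [wt_rate.n_tracks, mu_rate.n_tracks],
            }
        ).to_csv(outdir / "rates.csv", index=False)
        trajectory.events_table(wt_ann).to_csv(outdir / "events.csv", index=False)

        stage("lane-assay")
        lane_cfg = dataclasses.replace(config.lane, rng_seed=config.seed + 2)
        stack = synthetic.render_lane_stack(lane_cfg)
        geom = cla.LaneGeometry(
            lane_bounds=[(0, lane_cfg.n_px_width, 0, lane_cfg.n_px_length)],
            px_per_mm=lane_cfg.px_per_mm,
            source_end=lane_cfg.source_end,
            lane_length_mm=lane_cfg.lane_length,
            lane_width_mm=lane_cfg.lane_width,
        )
        prof = cla.extract_profiles(stack, geom, lane_cfg.timepoints)[0]
        result = cla.analyze_profile(prof, geom.lane_length_mm)
        report["chemotaxis_index"] = result.chemotaxis_index
        report["t_max_h"] = result.t_max
        pd.DataFrame(
            {"time_h": result.times_h, "slope_index": result.slope_index}
        ).to_csv(outdir / "slope_index.csv", index=False)

        stage("diffusion")
        profile = synthetic.simulate_diffusion_profiles(
            config.diffusion_D,
            config.diffusion_c0,
            times_h=[1, 2, 4, 12, 18, 24],
            positions_mm=np.arange(1.0, 41.0, 1.0),
            noise_frac=config.diffusion_noise_frac,
            rng_seed=config.seed + 3,
        )
        fit = diffusion.fit_diffusion_coefficient(profile)
        report["diffusion_D_cm2_s"] = fit.D
        report["diffusion_r_squared"] = fit.r_squared
        with open(outdir / "diffusion_fit.json", "w") as fh:
            json.dump(fit.report(), fh, indent=2)
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {err}") from err

    pd.DataFrame([report]).to_csv(outdir / "summary.csv", index=False)
    config.to_yaml(outdir / "config_echo.yaml")
    return report
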