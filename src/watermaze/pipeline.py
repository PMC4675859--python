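"""End-to-end orchestration: simulate → metrics → exclusion → session
means → median table → PCA → supplementary projection → variance
decomposition → permutation test → censored model → report files.

Every run writes its artifacts plus a ``manifest.json`` recording the
seed, package version, per-file SHA-256 checksums, excluded subjects and
any skipped stages, so that (config, seed) fully determines and documents
the numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortDesign, GroupBehavior, GroupSpec, default_cohort
from .geometry import PoolGeometry
from .io import write_grid, write_pca_json, write_scores_csv
from .metrics import (
    METRIC_COLUMNS,
    cued_exclusion,
    metrics_table,
    occupancy_heatmap,
    session_mean_metrics,
)
from .models import fit_censored_mixed
from .pca import build_group_median_table, fit_supervised_pca, project_supplementary
from .permutation import separation_test
from .simulate import simulate_cohort
from .variance import decompose_variance


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    geometry: PoolGeometry = field(default_factory=PoolGeometry)
    design: CohortDesign = field(default_factory=default_cohort)
    n_permutations: int = 200
    permutation_seed: int = 0
    quad_order: int = 16
    heatmap_bin_size: float = 5.0
    log_latency: bool = True
    verbose: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            g = dict(d["geometry"])
            if g.get("platform_center") is not None:
                g["platform_center"] = tuple(g["platform_center"])
            d["geometry"] = PoolGeometry(**g)
        if "design" in d:
            dd = dict(d["design"])
            dd["groups"] = tuple(
                GroupSpec(
                    genotype=g["genotype"],
                    treatment=g["treatment"],
                    n_subjects=g["n_subjects"],
                    behavior=GroupBehavior(**g["behavior"]),
                )
                for g in dd["groups"]
            )
            d["design"] = CohortDesign(**dd)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    session_means: pd.DataFrame
    excluded_subjects: list
    median_table: pd.DataFrame
    model: object
    supplementary: pd.DataFrame
    decomposition: object
    permutation: object | None
    latency_fits: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute the full analysis chain and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    skipped: list[str] = []

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts.append(path)

    trajectories = _stage("simulate", lambda: simulate_cohort(config.design, config.geometry))
    metrics = _stage(
        "metrics",
        lambda: metrics_table(trajectories, config.geometry, cutoff=config.design.trial_cutoff),
    )
    _write("metrics.csv", lambda p: metrics.to_csv(p, index=False))

    cued = metrics[metrics["phase"] == "cued"]
    excluded = _stage("cued_exclusion", lambda: cued_exclusion(cued)) if len(cued) else []
    if not len(cued):
        skipped.append("cued_exclusion")
    kept = metrics[~metrics["subject_id"].isin(excluded)]

    acq = kept[kept["phase"] == "acquisition"]
    session_means = _stage("session_means", lambda: session_mean_metrics(acq))
    _write("session_means.csv", lambda p: session_means.to_csv(p, index=False))

    median_table = _stage("median_table", lambda: build_group_median_table(session_means))
    _write("median_table.csv", lambda p: median_table.to_csv(p))

    model = _stage("pca", lambda: fit_supervised_pca(median_table))
    _write("pca_model.json", lambda p: write_pca_json(model, p))
    _write("pca_scores.csv", lambda p: write_scores_csv(model, p))

    supplementary = _stage("supplementary", lambda: project_supplementary(session_means, model))
    _write("supplementary_scores.csv", lambda p: supplementary.to_csv(p, index=False))

    decomposition = _stage("decompose", lambda: decompose_variance(model, supplementary))
    _write(
        "variance_decomposition.json",
        lambda p: p.write_text(json.dumps(decomposition.as_dict(), indent=1, sort_keys=True)),
    )

    if config.n_permutations > 0:
        perm = _stage(
            "permutation",
            lambda: separation_test(
                session_means,
                n_permutations=config.n_permutations,
                seed=config.permutation_seed,
            ),
        )
        payload = {
            "statistic": perm.statistic,
            "observed": perm.observed,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "seed": perm.seed,
            "null": perm.null.tolist(),
        }
    else:
        perm = None
        skipped.append("permutation")
        payload = {"statistic": "within_session_separation", "skipped": True}
    _write(
        "permutation.json",
        lambda p: p.write_text(json.dumps(payload, indent=1, sort_keys=True)),
    )

    def _latency_fits() -> pd.DataFrame:
        frames = []
        lat = acq.copy()
        if config.log_latency:
            lat["log_latency"] = np.log(lat["latency"])
            response, thr = "log_latency", math.log(config.design.trial_cutoff)
        else:
            response, thr = "latency", config.design.trial_cutoff
        for ref in ("WT", "TS"):
            if ref not in set(lat["group"]):
                continue
            fit = fit_censored_mixed(
                lat, response, thr, ref, quad_order=config.quad_order
            )
            block = fit.params.copy()
            block.insert(0, "reference", ref)
            block["sigma_u"] = fit.sigma_u
            block["sigma_e"] = fit.sigma_e
            block["loglik"] = fit.loglik
            frames.append(block)
        if not frames:
            raise ValueError("no reference group present for the latency model")
        return pd.concat(frames, ignore_index=True)

    latency_fits = _stage("censored_model", _latency_fits)
    _write("censored_latency_fit.csv", lambda p: latency_fits.to_csv(p, index=False))

    acq_trajs = [t for t in trajectories if t.phase == "acquisition"]
    heat = _stage(
        "heatmap",
        lambda: occupancy_heatmap(
            acq_trajs, config.geometry, bin_size=config.heatmap_bin_size, scope="acquisition"
        ),
    )
    _write("heatmap_acquisition.txt", lambda p: write_grid(heat, p))
    artifacts.append(outdir / "heatmap_acquisition.txt.meta.json")

    manifest = {
        "version": __version__,
        "seed": config.design.seed,
        "permutation_seed": config.permutation_seed,
        "n_permutations": config.n_permutations,
        "excluded_subjects": list(excluded),
        "skipped_stages": skipped,
        "artifacts": {
            p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size} for p in artifacts
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        metrics=metrics,
        session_means=session_means,
        excluded_subjects=list(excluded),
        median_table=median_table,
        model=model,
        supplementary=supplementary,
        decomposition=decomposition,
        permutation=perm,
        latency_fits=latency_fits,
        manifest=manifest,
    )
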