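"""End-to-end run orchestration: score → network → metrics → cluster.

A run is described by a :class:`RunConfig` (YAML/JSON-loadable), consumes
either cohort CSVs or a simulation spec, and writes a self-contained run
directory: per-disease scorecards, cohort summaries, thresholded item- and
subscale-level networks (edge CSV + GraphML), centrality and global-metric
tables, the pooled two-cluster solution, and a manifest with SHA-256 hashes
of every artifact. Identical configs produce bit-identical artifacts and
therefore identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog
from .clustering import RiskProfileKMeans
from .cohort import Cohort
from .metrics import centralities, global_metrics
from .network import PsychosocialNetworkModel
from .scoring import cohort_summary, score_cohort
from .simulate import COHORT_SIZES, DISEASES, calibrate_profile, generate_cohort

log = logging.getLogger("patnet")

THRESHOLD_MODES = ("significance", "proportional", "both")


@dataclass
class RunConfig:
    """Configuration of one pipeline run. Exactly one input source: either
    ``simulate`` (disease → cohort size, plus a seed) or ``cohorts`` (CSV
    paths with their instrument variant)."""

    output_dir: str
    simulate: Optional[dict] = None  # {"diseases": {...}, "seed": int}
    cohorts: Optional[list] = None  # [{"path": ..., "variant": ...}]
    threshold_mode: str = "both"
    alpha: float = 0.05
    keep_fraction: float = 0.2
    significance_first: bool = True
    cluster_k: int = 2
    cluster_restarts: int = 20
    cluster_seed: int = 0
    layout_seed: int = 0
    layout_iterations: int = 200
    layout_gravity: float = 10.0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.cohorts is None):
            raise ValueError("exactly one of 'simulate' and 'cohorts' must be given")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.simulate is not None and "seed" not in self.simulate:
            self.simulate = {**self.simulate, "seed": 0}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _threshold(results, config: RunConfig):
    ops = []
    if config.threshold_mode == "significance":
        ops = [("significance", config.alpha)]
    elif config.threshold_mode == "proportional":
        ops = [("proportional", config.keep_fraction)]
    else:
        ops = [("significance", config.alpha), ("proportional", config.keep_fraction)]
        if not config.significance_first:
            ops.reverse()
    for mode, value in ops:
        if mode == "significance":
            results = results.threshold_significance(value)
        else:
            results = results.threshold_proportional(value)
    return results


def _load_inputs(config: RunConfig, outdir: Path) -> list[Cohort]:
    cohorts: list[Cohort] = []
    if config.simulate is not None:
        spec = config.simulate
        seed = int(spec.get("seed", 0))
        diseases = spec.get("diseases") or {d: {"n": COHORT_SIZES[d]} for d in DISEASES}
        profiles_meta = {}
        for offset, (disease, opts) in enumerate(sorted(diseases.items())):
            profile = calibrate_profile(disease)
            n = int(opts.get("n", profile.n_default)) if isinstance(opts, dict) else int(opts)
            cohort = generate_cohort(profile, n=n, seed=seed + offset)
            cohort.to_csv(outdir / f"cohort_{disease}.csv")
            profiles_meta[disease] = {
                "disease": disease,
                "n": n,
                "seed": seed + offset,
                "variant": profile.catalog.variant,
                "sibling_applicable_rate": profile.sibling_applicable_rate,
                "item_prevalence": profile.item_prevalence,
            }
            cohorts.append(cohort)
        with open(outdir / "profiles.json", "w") as fh:
            json.dump(profiles_meta, fh, indent=2, sort_keys=True)
    else:
        for entry in config.cohorts:
            catalog = load_catalog(entry.get("variant", "PAT2.0"))
            cohorts.append(Cohort.from_csv(entry["path"], catalog))
    return cohorts


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = _load_inputs(config, outdir)

    all_scores = []
    for cohort in cohorts:
        disease = str(cohort.frame["disease"].iloc[0])
        log.info("scoring cohort %s (n=%d)", disease, len(cohort))
        scores = score_cohort(cohort.frame, cohort.catalog)
        scores.to_csv(outdir / f"scorecards_{disease}.csv", index=False)
        with open(outdir / f"summary_{disease}.json", "w") as fh:
            json.dump(cohort_summary(scores), fh, indent=2, sort_keys=True)
        all_scores.append(scores)

        for level in ("item", "subscale"):
            results = PsychosocialNetworkModel(cohort, level=level).fit()
            results = _threshold(results, config)
            results.layout(
                seed=config.layout_seed,
                iterations=config.layout_iterations,
                gravity=config.layout_gravity,
            )
            stem = f"network_{disease}_{level}"
            results.to_edge_csv(outdir / f"{stem}_edges.csv")
            results.to_graphml(outdir / f"{stem}.graphml")
            centralities(results).to_csv(
                outdir / f"centrality_{disease}_{level}.csv", index=False
            )
            if len(results.node_ids) >= 2:
                with open(outdir / f"global_metrics_{disease}_{level}.json", "w") as fh:
                    json.dump(global_metrics(results).to_dict(), fh, indent=2,
                              sort_keys=True)

    pooled = pd.concat(all_scores, ignore_index=True)
    solution = RiskProfileKMeans(pooled, k=config.cluster_k).fit(
        seed=config.cluster_seed, restarts=config.cluster_restarts
    )
    solution.assignment.rename_axis("family_id").reset_index().to_csv(
        outdir / "cluster_assignments.csv", index=False
    )
    payload = {
        "k": solution.k,
        "sizes": {int(k): int(v) for k, v in solution.cluster_sizes.items()},
        "inertia": solution.inertia,
        "silhouette": solution.silhouette,
        "seed": solution.seed,
        "restarts": solution.restarts,
        "centroids_z": solution.centroids_z.round(10).to_dict(),
        "profile_table": solution.profile_table.round(10).to_dict(),
        "crosstab_disease": (
            {str(c): {int(k): int(v) for k, v in col.items()}
             for c, col in solution.crosstab_disease.to_dict().items()}
            if solution.crosstab_disease is not None else None
        ),
        "crosstab_risk": (
            {str(c): {int(k): int(v) for k, v in col.items()}
             for c, col in solution.crosstab_risk.to_dict().items()}
            if solution.crosstab_risk is not None else None
        ),
    }
    with open(outdir / "cluster_solution.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "artifacts": {},
    }
    for path in sorted(outdir.glob("*")):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest["artifacts"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", outdir)
    return outdir
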