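"""End-to-end seeded pipeline: simulate -> stratify -> CDP -> LME -> evaluate.

Each stage reads and writes plain CSV/JSON artifacts in the run directory,
never in-memory state from another stage, so any stage can be re-run in
isolation.  One global seed deterministically derives a sub-seed per stage
(SHA-256 of "seed:stage"), and a manifest records configuration, seeds and
artifact hashes so a re-run with the same config and seed is byte-identical.
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
from .cdp import CDPRule, cdp_table
from .evaluation import (FEATURE_SETS, comparison_table, compute_features,
                         evaluate, kmeans_baseline)
from .gmm import GMMError, GMMSpec, classify, select_classes
from .lme import fit_gait_lme, outcome_test_family
from .synthetic import CohortConfig, apply_missingness, simulate_cohort, write_cohort

log = logging.getLogger("gaitmix")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_max: int = 5
    n_starts: int = 5
    fdr_level: float = 0.05
    baselines: tuple[str, ...] = tuple(FEATURE_SETS)
    seed: int = 0
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write artifacts under ``out_dir``, return manifest.

    On a stage failure the partially written artifacts of that stage are
    renamed with a ``.partial`` suffix and a :class:`PipelineError` naming
    the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s)
             for s in ("simulate", "missingness", "gmm", "kmeans")}
    artifacts: list[Path] = []
    stage_files: list[Path] = []

    def _stage(name):
        def deco(fn):
            def run():
                stage_files.clear()
                log.info("stage %s", name)
                try:
                    fn()
                except Exception as exc:
                    for f in stage_files:
                        if f.exists():
                            f.rename(f.with_suffix(f.suffix + ".partial"))
                    raise PipelineError(name, exc) from exc
                artifacts.extend(stage_files)
            return run
        return deco

    def _track(path: Path) -> Path:
        stage_files.append(path)
        return path

    @_stage("simulate")
    def stage_simulate():
        cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
        subjects, gait, visits = simulate_cohort(cfg)
        gait = apply_missingness(gait, cfg.missingness, seeds["missingness"])
        visits = apply_missingness(visits, cfg.missingness,
                                   seeds["missingness"])
        for n in ("subjects", "gait", "visits"):
            _track(out / f"{n}.csv")
        write_cohort(out, subjects, gait, visits)

    @_stage("gmm")
    def stage_gmm():
        from .synthetic import read_cohort

        subjects, gait, _ = read_cohort(out)
        spec = GMMSpec(n_starts=config.n_starts, seed=seeds["gmm"])
        fits, chosen = select_classes(gait, subjects, config.k_max, spec)
        if chosen != 2 or 2 not in fits:
            raise GMMError(
                "two-class stratification undetectable: model selection "
                f"chose K={chosen} (BIC over K in {sorted(fits)}); the "
                "high/low-risk split is defined only for a two-class fit")
        strat = classify(fits[2])
        _write_json(_track(out / "gmm_fit.json"), {
            "chosen_k": int(chosen),
            "bic_by_k": {str(k): fits[k].bic for k in sorted(fits)},
            "aic_by_k": {str(k): fits[k].aic for k in sorted(fits)},
            "fit_k2": fits[2].to_dict(),
        })
        strat.table.to_csv(_track(out / "strata.csv"), index=False)

    @_stage("cdp")
    def stage_cdp():
        from .synthetic import read_cohort

        subjects, _, visits = read_cohort(out)
        table, prevalence, skipped = cdp_table(visits, subjects, CDPRule())
        table.to_csv(_track(out / "cdp.csv"), index=False)
        _write_json(_track(out / "cdp_summary.json"),
                    {"prevalence": prevalence, "skipped_subjects": skipped})

    @_stage("lme")
    def stage_lme():
        from .synthetic import read_cohort

        subjects, gait, visits = read_cohort(out)
        strata = pd.read_csv(out / "strata.csv")
        fit = fit_gait_lme(gait, subjects, strata)
        _write_json(_track(out / "lme_fit.json"), fit.to_dict())
        family = outcome_test_family(visits, subjects, strata,
                                     fdr_level=config.fdr_level)
        family.to_csv(_track(out / "outcome_tests.csv"), index=False)

    @_stage("evaluate")
    def stage_evaluate():
        from .synthetic import read_cohort

        subjects, gait, visits = read_cohort(out)
        strata = pd.read_csv(out / "strata.csv")
        cdp = pd.read_csv(out / "cdp.csv")
        feats = compute_features(gait, subjects, visits)
        reports = []
        gmm_pred = strata.rename(columns={"p_hrp": "score"})
        reports.append(evaluate(gmm_pred, cdp, method="gmm_6mwgst"))
        for fs in config.baselines:
            labels = kmeans_baseline(feats, fs,
                                     seed=derive_seed(seeds["kmeans"], fs))
            if labels.degenerate:
                continue
            reports.append(evaluate(labels.table, cdp, method=fs))
        _write_json(_track(out / "eval_report.json"),
                    [r.to_dict() for r in reports])
        comparison_table(reports).to_csv(
            _track(out / "method_comparison.csv"), index=False)

    @_stage("figures")
    def stage_figures():
        from .synthetic import read_cohort

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        subjects, gait, _ = read_cohort(out)
        strata = pd.read_csv(out / "strata.csv")
        lab = subjects.set_index("subject_id")["cohort"].copy()
        lab[strata.set_index("subject_id").index] = \
            strata.set_index("subject_id")["label"]
        df = gait[gait["visit"] == 0].copy()
        df["group"] = lab.reindex(df["subject_id"]).to_numpy()
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, sub in df.groupby("group"):
            prof = sub.groupby("minute")["speed_ft_min"].mean()
            ax.plot(prof.index, prof.values, marker="o", label=g)
        ax.set_xlabel("minute of 6MW")
        ax.set_ylabel("gait speed (feet/min)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(_track(out / "baseline_trajectories.png"), dpi=120)
        plt.close(fig)

    stage_simulate()
    stage_gmm()
    stage_cdp()
    stage_lme()
    stage_evaluate()
    if config.make_figures:
        stage_figures()

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            "k_max": config.k_max,
            "n_starts": config.n_starts,
            "fdr_level": config.fdr_level,
            "baselines": list(config.baselines),
            "cohort": {
                "n_hc": config.cohort.n_hc,
                "n_lrp": config.cohort.n_lrp,
                "n_hrp": config.cohort.n_hrp,
                "missingness": list(config.cohort.missingness),
            },
        },
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
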