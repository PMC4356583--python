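"""Run configuration, named RNG streams, logging and the full pipeline.

Every stochastic stage draws from a named stream derived from (base seed,
stream label) via a counter-free hash, so adding a stage never shifts
another stage's draws.  ``run_pipeline`` executes
generate -> impute -> train -> evaluate -> hr -> tree -> allocate as
configured, stamps every artifact with the config hash, and writes a
manifest listing all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("ihtsa")


def configure_logging(verbosity: int = 1) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(level=level, format="%(message)s")


def log_event(stage: str, **kv) -> None:
    """Line-delimited key=value event logging."""
    parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in kv.items()]
    log.info(" ".join(parts))


def stream_seed(base_seed: int, label: str) -> np.random.SeedSequence:
    """Named, order-independent RNG stream for (base seed, label)."""
    return np.random.SeedSequence((int(base_seed), zlib.crc32(label.encode())))


def stream_rng(base_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(base_seed, label))


def stream_int(base_seed: int, label: str) -> int:
    """A derived integer seed below 2^31 for APIs that take plain ints."""
    return int(stream_seed(base_seed, label).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "ihtsa-run"
    verbosity: int = 1
    # generate
    n: int = 5000
    missing: bool = True
    # split
    dc_fraction: float = 0.83
    # impute
    m: int = 10
    stratify: str = "era"
    # train
    K: int = 25
    hidden: int = 18
    decay: float = 1e-4
    epochs: int = 400
    folds: int = 5
    # hazard ratios
    hr_variables: tuple[str, ...] = ("donor_age", "creatinine", "ecmo", "diabetes")
    hr_times: tuple[float, ...] = (1.0, 5.0, 10.0)
    bootstrap_B: int = 0  # 0 disables the bootstrap stage
    # tree
    cc_alpha: float = 0.0035
    min_leaf: int = 50
    # allocation
    nw: int = 50
    donor_draws: int = 1000
    policies: tuple[str, ...] = ("ihtsa", "clinical", "random")
    stages: tuple[str, ...] = (
        "generate", "impute", "train", "evaluate", "hr", "tree", "allocate"
    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("hr_variables", "hr_times", "policies", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        """Digest of the scientific configuration (output location and
        verbosity excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "verbosity")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def validate(self) -> None:
        if "hr" in self.stages and "train" not in self.stages:
            raise ValueError("stage 'hr' requires stage 'train'")
        if "tree" in self.stages and "train" not in self.stages:
            raise ValueError("stage 'tree' requires stage 'train'")
        if "allocate" in self.stages and "ihtsa" in self.policies and "train" not in self.stages:
            raise ValueError("stage 'allocate' with the ihtsa policy requires stage 'train'")
        if "evaluate" in self.stages and "train" not in self.stages:
            raise ValueError("stage 'evaluate' requires stage 'train'")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    from . import alloc as alloc_mod
    from . import hazard as hazard_mod
    from . import metrics as metrics_mod
    from . import synth, tree as tree_mod
    from .impute import impute_probability
    from .model import (
        TrainConfig,
        ensemble_hazards,
        median_from_hazards,
        save_model,
        survival_probability,
        train_ensemble,
    )
    from .registry import split_cohort, write_cohort

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest: dict = {"config_hash": cfg_hash, "artifacts": {}, "stages": []}
    state: dict = {}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path)

    def stage(name: str):
        return name in config.stages

    try:
        if stage("generate"):
            gen = synth.GeneratorConfig(n=config.n, seed=stream_int(config.seed, "generate"))
            cohort, truth = synth.generate_cohort(gen)
            if config.missing:
                cohort = synth.inject_missingness(cohort, gen)
            state["cohort"], state["truth"] = cohort, truth
            path = out / "cohort.csv"
            write_cohort(cohort, path)
            record("cohort", path)
            log_event("generate", n=cohort.n, hash=cfg_hash)
            manifest["stages"].append("generate")

        if stage("impute") or stage("train"):
            cohort = state["cohort"]
            dc, ivc = split_cohort(
                cohort, (config.dc_fraction, 1 - config.dc_fraction),
                seed=stream_int(config.seed, "split"),
            )
            state["dc"], state["ivc"] = dc, ivc
            imp = impute_probability(
                dc, m=config.m, stratify=config.stratify,
                seed=stream_int(config.seed, "impute"),
            )
            state["imputed"] = imp
            log_event("impute", m=config.m, strata=config.stratify)
            manifest["stages"].append("impute")

        if stage("train"):
            tc = TrainConfig(
                hidden=config.hidden, decay=config.decay, epochs=config.epochs,
                folds=config.folds, seed=stream_int(config.seed, "train"),
            )
            model = train_ensemble(state["imputed"], tc, K=config.K)
            state["model"], state["train_config"] = model, tc
            path = out / "model.json"
            save_model(model, path)
            record("model", path)
            log_event("train", members=model.M, K=model.grid.K, hidden=config.hidden)
            manifest["stages"].append("train")

        if stage("evaluate"):
            model = state["model"]
            ivc_imp = impute_probability(
                state["ivc"], m=1, stratify=config.stratify,
                seed=stream_int(config.seed, "evaluate-impute"),
            )
            ivc_complete = ivc_imp.cohorts[0]
            hz = ensemble_hazards(model, ivc_complete)
            med = median_from_hazards(hz, model.grid)
            t = ivc_complete.df["followup_years"].to_numpy(float)
            d = ivc_complete.df["death"].to_numpy(float)
            conc = metrics_mod.harrell_c(med, t, d)
            s1 = survival_probability(hz, model.grid, 1.0)
            labels, include, n_excl = metrics_mod.one_year_labels(t, d)
            roc = metrics_mod.auroc(1 - s1[include], labels)
            hl = metrics_mod.hosmer_lemeshow(1 - s1[include], labels)
            recal = metrics_mod.recalibrate_logistic(1 - s1[include], labels)
            results = {
                "config_hash": cfg_hash,
                "n_validation": int(ivc_complete.n),
                "harrell_c": conc.c,
                "harrell_c_ci": [conc.ci_lower, conc.ci_upper],
                "auroc_1yr": roc.auc,
                "auroc_1yr_se": float(np.sqrt(roc.variance)),
                "excluded_1yr_labels": n_excl,
                "hosmer_lemeshow_chi2": hl.chi2,
                "hosmer_lemeshow_p": hl.p,
                "calibration_intercept": recal.intercept,
                "calibration_slope": recal.slope,
                "mean_predicted_median_years": float(med.mean()),
            }
            path = out / "metrics.json"
            path.write_text(json.dumps(results, indent=2))
            record("metrics", path)
            state["metrics"] = results
            log_event("evaluate", c=round(conc.c, 4), auroc=round(roc.auc, 4))
            manifest["stages"].append("evaluate")

        if stage("hr"):
            model = state["model"]
            dc_ref = state["imputed"].cohorts[0]
            rows = []
            for var in config.hr_variables:
                if var in model.designs[0].degenerate:
                    continue
                est = hazard_mod.estimate_hr(model, dc_ref, var, times=config.hr_times)
                if config.bootstrap_B >= 100:
                    est = hazard_mod.bootstrap_hr_ci(
                        model, dc_ref, var, B=config.bootstrap_B,
                        seed=stream_int(config.seed, f"hr-{var}"),
                        times=config.hr_times, config=state["train_config"],
                    )
                row = {"variable": var, "increment": est.increment, "config_hash": cfg_hash}
                for tt in config.hr_times:
                    row[f"hr_{tt:g}y"] = est.hr[float(tt)]
                    if est.ci:
                        row[f"hr_{tt:g}y_lo"], row[f"hr_{tt:g}y_hi"] = est.ci[float(tt)]
                rows.append(row)
            import pandas as pd

            path = out / "hr.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            record("hr", path)
            state["hr"] = rows
            log_event("hr", variables=len(rows))
            manifest["stages"].append("hr")

        if stage("tree"):
            model = state["model"]
            dc_ref = state["imputed"].cohorts[0]
            adjusted = tree_mod.adjust_to_latest_era(dc_ref)
            target = model.predict_median(adjusted)
            feats = dc_ref.df[list(tree_mod.DEFAULT_TREE_FEATURES)]
            fitted = tree_mod.fit_tree(feats, target, min_leaf=config.min_leaf)
            pruned = tree_mod.prune_tree(fitted, config.cc_alpha)
            payload = tree_mod.tree_to_dict(pruned)
            payload["config_hash"] = cfg_hash
            path = out / "tree.json"
            path.write_text(json.dumps(payload, indent=2))
            record("tree", path)
            state["tree"] = pruned
            log_event("tree", leaves=len(pruned.leaves()))
            manifest["stages"].append("tree")

        if stage("allocate"):
            model = state.get("model")
            pool_imp = impute_probability(
                state["ivc"], m=1, stratify=config.stratify,
                seed=stream_int(config.seed, "allocate-impute"),
            )
            pool = pool_imp.cohorts[0]
            run = alloc_mod.run_simulation(
                pool, nw=config.nw, n_donor_draws=config.donor_draws,
                policies=config.policies, model=model,
                seed=stream_int(config.seed, "allocate"),
            )
            summary = {
                "config_hash": cfg_hash,
                "nw": run.nw,
                "donor_draws": run.n_donor_draws,
                "policies": {
                    p: {
                        "transplants": tr.transplants,
                        "refusals": tr.refusals,
                        "mean_predicted_median_years": (
                            float(np.nanmean(tr.predicted_medians))
                            if tr.matches else None
                        ),
                    }
                    for p, tr in run.traces.items()
                },
            }
            path = out / "allocation.json"
            path.write_text(json.dumps(summary, indent=2))
            record("allocation", path)
            state["allocation"] = run
            log_event("allocate", **{p: tr.transplants for p, tr in run.traces.items()})
            manifest["stages"].append("allocate")
    except Exception as err:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(
            f"pipeline failed after stages {manifest['stages']}: {err}"
        ) from err

    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    state["manifest"] = manifest
    return state
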