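"""End-to-end orchestration: simulate -> candidates -> process -> features -> evaluate.

Each stage is a pure function of (inputs, config, seed) writing plain-text
outputs under the run directory; ``run_all`` chains them and records a run
manifest (config hash, seeds, output checksums, QC exclusions, chosen
features, per-model metrics) sufficient to reproduce the run bit-for-bit.
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

from . import candidates as cand
from . import evaluate as ev
from . import features as feat
from . import prm
from . import synthetic as syn

logger = logging.getLogger("glycoprm")

__all__ = ["RunManifest", "load_config", "run_all", "DEFAULT_CONFIG"]

#: every threshold of the method, with the published values as defaults
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_pca": 79, "n_bph": 84, "n_nag": 26, "n_ag": 53},
    "signal": {
        "enrichment_cv": 0.10,
        "heavy_spike_cv": 0.05,
        "measurement_cv": 0.08,
        "biological_cv": 0.40,
        "frac_discordant_runs": 32.0 / 163.0,
        "frac_low_recovery_runs": 0.0,
        "duplicate": True,
    },
    "filter": {
        "p_max": 0.1,
        "fc_min": 1.2,
        "fc_rescue_min": 1.08,
        "max_length": 25,
        "max_missed_cleavages": 1,
    },
    "qc": {"srd_max": 0.50, "sd_mult": 2.0},
    "selection": {"cap": 20, "min_votes": 4},
    "split": {"holdout_greyzone": 20, "train_frac": 0.70, "greyzone_range": [4.0, 10.0]},
    "evaluate": {"n_boot": 2000, "aggressiveness": True},
}

_NUMERIC = (int, float)
_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "cohort": {"n_pca": int, "n_bph": int, "n_nag": int, "n_ag": int},
    "signal": {
        "enrichment_cv": _NUMERIC,
        "heavy_spike_cv": _NUMERIC,
        "measurement_cv": _NUMERIC,
        "biological_cv": _NUMERIC,
        "frac_discordant_runs": _NUMERIC,
        "frac_low_recovery_runs": _NUMERIC,
        "duplicate": bool,
    },
    "filter": {
        "p_max": _NUMERIC,
        "fc_min": _NUMERIC,
        "fc_rescue_min": _NUMERIC,
        "max_length": int,
        "max_missed_cleavages": int,
    },
    "qc": {"srd_max": _NUMERIC, "sd_mult": _NUMERIC},
    "selection": {"cap": int, "min_votes": int},
    "split": {
        "holdout_greyzone": int,
        "train_frac": _NUMERIC,
        "greyzone_range": list,
    },
    "evaluate": {"n_boot": int, "aggressiveness": bool},
}


def load_config(source: dict | str | Path | None = None) -> dict:
    """Merge a config mapping or YAML file over the defaults and validate.

    Schema violations are collected and reported together, each with its
    dotted field path.
    """
    user: dict = {}
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        user = source

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    errors: list[str] = []
    for key, value in user.items():
        if key == "seed":
            if not isinstance(value, int):
                errors.append("seed: expected int")
            else:
                cfg["seed"] = value
            continue
        if key not in _SCHEMA:
            errors.append(f"{key}: unknown section")
            continue
        if not isinstance(value, dict):
            errors.append(f"{key}: expected a mapping")
            continue
        for sub, sval in value.items():
            if sub not in _SCHEMA[key]:
                errors.append(f"{key}.{sub}: unknown field")
                continue
            expected = _SCHEMA[key][sub]
            ok = (
                isinstance(sval, bool)
                if expected is bool
                else isinstance(sval, expected) and not isinstance(sval, bool)
            )
            if not ok:
                errors.append(f"{key}.{sub}: expected {expected}")
            else:
                cfg[key][sub] = sval
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    qc_exclusions: list[dict] = field(default_factory=list)
    features: list[str] = field(default_factory=list)
    ag_features: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    voting: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _register(manifest: RunManifest, out: Path, *paths: Path) -> None:
    for p in paths:
        manifest.files[str(p.relative_to(out))] = _sha256(p)


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_select_candidates(cfg: dict, out: Path) -> dict:
    """Discovery filtering and merging on the packaged candidate tables."""
    policy = cand.FilterPolicy(**cfg["filter"])
    tmta = cand.filter_candidates(cand.load_candidate_table("tmt_a"), policy)
    tmtb = cand.filter_candidates(cand.load_candidate_table("tmt_b"), policy)
    t3d = cand.load_candidate_table("3d")
    merged = cand.merge_candidate_lists(
        tmta[tmta["retained"]].drop(columns=["retained", "rejection_reason"]),
        tmtb[tmtb["retained"]].drop(columns=["retained", "rejection_reason"]),
        t3d,
    )
    panel = cand.load_verification_panel()
    merged.to_csv(out / "candidates_merged.tsv", sep="\t", index=False)
    panel.to_csv(out / "verification_panel.tsv", sep="\t", index=False)
    counts = {
        "tmta_retained": int(tmta["retained"].sum()),
        "tmtb_retained": int(tmtb["retained"].sum()),
        "candidates_merged": len(merged),
        "candidate_proteins": cand.n_proteins(merged),
        "panel_peptides": len(panel),
        "panel_proteins": cand.n_proteins(panel),
    }
    logger.info("candidate selection: %s", counts)
    return counts


def stage_simulate(cfg: dict, out: Path, seed: int) -> dict:
    """Generate the synthetic cohort and PRM run tables."""
    cohort_cfg = syn.CohortConfig(**cfg["cohort"], seed=seed)
    signal = syn.SignalConfig(**cfg["signal"])
    cohort, runs, truth = syn.generate_dataset(cohort_cfg, signal)
    paths = syn.write_dataset(out, cohort, runs, truth)
    n_runs = len(runs[["sample_id", "replicate_idx"]].drop_duplicates())
    logger.info("simulated %d samples, %d LC-MS runs", len(cohort), n_runs)
    return {
        "paths": paths,
        "n_samples": len(cohort),
        "n_runs_generated": int(n_runs),
        "informative_features": truth["informative_features"],
    }


def stage_process(cfg: dict, out: Path) -> dict:
    """QC-filter the run table and assemble the quantification matrix."""
    runs_path = out / "prm_runs.tsv"
    clinical_path = out / "clinical.csv"
    for p in (runs_path, clinical_path):
        if not p.exists():
            raise FileNotFoundError(f"required stage input missing: {p}")
    runs = pd.read_csv(runs_path, sep="\t")
    clinical = pd.read_csv(clinical_path)
    retained, report = prm.qc_filter(
        runs, srd_max=cfg["qc"]["srd_max"], sd_mult=cfg["qc"]["sd_mult"]
    )
    for _, row in report.dropped.iterrows():
        logger.warning(
            "excluded run %s/replicate %d: %s",
            row["sample_id"], row["replicate_idx"], row["reason"],
        )
    panel = cand.load_verification_panel()
    matrix = prm.assemble_matrix(retained, clinical, panel)
    report.srd.to_csv(out / "qc_srd.tsv", sep="\t", index=False)
    report.dropped.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    matrix.to_csv(out / "quant_matrix.csv", index=False)
    return {
        "qc": report.summary(),
        "exclusions": report.dropped.to_dict("records"),
        "n_matrix_samples": len(matrix),
    }


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    panel = cand.load_verification_panel()
    peptides = [p for p in panel["peptide_id"] if p in matrix.columns]
    clin = [c for c in prm.CLINICAL_COLUMNS if c in matrix.columns]
    return peptides + clin


def stage_select_features(cfg: dict, out: Path, seed: int) -> dict:
    """Consensus feature selection on the assembled matrix."""
    matrix = pd.read_csv(out / "quant_matrix.csv")
    cols = _feature_columns(matrix)
    X = matrix[cols]
    grid = feat.select_features(
        X, matrix["diagnosis"], cap=cfg["selection"]["cap"], seed=seed
    )
    chosen = feat.consensus(grid, min_votes=cfg["selection"]["min_votes"])
    grid.to_csv(out / "selection_matrix.tsv", sep="\t")
    (out / "consensus_features.txt").write_text("\n".join(chosen) + "\n")
    logger.info("consensus features (%d): %s", len(chosen), chosen)
    return {"features": chosen, "grid": grid}


def stage_evaluate(cfg: dict, out: Path, seed: int) -> dict:
    """Split, train, score, vote on the grey zone, and the AG sub-analysis."""
    matrix = pd.read_csv(out / "quant_matrix.csv")
    features = (out / "consensus_features.txt").read_text().split()
    spec = ev.SplitSpec(
        holdout_greyzone=cfg["split"]["holdout_greyzone"],
        train_frac=cfg["split"]["train_frac"],
        greyzone_range=tuple(cfg["split"]["greyzone_range"]),
        seed=seed,
    )
    parts = ev.split(matrix, spec)
    n_boot = cfg["evaluate"]["n_boot"]
    report = ev.train_and_score(
        parts["train"], parts["test"], features, seed=seed, n_boot=n_boot
    )
    build = pd.concat([parts["train"], parts["test"]])
    f1_weights = {n: ms.metrics["f1"] for n, ms in report.models.items()}
    votes = ev.greyzone_vote(
        build, parts["greyzone"], features, f1_weights, seed=seed
    )
    report.voting = votes

    metrics = {
        name: {
            "metrics": ms.metrics,
            "ci": {k: list(v) for k, v in ms.ci.items()},
            "confusion": ms.confusion.tolist(),
        }
        for name, ms in report.models.items()
    }
    result = {
        "split_sizes": {k: len(v) for k, v in parts.items()},
        "models": metrics,
        "baseline": report.baseline,
        "delong": report.delong,
        "voting": {
            "hard_correct": int(votes["hard_correct"].sum()),
            "soft_correct": int(votes["soft_correct"].sum()),
            "n_greyzone": len(votes),
        },
    }

    ag_features: list[str] = []
    if cfg["evaluate"]["aggressiveness"]:
        pca = matrix[matrix["aggressiveness"].isin(["AG", "NAG"])]
        cols = _feature_columns(pca)
        ag_grid = feat.select_features(
            pca[cols], pca["aggressiveness"], cap=cfg["selection"]["cap"], seed=seed
        )
        ag_features = feat.consensus(ag_grid, min_votes=cfg["selection"]["min_votes"])
        if len(ag_features) < 3:
            # sparse consensus at this cohort size: fall back to the top 8 by votes
            ag_features = list(
                ag_grid.sort_values(["total", "mean_rank"], ascending=[False, True])
                .head(8)
                .index
            )
        ag_report = ev.run_aggressiveness(
            matrix, ag_features, train_frac=cfg["split"]["train_frac"],
            seed=seed, n_boot=n_boot,
        )
        result["aggressiveness"] = {
            "features": ag_features,
            "models": {
                name: {"metrics": ms.metrics, "ci": {k: list(v) for k, v in ms.ci.items()}}
                for name, ms in ag_report.models.items()
            },
        }

    (out / "evaluation.json").write_text(json.dumps(result, indent=2, default=float))
    votes.to_csv(out / "greyzone_votes.tsv", sep="\t")
    _plot_roc(report, out / "roc_curves.png")
    result["ag_features"] = ag_features
    return result


def _plot_roc(report: ev.EvaluationReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, ms in report.models.items():
        ax.plot(*ms.roc, label=f"{name} (AUC {ms.metrics['auc']:.2f})")
    if report.baseline:
        ax.plot(
            [], [], " ",
            label=f"{report.baseline['marker']} baseline AUC {report.baseline['auc']:.2f}",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def synthetic_recovery_run(
    seed: int,
    cap: int = 20,
    min_votes: int = 4,
    n_boot: int = 0,
    model_names: tuple[str, ...] = ev.DEFAULT_MODELS,
) -> dict:
    """One desk-scale study replicate: simulate, QC, select, train, score.

    Used to measure how reliably the planted signal is recovered under the
    default study-design conditions; returns the selection grid vote totals,
    the truth sidecar's recoverable-feature list, and the held-out AUCs of
    the random forest and the univariate tPSA baseline.
    """
    cohort, runs, truth = syn.generate_dataset(seed=seed)
    retained, report = prm.qc_filter(runs)
    panel = cand.load_verification_panel()
    matrix = prm.assemble_matrix(retained, cohort, panel)
    cols = _feature_columns(matrix)
    grid = feat.select_features(matrix[cols], matrix["diagnosis"], cap=cap, seed=seed)
    chosen = feat.consensus(grid, min_votes=min_votes)
    parts = ev.split(matrix, ev.SplitSpec(seed=seed))
    rep = ev.train_and_score(
        parts["train"], parts["test"], chosen, seed=seed, n_boot=n_boot,
        model_names=model_names,
    )
    return {
        "informative": truth["informative_features"],
        "votes": grid["total"].to_dict(),
        "consensus": chosen,
        "rf_auc": rep.models["random_forest"].metrics["auc"],
        "tpsa_auc": rep.baseline["auc"],
        "delong": rep.delong,
        "qc": report.summary(),
        "matrix": matrix,
        "parts": parts,
        "report": rep,
    }


def run_all(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "glycoprm_run",
    seed: int | None = None,
) -> RunManifest:
    """Execute the whole pipeline and write outputs + manifest under out_dir."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from . import __version__

    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=cfg["seed"],
        package_version=__version__,
    )

    logger.info("stage 1/5: candidate selection")
    counts = stage_select_candidates(cfg, out)
    manifest.counts.update(counts)

    logger.info("stage 2/5: simulation")
    sim = stage_simulate(cfg, out, cfg["seed"])
    manifest.counts["n_samples"] = sim["n_samples"]
    manifest.counts["n_runs_generated"] = sim["n_runs_generated"]

    logger.info("stage 3/5: PRM processing")
    proc = stage_process(cfg, out)
    manifest.counts["n_runs_retained"] = proc["qc"]["n_runs_retained"]
    manifest.qc_exclusions = proc["exclusions"]

    logger.info("stage 4/5: feature selection")
    sel = stage_select_features(cfg, out, cfg["seed"])
    manifest.features = sel["features"]

    logger.info("stage 5/5: evaluation")
    evl = stage_evaluate(cfg, out, cfg["seed"])
    manifest.metrics = {k: v for k, v in evl.items() if k in ("models", "baseline", "delong", "aggressiveness", "split_sizes")}
    manifest.voting = evl["voting"]
    manifest.ag_features = evl["ag_features"]

    _register(
        manifest, out,
        *[p for p in out.iterdir() if p.is_file() and p.suffix in (".tsv", ".csv", ".txt", ".json")],
    )
    manifest.write(out / "manifest.json")
    logger.info("run complete: %s", out / "manifest.json")
    return manifest
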