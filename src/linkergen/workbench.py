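"""Run orchestration: configuration, artifact IO, and the commands tying the
modules into the design workflow (train predictor → train generator →
design → report).

Every run writes a JSON manifest carrying the configuration hash, the seed
and the package version, so a run is reproducible from its manifest alone.
Per-run seeds are derived as ``seed + run_index``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import kmedoids_cluster, moving_average, similarity_report, top_k_by_reward
from .chem import BIT_FP_2048, FingerprintSpec, morgan_fingerprint, parse_ligand
from .errors import ConfigError
from .filters import (
    FilterConfig,
    FilterReferences,
    default_alert_patterns,
    default_specific_patterns,
    load_smarts_file,
)
from .generator import (
    EvaluationContext,
    GenerationEntry,
    GenerationLog,
    RewardConfig,
    augment_corpus,
    evaluate_candidate,
    mcts_search,
)
from .permeability import PermeabilityDataset, PermeabilityRegressor, loocv_evaluate
from .policy import SmilesPolicy

logger = logging.getLogger("linkergen")


# ---------------------------------------------------------------------------
# SMILES file IO
# ---------------------------------------------------------------------------


def read_smiles_file(path) -> list[str]:
    """One SMILES per line, optional tab-separated ID.

    Lines starting with '#' are comments ('#' inside a SMILES is triple-bond
    syntax, so only leading '#' comments are supported).
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def write_smiles_file(path, smiles: list[str], ids: list[str] | None = None) -> None:
    lines = (
        [f"{s}\t{i}" for s, i in zip(smiles, ids)] if ids is not None else list(smiles)
    )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of a design run."""

    corpus: str | None = None
    permeability_table: str | None = None
    poi: str | None = None
    e3: str | None = None
    model_archive: str | None = None
    policy_archive: str | None = None
    alert_smarts: str | None = None
    specific_smarts: str | None = None
    output_dir: str = "runs"
    preset: str = "strict"
    budget: int = 1000
    n_runs: int = 1
    seed: int = 0
    epochs: int = 15
    n_randomizations: int = 4
    regressor: str = "gbt"
    skip_alert: bool = False
    ucb_c: float = 1.0
    expansion_k: int = 10
    min_expand_prob: float = 0.02
    top_k: int = 5000
    n_clusters: int = 10
    trend_window: int = 500
    reward: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)
    policy: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.budget < 1:
            raise ConfigError("budget must be >= 1")
        if self.preset not in ("relaxed", "intermediate", "strict"):
            raise ConfigError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def require_files(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config field {name!r} is required for this command")
            if not Path(value).exists():
                raise ConfigError(f"{name} file not found: {value}")

    def reward_config(self) -> RewardConfig:
        return RewardConfig(**self.reward)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filters)

    def fingerprint_spec(self) -> FingerprintSpec:
        return FingerprintSpec(**{"radius": 2, "dim": 500, "counted": True, **self.fingerprint})

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "config_hash": config.digest(),
        "version": __version__,
        "seed": config.seed,
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------


def cmd_train_predictor(config: RunConfig) -> dict:
    """Curate the permeability table, run LOOCV, fit and archive the model."""
    config.require_files("permeability_table")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spec = config.fingerprint_spec()
    dataset = PermeabilityDataset.from_csv(config.permeability_table, spec)
    est = PermeabilityRegressor(
        regressor=config.regressor,
        radius=spec.radius,
        dim=spec.dim,
        counted=spec.counted,
        random_state=config.seed,
    )
    metrics, table = loocv_evaluate(dataset, est)
    table.to_csv(out_dir / "loocv_predictions.csv", index=False, float_format="%.10g")
    est.fit_dataset(dataset)
    archive = config.model_archive or str(out_dir / "permeability_model.joblib")
    est.save(archive)
    report = {
        "n_compounds": len(dataset),
        "r2": metrics.r2,
        "r": metrics.r,
        "rmse": metrics.rmse,
        "model_archive": archive,
    }
    (out_dir / "loocv_metrics.json").write_text(json.dumps(report, indent=2) + "\n")
    _write_manifest(out_dir, config, {"command": "train-predictor"})
    logger.info("LOOCV on %d compounds: R2=%.3f R=%.3f RMSE=%.3f",
                len(dataset), metrics.r2, metrics.r, metrics.rmse)
    return report


def cmd_train_generator(config: RunConfig) -> SmilesPolicy:
    """Augment the linker corpus and train the recurrent policy."""
    config.require_files("corpus")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    linkers = read_smiles_file(config.corpus)
    corpus = augment_corpus(linkers, config.n_randomizations, seed=config.seed)
    policy = SmilesPolicy(
        epochs=config.epochs, random_state=config.seed, **config.policy
    ).fit(corpus)
    archive = config.policy_archive or str(out_dir / "policy.joblib")
    joblib.dump(policy, archive)
    _write_manifest(
        out_dir,
        config,
        {
            "command": "train-generator",
            "corpus_size": len(corpus),
            "final_loss": policy.losses_[-1],
        },
    )
    logger.info("trained policy on %d strings; loss %.4f -> %.4f",
                len(corpus), policy.losses_[0], policy.losses_[-1])
    return policy


def build_references(config: RunConfig, model: PermeabilityRegressor) -> FilterReferences:
    """Assemble the reference data the filter cascade needs."""
    if config.poi is None or config.e3 is None:
        raise ConfigError("poi and e3 ligand SMILES are required")
    poi = parse_ligand(config.poi, "POI")
    e3 = parse_ligand(config.e3, "E3")
    cfg = config.filter_config()
    linker_fps = None
    if config.corpus and Path(config.corpus).exists():
        linker_fps = [
            morgan_fingerprint(s, cfg.similarity_fp) for s in read_smiles_file(config.corpus)
        ]
    alert = (
        load_smarts_file(config.alert_smarts)
        if config.alert_smarts
        else default_alert_patterns()
    )
    specific = (
        load_smarts_file(config.specific_smarts)
        if config.specific_smarts
        else default_specific_patterns()
    )
    return FilterReferences(
        poi=poi,
        e3=e3,
        linker_fps=linker_fps,
        protac_fps=getattr(model, "train_ad_fps_", None),
        alert_patterns=alert,
        specific_patterns=specific,
    )


def cmd_design(config: RunConfig) -> list[GenerationLog]:
    """Run ``n_runs`` independent searches, one log CSV per run."""
    config.require_files("model_archive", "policy_archive")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = PermeabilityRegressor.load(config.model_archive)
    policy = joblib.load(config.policy_archive)
    refs = build_references(config, model)
    ctx = EvaluationContext(
        model=model,
        preset=config.preset,
        filter_config=config.filter_config(),
        references=refs,
        reward=config.reward_config(),
        skip_alert=config.skip_alert,
    )

    logs = []
    for run in range(config.n_runs):
        run_seed = config.seed + run
        log = mcts_search(
            policy,
            lambda s: evaluate_candidate(s, ctx),
            budget=config.budget,
            seed=run_seed,
            ucb_c=config.ucb_c,
            expansion_k=config.expansion_k,
            min_expand_prob=config.min_expand_prob,
            preset=config.preset,
        )
        log.to_csv(out_dir / f"generation_run{run}.csv")
        logs.append(log)
        rewards = log.rewards()
        logger.info("run %d (seed %d): %d candidates, max reward %.3f",
                    run, run_seed, len(log.entries), rewards.max() if rewards.size else 0.0)
    _write_manifest(
        out_dir,
        config,
        {"command": "design", "n_runs": config.n_runs, "budget": config.budget},
    )
    return logs


def cmd_report(config: RunConfig, log_paths: list[str]) -> dict:
    """Trend, top-k, clustering and similarity reports for design logs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not log_paths:
        raise ConfigError("at least one generation log is required")

    frames = [pd.read_csv(p, keep_default_na=False) for p in log_paths]
    outputs = {}

    trend = pd.concat(
        [
            pd.DataFrame(
                {
                    "run": i,
                    "index": f["index"],
                    "reward": f["reward"],
                    "reward_ma": moving_average(f["reward"].to_numpy(), config.trend_window),
                }
            )
            for i, f in enumerate(frames)
        ],
        ignore_index=True,
    )
    trend.to_csv(out_dir / "reward_trend.csv", index=False, float_format="%.10g")
    outputs["trend"] = str(out_dir / "reward_trend.csv")

    merged = pd.concat(frames, ignore_index=True)
    merged["index"] = np.arange(len(merged))
    entries = [
        GenerationEntry(
            index=int(row["index"]),
            smiles=str(row["smiles"]),
            passed=(str(row["passed"]).lower() == "true"),
            failed_at=str(row["failed_at"]) or None,
            predicted_mean=float(row["predicted_mean"]) if row["predicted_mean"] != "" else float("nan"),
            reward=float(row["reward"]),
        )
        for _, row in merged.iterrows()
    ]
    log = GenerationLog(
        entries=entries, seed=config.seed, preset=config.preset, budget=len(merged)
    )
    top = top_k_by_reward(log, min(config.top_k, max(len(log.entries), 1)))
    top.to_csv(out_dir / "top_candidates.csv", index=False, float_format="%.10g")
    outputs["top_k"] = str(out_dir / "top_candidates.csv")

    def _parseable(strings):
        out = []
        for s in strings:
            try:
                morgan_fingerprint(s, BIT_FP_2048)
                out.append(s)
            except Exception:
                continue
        return out

    if top["passed"].any():
        smiles = top[top["passed"]]["canonical"].tolist()
    else:
        smiles = _parseable(top["canonical"].tolist())
    if smiles:
        fps = np.vstack([morgan_fingerprint(s, BIT_FP_2048) for s in smiles])
        k = min(config.n_clusters, len(smiles))
        assign = kmedoids_cluster(fps, k=k, seed=config.seed)
        clusters = pd.DataFrame(
            {
                "smiles": smiles,
                "cluster": assign.labels,
                "is_medoid": [
                    i in set(assign.medoid_indices.tolist()) for i in range(len(smiles))
                ],
            }
        )
    else:
        clusters = pd.DataFrame(columns=["smiles", "cluster", "is_medoid"])
        logger.warning("no candidates available for clustering")
    clusters.to_csv(out_dir / "clusters.csv", index=False)
    outputs["clusters"] = str(out_dir / "clusters.csv")

    if config.corpus and Path(config.corpus).exists() and smiles:
        sim = similarity_report(smiles, read_smiles_file(config.corpus))
    else:
        sim = pd.DataFrame(columns=["candidate", "max_similarity", "nearest_reference"])
    sim.to_csv(out_dir / "similarity.csv", index=False, float_format="%.10g")
    outputs["similarity"] = str(out_dir / "similarity.csv")

    _write_manifest(out_dir, config, {"command": "report", "n_logs": len(log_paths)})
    return outputs
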