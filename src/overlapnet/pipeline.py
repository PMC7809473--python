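"""End-to-end orchestration: config, seeding, run manifests, table export.

Two arms wired in sequence: unsupervised decomposition (simulate/extract ->
z-score -> train -> subnetwork analytics) and supervised trait prediction
from the latent embeddings. A master seed fans out to per-stage seeds by a
fixed offset scheme so stages can be re-run in isolation:

    simulate: seed + 0      train: seed + 1      predict: seed + 2
    splits:   seed + 3      per-architecture: train seed + 100 * index
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import load_atlas
from .autoencoders import (
    AutoencoderModel,
    CVPlan,
    canonical_specs,
    canonicalize_latents,
    train_autoencoder,
)
from .errors import InsufficientDataError, MissingFileError
from .roi import Scaler, VolumeMatrix, zscore_apply, zscore_fit
from .subnetworks import (
    cluster_relevance,
    compare_runs,
    per_subnetwork_score,
    relevance_matrix,
)
from .synthetic import SyntheticSpec, simulate_dataset
from .traits import (
    chance_level,
    dichotomize_trait,
    make_four_class_labels,
    nested_cv_classify,
    summarize_weights,
)


@dataclass
class RunConfig:
    mode: str = "synthetic"
    output_dir: str = "overlapnet_run"
    atlas: str = "default"
    seed: int = 0
    # synthetic-mode knobs (forwarded to SyntheticSpec)
    n_participants: int = 2000
    n_regions: int = 36
    n_factors: int = 15
    noise_sd: float = 0.5
    n_traits: int = 6
    trait_effect: float = 1.0
    # extraction (real mode)
    volumes_csv: str | None = None
    fwhm_mm: float = 5.0
    diameter_mm: float = 5.0
    zscore_scope: str = "train_only"  # "global", or "center_only" (no scaling)
    canonicalize: bool = True  # identify single-layer linear latents post-training
    # training
    architectures: tuple[str, ...] = ("baseline",)
    latent_dim: int = 15
    max_epochs: int = 300
    train_fraction: float = 0.5
    outer_folds: int = 5
    inner_folds: int = 10
    # prediction
    estimator: str = "logistic"
    run_prediction: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "architectures" in raw:
            raw["architectures"] = tuple(raw["architectures"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["architectures"] = list(d["architectures"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_inputs(config: RunConfig):
    """Volumes + covariates per mode. Synthetic mode generates both."""
    if config.mode == "synthetic":
        spec = SyntheticSpec(
            n_participants=config.n_participants,
            n_regions=config.n_regions,
            n_factors=config.n_factors,
            noise_sd=config.noise_sd,
            n_traits=config.n_traits,
            trait_effect=config.trait_effect,
            seed=config.seed + 0,
        )
        ds = simulate_dataset(spec)
        return ds.volumes, ds.covariates, ds
    if config.volumes_csv is None or not Path(config.volumes_csv).exists():
        raise MissingFileError(f"volumes CSV not found: {config.volumes_csv}")
    return VolumeMatrix.from_csv(config.volumes_csv), None, None


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate/extract -> train -> subnetworks -> predict, write artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config),
                           software_version=__version__)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    t0 = time.time()
    volumes, covariates, _ds = _load_inputs(config)
    emit("volumes_raw.csv", volumes.to_csv)
    if covariates is not None:
        emit("covariates.csv", lambda p: covariates.to_csv(p))
    manifest.stage_seconds["inputs"] = time.time() - t0

    # train/test split + z-scoring per configured scope
    t0 = time.time()
    rng = np.random.default_rng(config.seed + 3)
    n = volumes.n_participants
    perm = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    scaler_rows = train_idx if config.zscore_scope == "train_only" else np.arange(n)
    sub = VolumeMatrix(volumes.values[scaler_rows],
                       [volumes.participant_ids[i] for i in scaler_rows],
                       volumes.region_names)
    scaler = zscore_fit(sub)
    if config.zscore_scope == "center_only":
        scaler = Scaler(mean=scaler.mean, sd=np.ones_like(scaler.sd))
    z = zscore_apply(volumes, scaler)
    x_train, x_test = z.values[train_idx], z.values[test_idx]

    atlas = load_atlas(config.atlas) if z.n_regions == 36 else None
    models: dict[str, AutoencoderModel] = {}
    specs = canonical_specs(latent_dim=config.latent_dim, max_epochs=config.max_epochs)
    score_rows = []
    for ai, arch in enumerate(config.architectures):
        spec = specs[arch]
        spec.seed = config.seed + 1 + 100 * ai
        model = train_autoencoder(spec, x_train, x_test)
        if (config.canonicalize and spec.activation == "identity"
                and len(spec.latent_layers) == 1):
            model = canonicalize_latents(model, x_train)
        models[arch] = model
        emit(f"model_{arch}.json", model.to_json)
        emit(f"training_log_{arch}.csv",
             lambda p, m=model: pd.DataFrame(m.training_log).to_csv(p, index=False))
        score_rows.append({"architecture": arch, "test_score": model.score(x_test),
                           "test_mae": 1.0 - model.score(x_test)})

        ranking = per_subnetwork_score(model, x_test)
        emit(f"subnetwork_ranking_{arch}.csv",
             lambda p, r=ranking: r.to_frame().to_csv(p, index=False))
        rel = relevance_matrix(model, z.region_names)
        emit(f"relevance_{arch}.csv", lambda p, r=rel: r.to_frame().to_csv(p))
        if atlas is not None:
            agg = cluster_relevance(rel, atlas)
            emit(f"cluster_relevance_{arch}.csv", lambda p, a=agg: a.to_csv(p))
    emit("architecture_scores.csv",
         lambda p: pd.DataFrame(score_rows).to_csv(p, index=False))
    manifest.stage_seconds["train_subnetworks"] = time.time() - t0

    if config.run_prediction and covariates is not None:
        t0 = time.time()
        primary = models[config.architectures[0]]
        embeddings = primary.encode(z.values)
        cv_plan = CVPlan(outer_folds=config.outer_folds,
                         inner_folds=config.inner_folds, seed=config.seed + 2)
        reports = {}
        trait_cols = [c for c in covariates.columns if c.startswith("trait_")]
        acc_rows = []
        for trait in trait_cols:
            binary, median = dichotomize_trait(covariates[trait].to_numpy())
            labels = make_four_class_labels(covariates["sex"].to_numpy(), binary,
                                            trait_id=trait, median=median)
            rep = nested_cv_classify(embeddings, covariates["age"].to_numpy(),
                                     labels, estimator=config.estimator,
                                     cv_plan=cv_plan, seed=config.seed + 2)
            reports[trait] = rep
            chance = chance_level(labels, mode="analytic")
            acc_rows.append({"trait": trait, "mean_accuracy": rep.mean_accuracy,
                             "sd_accuracy": rep.sd_accuracy, "chance": chance.value})
        emit("trait_accuracies.csv",
             lambda p: pd.DataFrame(acc_rows).to_csv(p, index=False))
        if config.estimator == "logistic":
            summary = summarize_weights(reports)
            emit("trait_weights_long.csv",
                 lambda p: summary["per_trait"].to_csv(p, index=False))
            emit("trait_weights_signed_mean.csv",
                 lambda p: summary["signed_mean"].to_csv(p))
            emit("trait_weights_abs_mean.csv",
                 lambda p: summary["abs_mean"].to_csv(p))
        manifest.stage_seconds["predict"] = time.time() - t0

    config.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    for path in written:
        manifest.outputs[path.name] = _sha256(path)
    manifest.to_json(out / "manifest.json")
    return manifest


def replicate(config: RunConfig, n_splits: int = 2) -> pd.DataFrame:
    """Run the pipeline on row-disjoint splits; pairwise-correlate solutions.

    Returns a long table with one row per split pair: mean/SD of matched
    |rho| between the two solutions' relevance matrices.
    """
    if n_splits < 1:
        raise InsufficientDataError("need at least one split")
    volumes, _, _ = _load_inputs(config)
    n = volumes.n_participants
    per_split = n // n_splits
    if per_split < 10 * config.n_factors:
        raise InsufficientDataError(
            f"{per_split} participants per split is too few for {config.n_factors} factors"
        )
    rng = np.random.default_rng(config.seed + 4)
    perm = rng.permutation(n)
    base_out = Path(config.output_dir)
    base_out.mkdir(parents=True, exist_ok=True)
    runs = []
    arch = config.architectures[0]
    for s in range(n_splits):
        rows = np.sort(perm[s * per_split:(s + 1) * per_split])
        split_vm = VolumeMatrix(volumes.values[rows],
                                [volumes.participant_ids[i] for i in rows],
                                volumes.region_names)
        split_dir = base_out / f"split_{s}"
        split_dir.mkdir(parents=True, exist_ok=True)
        split_vm.to_csv(split_dir / "volumes_in.csv")
        split_cfg = RunConfig(**{**asdict(config),
                                 "mode": "real",
                                 "volumes_csv": str(split_dir / "volumes_in.csv"),
                                 "output_dir": str(split_dir),
                                 "n_participants": per_split,
                                 "run_prediction": False,
                                 "architectures": tuple(config.architectures)})
        run_pipeline(split_cfg)
        runs.append(AutoencoderModel.from_json(split_dir / f"model_{arch}.json"))
    rows = []
    for i in range(n_splits):
        for j in range(i + 1, n_splits):
            report, _ = compare_runs(runs[i], runs[j])
            rows.append({"split_a": i, "split_b": j,
                         "mean_abs_rho": report.mean_abs_rho,
                         "sd_abs_rho": report.sd_abs_rho})
    df = pd.DataFrame(rows, columns=["split_a", "split_b", "mean_abs_rho", "sd_abs_rho"])
    df.to_csv(base_out / "replication_stability.csv", index=False)
    return df
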