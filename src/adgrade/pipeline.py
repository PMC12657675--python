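"""End-to-end orchestration: generate -> balance -> split -> optimize ->
train -> evaluate -> explain, under one config and one master seed.

Per-stage seeds derive from hash(master_seed, stage_name), so any stage can
be re-run independently yet reproducibly. The run report collects per-stage
dataset accounting, GA history, evaluation metrics, GAN quality statistics
and ROI attribution fractions, plus the seed and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import cnn_classifier, gan_balance, medga, preprocess, shap_attrib
from . import synthetic_mri as smri

STAGES = ("gen_data", "balance", "split", "optimize", "train", "explain")


@dataclass
class RunConfig:
    """One pipeline run. Defaults are the desk-scale smoke configuration."""

    class_sizes: tuple[int, int, int, int] = (40, 40, 40, 40)
    image_size: int = 32
    noise_sd: float = 0.03
    train_fraction: float = 0.80

    # GAN section
    gan_target_class: int = 3
    gan_n_synthetic: int = 0
    gan_epochs: int = 2
    gan_latent_dim: int = 100
    gan_batch_size: int = 32

    # GA section
    ga_backend: str = "surrogate"  # or "cnn"
    ga_population: int = 8
    ga_generations: int = 2
    ga_p_mut: float = 0.5
    ga_crossover_rate: float = 0.70
    ga_fitness_mode: str = "accuracy"
    ga_cnn_epochs: int = 3  # per-candidate training epochs (cnn backend)
    ga_layer_set: tuple[int, ...] = (2, 3)
    ga_filter_set: tuple[int, ...] = (8, 16, 32)
    ga_lr_set: tuple[float, ...] = medga.DEFAULT_LR_SET

    # final training section
    train_epochs: int = 5
    train_patience: int = 10
    batch_size: int = 32

    # explainability section
    shap_tile: int = 8
    shap_background: int = 100
    shap_permutations: int = 10
    shap_background_draws: int = 5

    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        order = {s: i for i, s in enumerate(STAGES)}
        idx = [order[s] for s in self.stages]
        if idx != list(range(len(idx))):
            raise ValueError("stages must be a prefix of the full stage order")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _counts(ds: smri.ImageDataset) -> list[int]:
    return list(preprocess.class_counts(ds))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stage prefix; returns the run report dict."""
    report: dict = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "stages": {},
    }
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- gen_data ---
    dataset = smri.generate_dataset(
        config.class_sizes,
        image_size=config.image_size,
        seed=stage_seed(config.seed, "gen_data"),
        noise_sd=config.noise_sd,
    )
    report["stages"]["gen_data"] = {"counts": _counts(dataset), "total": len(dataset)}
    if "balance" not in config.stages:
        return _finish(report, out_dir)

    # --- balance ---
    if config.gan_n_synthetic > 0:
        seed = stage_seed(config.seed, "balance")
        real = dataset.images[dataset.labels == config.gan_target_class]
        gcfg = gan_balance.GanConfig(
            latent_dim=config.gan_latent_dim,
            image_size=config.image_size,
            epochs=config.gan_epochs,
            batch_size=min(config.gan_batch_size, len(real)),
        )
        bundle = gan_balance.train_gan(real * 2.0 - 1.0, gcfg, seed)
        dataset = gan_balance.balance_class(
            dataset, config.gan_target_class, config.gan_n_synthetic, bundle, seed + 1
        )
        synth = dataset.images[np.asarray(dataset.provenance) == "synthetic"]
        ssim = gan_balance.ssim_stats(real * 2.0 - 1.0, synth * 2.0 - 1.0)
        overlap = gan_balance.intensity_overlap(real * 2.0 - 1.0, synth * 2.0 - 1.0)
        report["stages"]["balance"] = {
            "counts": _counts(dataset),
            "total": len(dataset),
            "n_synthetic": int((np.asarray(dataset.provenance) == "synthetic").sum()),
            "n_real": int((np.asarray(dataset.provenance) == "real").sum()),
            "ssim": ssim,
            "intensity_overlap": overlap,
            "gan_d_loss": bundle.d_losses,
            "gan_g_loss": bundle.g_losses,
        }
    else:
        report["stages"]["balance"] = {
            "counts": _counts(dataset),
            "total": len(dataset),
            "n_synthetic": 0,
            "n_real": len(dataset),
        }
    if "split" not in config.stages:
        return _finish(report, out_dir)

    # --- split ---
    split_spec = preprocess.SplitSpec(
        train_fraction=config.train_fraction, seed=stage_seed(config.seed, "split")
    )
    train_ds, test_ds = preprocess.stratified_split(dataset, split_spec)
    report["stages"]["split"] = {
        "train_counts": _counts(train_ds),
        "test_counts": _counts(test_ds),
        "train_total": len(train_ds),
        "test_total": len(test_ds),
    }
    if "optimize" not in config.stages:
        return _finish(report, out_dir)

    # --- optimize ---
    ga_seed = stage_seed(config.seed, "optimize")
    domains = medga.Domains(
        lr_set=tuple(config.ga_lr_set),
        layer_set=tuple(config.ga_layer_set),
        filter_set=tuple(config.ga_filter_set),
    )
    ga_cfg = medga.GAConfig(
        population_size=config.ga_population,
        generations=config.ga_generations,
        p_mut=config.ga_p_mut,
        crossover_rate=config.ga_crossover_rate,
        fitness_mode=config.ga_fitness_mode,
        seed=ga_seed,
    )
    shape = (config.image_size, config.image_size)
    counter = cnn_classifier.genome_param_counter(shape)
    # stratified validation subset carved from the training split
    fit_ds, val_ds = preprocess.stratified_split(
        train_ds, preprocess.SplitSpec(train_fraction=0.85, seed=ga_seed + 1)
    )
    weights = medga.class_weights(preprocess.class_counts(fit_ds))

    if config.ga_backend == "surrogate":
        rng = np.random.default_rng(ga_seed)
        target = domains.sample(rng)
        evaluator = medga.surrogate_evaluator(target, param_counter=counter)
    elif config.ga_backend == "cnn":
        evaluator = _cnn_evaluator(
            fit_ds, val_ds, weights, shape, config, counter, ga_seed
        )
    else:
        raise ValueError(f"unknown GA backend {config.ga_backend!r}")

    best, history = medga.evolve(domains, evaluator, ga_cfg)
    report["stages"]["optimize"] = {
        "backend": config.ga_backend,
        "best_genome": _genome_dict(best),
        "best_fitness": history[-1]["best_so_far"],
        "history": [
            {k: v for k, v in h.items() if k != "best_genome"} for h in history
        ],
        "best_param_count": counter(best.n_layers, best.filters),
    }
    if "train" not in config.stages:
        return _finish(report, out_dir)

    # --- train + evaluate ---
    tr_seed = stage_seed(config.seed, "train")
    spec = cnn_classifier.build_cnn(best, shape, n_classes=4)
    tcfg = cnn_classifier.TrainConfig(
        batch_size=config.batch_size,
        max_epochs=config.train_epochs,
        patience=min(config.train_patience, config.train_epochs),
        class_weights=weights,
        seed=tr_seed,
    )
    model = cnn_classifier.train(
        spec, fit_ds.images, fit_ds.labels, val_ds.images, val_ds.labels, tcfg
    )
    probs = model.predict_proba(test_ds.images)
    eval_report = cnn_classifier.evaluate(probs, test_ds.labels)
    report["stages"]["train"] = {
        "epochs_run": len(model.curves["train_loss"]),
        "final_train_acc": model.curves["train_acc"][-1],
        "final_val_acc": model.curves["val_acc"][-1],
        "test_accuracy": eval_report.accuracy,
        "eval": eval_report.to_dict(),
    }
    if "explain" not in config.stages:
        return _finish(report, out_dir)

    # --- explain ---
    ex_seed = stage_seed(config.seed, "explain")
    rng = np.random.default_rng(ex_seed)
    bg_idx = rng.choice(
        len(fit_ds), size=min(config.shap_background, len(fit_ds)), replace=False
    )
    background = shap_attrib.BackgroundSet(fit_ds.images[bg_idx])
    masks = smri.roi_masks(config.image_size)
    per_class = {}
    for c in range(4):
        cls_idx = np.flatnonzero(test_ds.labels == c)
        if len(cls_idx) == 0:
            continue
        img = test_ds.images[cls_idx[0]]
        attr = shap_attrib.image_attribution(
            model.predict_proba,
            img,
            background,
            target_class=c,
            tile=config.shap_tile,
            n_permutations=config.shap_permutations,
            background_draws=config.shap_background_draws,
            seed=ex_seed + c,
        )
        per_class[smri.CLASS_NAMES[c]] = {
            "base_value": attr.base_value,
            "predicted_class": attr.predicted_class,
            "roi_fraction_ventricle": shap_attrib.roi_fraction(attr, masks["ventricle"]),
            "roi_fraction_cortex": shap_attrib.roi_fraction(attr, masks["cortex"]),
            "roi_fraction_brain": shap_attrib.roi_fraction(
                attr, masks["ventricle"] | masks["cortex"]
            ),
        }
    report["stages"]["explain"] = {"per_class": per_class}
    return _finish(report, out_dir)


def _genome_dict(g: medga.Genome) -> dict:
    return {
        "lr": g.lr,
        "n_layers": g.n_layers,
        "filters": list(g.filters),
        "dropout": g.dropout,
    }


def _cnn_evaluator(fit_ds, val_ds, weights, shape, config: RunConfig, counter, seed):
    """Real fitness: train the candidate briefly, return validation accuracy."""

    def evaluator(genome: medga.Genome) -> tuple[float, int]:
        try:
            spec = cnn_classifier.build_cnn(genome, shape, n_classes=4)
        except cnn_classifier.ArchitectureError:
            return 0.0, counter(genome.n_layers, genome.filters)
        tcfg = cnn_classifier.TrainConfig(
            batch_size=config.batch_size,
            max_epochs=config.ga_cnn_epochs,
            patience=config.ga_cnn_epochs,
            class_weights=weights,
            seed=seed,
        )
        model = cnn_classifier.train(
            spec, fit_ds.images, fit_ds.labels, val_ds.images, val_ds.labels, tcfg
        )
        return model.curves["val_acc"][-1], cnn_classifier.count_parameters(spec)

    evaluator.param_counter = counter
    return evaluator


def _finish(report: dict, out_dir: Path | None) -> dict:
    if out_dir is not None:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n"
        )
        (out_dir / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = [
        "# Run report",
        "",
        f"- seed: {report['seed']}",
        f"- config hash: {report['config_hash']}",
        "",
    ]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        for key in ("counts", "total", "train_total", "test_total", "test_accuracy"):
            if key in info:
                lines.append(f"- {key}: {info[key]}")
        lines.append("")
    return "\n".join(lines)


__all__ = ["RunConfig", "STAGES", "stage_seed", "config_hash", "run_pipeline"]
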