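"""Joint optimization of the synthesizer and the registration network.

One Adam optimizer (beta1 = 0.5, beta2 = 0.999) updates both networks.  The
learning rate follows a warm-up cosine schedule: it rises from ``lr_init``
to ``lr_max`` at ``warmup_end_epoch`` and decays along a cosine to zero at
``total_epochs`` (reference values 1e-4 -> 0.1 at epoch 50 -> 0 at 200).
Every ``val_period`` epochs the mean intensity (Charbonnier) loss between
the registered synthesis and the target is computed on the validation set;
the weights minimizing it are kept as the best model.

Four ablation modes mirror the study design:

* M1 - synthesizer only, L1 loss against the (misaligned) target;
* M2 - joint synthesis + registration, L1 on the registered output + smoothness;
* M3 - joint, perceptual + local correlation + smoothness (no L1);
* M4 - the full composite objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._autodiff import nn as adnn
from .io_preprocess import TrainingPair, augment, random_patch, train_val_split
from .losses import (LossWeights, PerceptualLoss, intensity_loss, smooth_loss,
                     structure_loss, total_loss)
from .regnet import RegNet, RegNetConfig, compose_rsct
from .synthesizer import Synthesizer, SynthesizerConfig

MODES = ("M1", "M2", "M3", "M4")


@dataclass
class ScheduleConfig:
    lr_init: float = 1e-4
    lr_max: float = 0.1
    warmup_end_epoch: int = 50
    total_epochs: int = 200
    warmup_shape: str = "cosine"  # or "linear"

    def __post_init__(self):
        if not (0 < self.lr_init <= self.lr_max):
            raise ValueError("need 0 < lr_init <= lr_max")
        if not (0 < self.warmup_end_epoch < self.total_epochs):
            raise ValueError("need 0 < warmup_end_epoch < total_epochs")


def learning_rate(epoch: float, config: ScheduleConfig) -> float:
    """Warm-up cosine schedule; continuous, peaks at warmup_end, 0 at end."""
    if epoch < 0 or epoch > config.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.total_epochs}]")
    w, T = config.warmup_end_epoch, config.total_epochs
    if epoch <= w:
        t = epoch / w
        if config.warmup_shape == "linear":
            ramp = t
        else:
            ramp = 0.5 * (1.0 - math.cos(math.pi * t))
        return config.lr_init + (config.lr_max - config.lr_init) * ramp
    return config.lr_max * 0.5 * (1.0 + math.cos(math.pi * (epoch - w) / (T - w)))


@dataclass
class TrainConfig:
    mode: str = "M4"
    batch_size: int = 8
    seed: int = 0
    beta1: float = 0.5
    beta2: float = 0.999
    val_period: int = 10
    patch_size: int = 256
    augment_p: float = 0.3
    split_ratio: float = 0.9
    lncc_window: int = 9
    weights: LossWeights = field(default_factory=LossWeights)
    synthesizer: SynthesizerConfig = field(default_factory=SynthesizerConfig)
    regnet: RegNetConfig = field(default_factory=RegNetConfig)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def desk_profile(mode: str = "M4", seed: int = 0,
                 total_epochs: int = 20) -> tuple[TrainConfig, ScheduleConfig]:
    """Small-scale preset for 64x64 phantom experiments on one CPU.

    Tiny synthesizer (base 16 channels, depth 2, 2 transformer blocks,
    2 heads), a 3-stage registration network, 32-pixel training patches and
    a scaled schedule peaking at 1e-3 (the reference peak of 0.1 is far too
    hot for a small Adam-driven model; this preset deviates deliberately).
    """
    train = TrainConfig(
        mode=mode,
        batch_size=8,
        seed=seed,
        patch_size=32,
        synthesizer=SynthesizerConfig(base_channels=16, encoder_depth=2,
                                      num_dtb=2, num_heads=2),
        regnet=RegNetConfig(down_filters=(16, 32, 32, 32), num_residual=2),
    )
    sched = ScheduleConfig(lr_init=1e-4, lr_max=1e-3,
                           warmup_end_epoch=min(max(1, total_epochs // 4),
                                                total_epochs - 1),
                           total_epochs=total_epochs)
    return train, sched


# ----------------------------------------------------------------- model pair
class JointModel:
    """Synthesizer plus (for M2-M4) the registration network."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.mode = config.mode
        self.synthesizer = Synthesizer(config.synthesizer, rng=rng)
        self.regnet = None if config.mode == "M1" \
            else RegNet(config.regnet, rng=rng)

    def parameters(self):
        params = self.synthesizer.parameters()
        if self.regnet is not None:
            params += self.regnet.parameters()
        return params

    def state_dict(self):
        state = {f"syn.{k}": v for k, v in self.synthesizer.state_dict().items()}
        if self.regnet is not None:
            state.update({f"reg.{k}": v
                          for k, v in self.regnet.state_dict().items()})
        return state

    def load_state_dict(self, state):
        self.synthesizer.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("syn.")})
        if self.regnet is not None:
            self.regnet.load_state_dict(
                {k[4:]: v for k, v in state.items() if k.startswith("reg.")})


def _batch_tensors(pairs: list[TrainingPair]):
    x = Tensor(np.stack([p.cbct.pixels for p in pairs])[:, None])
    y = Tensor(np.stack([p.pct.pixels for p in pairs])[:, None])
    return x, y


def l1_loss(a, b) -> Tensor:
    """Mean absolute difference (smooth-at-zero surrogate, e = 1e-6)."""
    return intensity_loss(a, b, e=1e-6)


def train_step(model: JointModel, optimizer: adnn.Adam,
               batch: list[TrainingPair], config: TrainConfig,
               perceptual: PerceptualLoss | None = None) -> dict:
    """One forward/backward/update over a batch; returns the loss breakdown."""
    x, y = _batch_tensors(batch)
    w = config.weights
    components: dict[str, float]
    if config.mode == "M1":
        sct = model.synthesizer(x)
        loss = l1_loss(sct, y)
        components = {"l1": float(loss.data), "total": float(loss.data)}
    elif config.mode == "M2":
        sct, dvf, rsct = compose_rsct(x, y, model.synthesizer, model.regnet)
        li = l1_loss(rsct, y)
        lm = smooth_loss(dvf)
        loss = li + w.lam_smooth * lm
        components = {"l1": float(li.data), "smooth": float(lm.data),
                      "total": float(loss.data)}
    elif config.mode == "M3":
        sct, dvf, rsct = compose_rsct(x, y, model.synthesizer, model.regnet)
        perceptual = perceptual or PerceptualLoss()
        lp = perceptual(sct, y)
        ls = structure_loss(rsct, y, window=config.lncc_window)
        lm = smooth_loss(dvf)
        loss = lp + w.lam_structure * ls + w.lam_smooth * lm
        components = {"perceptual": float(lp.data), "structure": float(ls.data),
                      "smooth": float(lm.data), "total": float(loss.data)}
    else:  # M4
        sct, dvf, rsct = compose_rsct(x, y, model.synthesizer, model.regnet)
        loss, components = total_loss(sct, rsct, y, dvf, weights=w,
                                      perceptual=perceptual,
                                      lncc_window=config.lncc_window)
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite training loss: {components}")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return components


def validation_loss(model: JointModel, val_set: list[TrainingPair],
                    config: TrainConfig,
                    batch_size: int | None = None) -> dict:
    """Mean intensity loss between target and registered synthesis.

    Charbonnier (e = 1e-3) is the selection criterion; plain L1 is logged
    alongside.  For M1 the un-registered synthesis is scored.
    """
    if not val_set:
        raise ValueError("validation set is empty")
    bs = batch_size or config.batch_size
    tot_charb, tot_l1, n = 0.0, 0.0, 0
    for i in range(0, len(val_set), bs):
        chunk = val_set[i:i + bs]
        x, y = _batch_tensors(chunk)
        if model.regnet is None:
            out = model.synthesizer(x)
        else:
            _, _, out = compose_rsct(x, y, model.synthesizer, model.regnet)
        k = len(chunk)
        tot_charb += float(intensity_loss(out, y,
                                          e=config.weights.charbonnier_e).data) * k
        tot_l1 += float(l1_loss(out, y).data) * k
        n += k
    return {"intensity": tot_charb / n, "l1": tot_l1 / n}


@dataclass
class TrainResult:
    model: JointModel
    best_val: float
    best_epoch: int
    log: list[dict]
    train_pairs: list[TrainingPair]
    val_pairs: list[TrainingPair]


def fit(dataset: list[TrainingPair], config: TrainConfig,
        schedule: ScheduleConfig, checkpoint_path: str | Path | None = None,
        log_path: str | Path | None = None) -> TrainResult:
    """Full seeded training run; returns the best checkpoint and loss log."""
    if not dataset:
        raise ValueError("dataset is empty")
    train_set, val_set = train_val_split(dataset, config.split_ratio,
                                         seed=config.seed)
    model = JointModel(config, rng=np.random.default_rng(config.seed))
    optimizer = adnn.Adam(model.parameters(), lr=schedule.lr_init,
                          beta1=config.beta1, beta2=config.beta2)
    perceptual = PerceptualLoss() if config.mode in ("M3", "M4") else None
    root = np.random.SeedSequence(config.seed)
    epoch_seeds = root.spawn(schedule.total_epochs)
    log: list[dict] = []
    best_val, best_epoch, best_state = np.inf, -1, None

    for epoch in range(schedule.total_epochs):
        optimizer.lr = learning_rate(epoch, schedule)
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(len(train_set))
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = []
            for i in idx:
                p = random_patch(train_set[i], config.patch_size, rng)
                batch.append(augment(p, config.augment_p, rng))
            components = train_step(model, optimizer, batch, config, perceptual)
            log.append({"epoch": epoch, "lr": optimizer.lr, **components})
        if val_set and (epoch + 1) % config.val_period == 0:
            val = validation_loss(model, val_set, config)
            log.append({"epoch": epoch, "validation": val})
            if val["intensity"] < best_val:
                best_val = val["intensity"]
                best_epoch = epoch
                best_state = model.state_dict()
                if checkpoint_path is not None:
                    save_checkpoint(checkpoint_path, model, optimizer, config,
                                    schedule, epoch, best_val)
    if best_state is None and val_set:
        # run too short to hit the validation period: score the final weights
        val = validation_loss(model, val_set, config)
        log.append({"epoch": schedule.total_epochs - 1, "validation": val})
        best_val = val["intensity"]
        best_epoch = schedule.total_epochs - 1
        best_state = model.state_dict()
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, optimizer, config,
                            schedule, best_epoch, best_val)
    if best_state is None:  # no validation data at all; keep final weights
        best_val = float("nan")
        best_epoch = schedule.total_epochs - 1
    else:
        model.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return TrainResult(model, best_val, best_epoch, log, train_set, val_set)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path: str | Path, model: JointModel, optimizer: adnn.Adam,
                    config: TrainConfig, schedule: ScheduleConfig,
                    epoch: int, best_val: float) -> None:
    """Weights + optimizer moments to NPZ, configuration to a JSON sidecar."""
    path = Path(path)
    arrays = dict(model.state_dict())
    for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
        arrays[f"opt.m.{i}"] = m
        arrays[f"opt.v.{i}"] = v
    np.savez(path, **arrays)
    meta = {
        "mode": config.mode,
        "epoch": epoch,
        "best_val": best_val,
        "opt_t": optimizer.t,
        "lr": optimizer.lr,
        "train_config": _config_dict(config),
        "schedule": asdict(schedule),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[JointModel, adnn.Adam,
                                               TrainConfig, ScheduleConfig, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = _config_from_dict(meta["train_config"])
    schedule = ScheduleConfig(**meta["schedule"])
    model = JointModel(config, rng=0)
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    model.load_state_dict({k: v for k, v in arrays.items()
                           if not k.startswith("opt.")})
    optimizer = adnn.Adam(model.parameters(), lr=meta["lr"],
                          beta1=config.beta1, beta2=config.beta2)
    optimizer.t = int(meta["opt_t"])
    optimizer.m = [arrays[f"opt.m.{i}"].copy()
                   for i in range(len(optimizer.params))]
    optimizer.v = [arrays[f"opt.v.{i}"].copy()
                   for i in range(len(optimizer.params))]
    return model, optimizer, config, schedule, meta


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["weights"] = LossWeights(**d["weights"])
    d["synthesizer"] = SynthesizerConfig(**d["synthesizer"])
    reg = dict(d["regnet"])
    reg["down_filters"] = tuple(reg["down_filters"])
    d["regnet"] = RegNetConfig(**reg)
    return TrainConfig(**d)


# ------------------------------------------------------------------- harness
def evaluate_against_clean(model: JointModel,
                           pairs: list[TrainingPair]) -> dict:
    """HU-scale MAE/RMSE/PSNR/SSIM of sCT and CBCT against clean ground truth."""
    from .io_preprocess import denormalize
    from .metrics import image_report

    from dataclasses import replace as _replace

    sct_reports, cbct_reports = [], []
    for p in pairs:
        if p.clean_pct is None:
            raise ValueError("evaluation requires clean ground truth")
        x = Tensor(p.cbct.pixels[None, None])
        out = model.synthesizer(x).data[0, 0]
        sct_hu = denormalize(_replace(p.cbct, pixels=out))
        cbct_hu = denormalize(p.cbct)
        clean_hu = denormalize(p.clean_pct)
        sct_reports.append(image_report(sct_hu, clean_hu))
        cbct_reports.append(image_report(cbct_hu, clean_hu))
    agg = {}
    for name, reports in (("sct", sct_reports), ("cbct", cbct_reports)):
        for k in reports[0]:
            agg[f"{name}_{k}"] = float(np.mean([r[k] for r in reports]))
    return agg


def train_regnet_recovery(n_train: int = 100, n_test: int = 20,
                          max_displacement: float = 4.0, seed: int = 0,
                          epochs: int = 30, batch_size: int = 8,
                          regnet_config: RegNetConfig | None = None,
                          weights: LossWeights | None = None,
                          lr: float = 1e-3) -> dict:
    """Registration-recovery experiment on phantom pairs with known fields.

    Pairs (clean slice, warp(clean, d_true)) are generated with smooth random
    fields; the registration network alone is optimized with the intensity +
    structure + smoothness losses and scored by the mean endpoint error
    (mean over pixels of |d_pred - d_true| in px) on held-out pairs.  The
    zero-field baseline (mean |d_true|) is reported for reference.
    """
    from .phantom import (MisalignmentSpec, PhantomSpec, generate_pct,
                          make_misaligned_target)
    from .io_preprocess import clip_hu, normalize
    from ._autodiff import ops as adops

    weights = weights or LossWeights()
    mis = MisalignmentSpec(max_displacement=max_displacement)
    regnet_config = regnet_config or RegNetConfig(
        down_filters=(16, 32, 32, 32), num_residual=2)

    root = np.random.SeedSequence(seed)
    samples = []
    for child in root.spawn(n_train + n_test):
        rng = np.random.default_rng(child)
        pct = generate_pct(PhantomSpec(), rng)
        target, dvf = make_misaligned_target(pct, mis, rng)
        samples.append((normalize(clip_hu(pct)).pixels.astype(np.float32),
                        normalize(clip_hu(target)).pixels.astype(np.float32),
                        dvf))
    train, test = samples[:n_train], samples[n_train:]

    model = RegNet(regnet_config, rng=np.random.default_rng(seed))
    optimizer = adnn.Adam(model.parameters(), lr=lr, beta1=0.5, beta2=0.999)
    epoch_seeds = np.random.SeedSequence(seed + 1).spawn(epochs)
    for epoch in range(epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch_size):
            idx = order[start:start + batch_size]
            a = Tensor(np.stack([train[i][0] for i in idx])[:, None])
            b = Tensor(np.stack([train[i][1] for i in idx])[:, None])
            dvf = model(a, b)
            rsct = adops.warp(a, dvf)
            loss = weights.lam_intensity * intensity_loss(rsct, b) \
                + weights.lam_structure * structure_loss(rsct, b) \
                + weights.lam_smooth * smooth_loss(dvf)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

    def epe(sample_set):
        errs, base = [], []
        for a, b, d_true in sample_set:
            pred = model(Tensor(a[None, None]), Tensor(b[None, None])).data[0]
            pred = np.moveaxis(pred, 0, -1)  # (H, W, 2)
            errs.append(np.sqrt(((pred - d_true) ** 2).sum(-1)).mean())
            base.append(np.sqrt((d_true ** 2).sum(-1)).mean())
        return float(np.mean(errs)), float(np.mean(base))

    test_epe, test_base = epe(test)
    train_epe, _ = epe(train[: min(n_train, n_test)])
    return {"test_epe": test_epe, "zero_field_epe": test_base,
            "train_epe": train_epe, "n_train": n_train, "n_test": n_test}


def run_ablation(dataset: list[TrainingPair], modes=MODES, seed: int = 0,
                 total_epochs: int = 20,
                 test_pairs: list[TrainingPair] | None = None) -> dict:
    """Train each requested mode under a shared seed; report MAE/PSNR/SSIM
    against the clean ground truth, one row per mode."""
    report = {}
    for mode in modes:
        config, schedule = desk_profile(mode=mode, seed=seed,
                                        total_epochs=total_epochs)
        result = fit(dataset, config, schedule)
        eval_pairs = test_pairs if test_pairs is not None else result.val_pairs
        metrics = evaluate_against_clean(result.model, eval_pairs)
        report[mode] = {"mae": metrics["sct_mae"], "psnr": metrics["sct_psnr"],
                        "ssim": metrics["sct_ssim"],
                        "cbct_mae": metrics["cbct_mae"],
                        "cbct_ssim": metrics["cbct_ssim"],
                        "best_val": result.best_val}
    return report
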