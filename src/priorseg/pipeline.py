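"""Leave-one-out cross-validation harness and ablation protocol.

For each fold one subject is held out; the remaining reference set is split
80/20 into training and validation by a seeded shuffle. Appearance and
shape priors are built from the reference set only — the held-out subject's
mask is never touched before evaluation — and the conditional GAN is
trained on the reference condition volumes. Four input configurations are
supported:

* ``raw``      — one channel, the uncropped grayscale volume;
* ``roi``      — one channel, the kidney-centered ROI crop;
* ``roi_prob`` — three channels (ROI, P_app, P_app);
* ``full``     — three channels (ROI, P_app, S), the complete condition.

The held-out subject has no mask at inference time, so its ROI center is
the mean of the reference-set mask centroids, and its appearance map is
banded around the boundary of the binarized shape prior. For train/test
consistency the same prior-derived band field is used for every subject's
condition map.

Aggregation reports per-metric mean, std and a seeded nonparametric
percentile-bootstrap 95% CI across subjects; configuration pairs are
compared with two-sided Wilcoxon signed-rank tests, Benjamini-Hochberg
corrected across the metric family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .appearance import (
    AppearanceModel,
    accumulate_histograms,
    appearance_map,
    band_partition,
)
from .gan import (
    ConditionVolume,
    DiscriminatorConfig,
    GeneratorConfig,
    ResidualUNet3D,
    TrainConfig,
    predict_mask,
    train,
)
from .grid import BinaryMask, GridVolume, RoiSpec, extract_roi, mask_centroid, normalize_intensity
from .metrics import SegScores, score_pair
from .shape import ShapePrior, binarize_prior, build_shape_prior

__all__ = [
    "ABLATION_CONFIGS",
    "FoldPlan",
    "PipelineConfig",
    "FoldArtifacts",
    "plan_loocv",
    "prepare_fold",
    "train_fold",
    "evaluate_fold",
    "run_fold",
    "run_loocv",
    "aggregate",
    "paired_significance",
]

ABLATION_CONFIGS = ("raw", "roi", "roi_prob", "full")

Subjects = Mapping[int, Tuple[GridVolume, BinaryMask]]


@dataclass
class FoldPlan:
    """One LOOCV fold: held-out subject and the 80/20 inner split."""

    held_out: int
    reference_set: List[int]
    train_ids: List[int]
    val_ids: List[int]
    seed: int

    def __post_init__(self) -> None:
        if self.held_out in self.reference_set:
            raise ValueError("held-out subject must not appear in the reference set")
        if set(self.train_ids) | set(self.val_ids) != set(self.reference_set) or (
            set(self.train_ids) & set(self.val_ids)
        ):
            raise ValueError("inner split must partition the reference set")


@dataclass
class PipelineConfig:
    """Everything one fold needs: grid standardization, priors, network, training."""

    roi_size: Tuple[int, int, int] = (16, 48, 48)
    n_bands: int = 8
    band_thickness: int = 1
    neighborhood_radius: int = 1
    levels: int = 256
    shape_threshold: float = 0.5
    gen: GeneratorConfig = field(default_factory=GeneratorConfig)
    disc: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    epochs: int = 200
    lr: float = 4e-4
    lambda_rec: float = 200.0
    seed: int = 0


@dataclass
class FoldArtifacts:
    """Products of the leakage-safe preparation stage of one fold."""

    plan: FoldPlan
    config: str
    train_pairs: List[Tuple[ConditionVolume, BinaryMask]]
    val_pairs: List[Tuple[ConditionVolume, BinaryMask]]
    heldout_cond: ConditionVolume
    roi_center: Optional[Tuple[int, int, int]]
    spacing: Tuple[float, float, float]
    appearance: Optional[AppearanceModel] = None
    shape_prior: Optional[ShapePrior] = None


def plan_loocv(subject_ids: Sequence[int], seed: int = 0) -> List[FoldPlan]:
    """All N leave-one-out folds with seeded 80/20 inner splits.

    Validation size is ``max(1, round(0.2 * |R|))``; every subject is held
    out exactly once; the same seed reproduces identical plans.
    """
    ids = list(subject_ids)
    if len(ids) < 3:
        raise ValueError("LOOCV with an inner split needs at least 3 subjects")
    plans = []
    for i, held in enumerate(ids):
        ref = [s for s in ids if s != held]
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        perm = [ref[j] for j in rng.permutation(len(ref))]
        n_val = max(1, round(0.2 * len(ref)))
        plans.append(
            FoldPlan(
                held_out=held,
                reference_set=ref,
                train_ids=sorted(perm[n_val:]),
                val_ids=sorted(perm[:n_val]),
                seed=int(seed),
            )
        )
    return plans


def _scale01(vol_q: GridVolume, levels: int) -> np.ndarray:
    return (vol_q.data.astype(np.float32)) / float(levels - 1)


def prepare_fold(subjects: Subjects, plan: FoldPlan, config: str, cfg: PipelineConfig) -> FoldArtifacts:
    """Build priors and condition volumes for one fold (no training yet).

    Reads reference subjects' images and masks, and the held-out subject's
    *image only*; the held-out mask is untouched until
    :func:`evaluate_fold`, so priors and condition volumes are identical
    whether or not that mask exists.
    """
    if config not in ABLATION_CONFIGS:
        raise ValueError(f"unknown configuration {config!r}; choose from {ABLATION_CONFIGS}")

    ref_vols: Dict[int, GridVolume] = {}
    ref_masks: Dict[int, BinaryMask] = {}
    spacing = subjects[plan.held_out][0].spacing

    if config == "raw":
        # no spatial standardization: full-grid, single-channel input
        conds: Dict[int, ConditionVolume] = {}
        for sid in plan.reference_set + [plan.held_out]:
            vol = subjects[sid][0]
            q = normalize_intensity(vol, cfg.levels)
            conds[sid] = ConditionVolume(_scale01(q, cfg.levels)[None], names=("c1",))
        train_pairs = [(conds[s], subjects[s][1]) for s in plan.train_ids]
        val_pairs = [(conds[s], subjects[s][1]) for s in plan.val_ids]
        return FoldArtifacts(
            plan=plan,
            config=config,
            train_pairs=train_pairs,
            val_pairs=val_pairs,
            heldout_cond=conds[plan.held_out],
            roi_center=None,
            spacing=spacing,
        )

    # kidney-centered standardization for every reference subject
    centroids = []
    for sid in plan.reference_set:
        vol, mask = subjects[sid]
        spec = RoiSpec(size=cfg.roi_size, mode="train")
        vol_roi, mask_roi = extract_roi(vol, mask, spec)
        ref_vols[sid] = vol_roi
        ref_masks[sid] = mask_roi
        centroids.append(mask_centroid(mask))
    # the held-out subject has no mask: its ROI is centered on the
    # reference-cohort mean centroid (the only mask-free location estimate)
    center = tuple(int(round(c)) for c in np.mean(centroids, axis=0))
    heldout_vol, _ = extract_roi(
        subjects[plan.held_out][0],
        None,
        RoiSpec(size=cfg.roi_size, center=center, mode="inference"),
    )

    ref_q = {sid: normalize_intensity(v, cfg.levels) for sid, v in ref_vols.items()}
    heldout_q = normalize_intensity(heldout_vol, cfg.levels)

    appearance: Optional[AppearanceModel] = None
    shape_prior: Optional[ShapePrior] = None
    papp: Dict[int, np.ndarray] = {}
    if config in ("roi_prob", "full"):
        appearance = accumulate_histograms(
            [(ref_q[s], ref_masks[s]) for s in plan.reference_set],
            n_bands=cfg.n_bands,
            thickness=cfg.band_thickness,
            radius=cfg.neighborhood_radius,
            levels=cfg.levels,
        )
        shape_prior = build_shape_prior([ref_masks[s] for s in plan.reference_set])
        # one mask-free band reference for all subjects: the binarized
        # cohort prior, keeping train and inference conditions consistent
        bands = band_partition(
            binarize_prior(shape_prior, cfg.shape_threshold),
            n_bands=cfg.n_bands,
            thickness=cfg.band_thickness,
        )
        for sid in plan.reference_set:
            papp[sid] = appearance_map(appearance, ref_q[sid], bands).papp.astype(np.float32)
        papp[plan.held_out] = appearance_map(appearance, heldout_q, bands).papp.astype(
            np.float32
        )
    elif config == "roi":
        pass

    def build_cond(sid: int, q: GridVolume) -> ConditionVolume:
        c1 = _scale01(q, cfg.levels)
        if config == "roi":
            return ConditionVolume(c1[None], names=("c1",))
        if config == "roi_prob":
            return ConditionVolume(
                np.stack([c1, papp[sid], papp[sid]]), names=("c1", "c2", "c3")
            )
        s_chan = shape_prior.s.astype(np.float32)
        return ConditionVolume(np.stack([c1, papp[sid], s_chan]), names=("c1", "c2", "c3"))

    train_pairs = [(build_cond(s, ref_q[s]), ref_masks[s]) for s in plan.train_ids]
    val_pairs = [(build_cond(s, ref_q[s]), ref_masks[s]) for s in plan.val_ids]
    heldout_cond = build_cond(plan.held_out, heldout_q)
    return FoldArtifacts(
        plan=plan,
        config=config,
        train_pairs=train_pairs,
        val_pairs=val_pairs,
        heldout_cond=heldout_cond,
        roi_center=center,
        spacing=spacing,
        appearance=appearance,
        shape_prior=shape_prior,
    )


def train_fold(art: FoldArtifacts, cfg: PipelineConfig) -> tuple[ResidualUNet3D, pd.DataFrame]:
    """Train the conditional GAN on the fold's reference condition volumes."""
    n_cond = art.heldout_cond.channels.shape[0]
    gen_cfg = replace(cfg.gen, in_channels=n_cond)
    disc_cfg = replace(cfg.disc, cond_channels=n_cond)
    tcfg = TrainConfig(
        epochs=cfg.epochs, lr=cfg.lr, lambda_rec=cfg.lambda_rec, seed=cfg.seed
    )
    return train(
        art.train_pairs, tcfg, gen_cfg=gen_cfg, disc_cfg=disc_cfg, val_pairs=art.val_pairs
    )


def evaluate_fold(
    gen: ResidualUNet3D, art: FoldArtifacts, subjects: Subjects
) -> tuple[SegScores, BinaryMask]:
    """Predict the held-out mask and score it — the only stage reading that mask."""
    pred = predict_mask(gen, art.heldout_cond)
    ref = subjects[art.plan.held_out][1]
    if art.roi_center is not None:
        _, ref = extract_roi(
            subjects[art.plan.held_out][0],
            ref,
            RoiSpec(size=art.heldout_cond.spatial_shape, center=art.roi_center, mode="inference"),
        )
    return score_pair(pred, ref, art.spacing), pred


def run_fold(
    subjects: Subjects, plan: FoldPlan, config: str, cfg: PipelineConfig
) -> tuple[dict, FoldArtifacts, ResidualUNet3D]:
    """Full stage sequence for one fold; returns the held-out score row."""
    art = prepare_fold(subjects, plan, config, cfg)
    gen, history = train_fold(art, cfg)
    scores, _ = evaluate_fold(gen, art, subjects)
    row = {
        "subject": plan.held_out,
        "config": config,
        "dice": scores.dice,
        "iou": scores.iou,
        "hd95": scores.hd95,
        "assd": scores.assd,
        "empty_prediction": bool(np.isnan(scores.hd95)),
        "best_epoch": int(history.attrs.get("best_epoch", -1)),
    }
    return row, art, gen


def run_loocv(
    subjects: Subjects,
    config: str,
    cfg: PipelineConfig,
    n_folds: Optional[int] = None,
) -> pd.DataFrame:
    """Run (a prefix of) the LOOCV folds for one configuration."""
    plans = plan_loocv(sorted(subjects), seed=cfg.seed)
    if n_folds is not None:
        plans = plans[:n_folds]
    rows = []
    for plan in plans:
        row, _, _ = run_fold(subjects, plan, config, cfg)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(results: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-configuration mean, std and percentile-bootstrap 95% CI per metric."""
    if len(results) < 2:
        raise ValueError("aggregation needs scores from at least 2 subjects")
    metrics = [m for m in ("dice", "iou", "hd95", "assd") if m in results.columns]
    group_cols = [c for c in ("modality", "config") if c in results.columns]
    rng = np.random.default_rng(seed)
    rows = []
    grouped = results.groupby(group_cols) if group_cols else [((), results)]
    for key, df in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for m in metrics:
            vals = df[m].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
            row = dict(zip(group_cols, key))
            row.update(
                metric=m,
                mean=float(vals.mean()),
                std=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                ci_lo=float(np.percentile(boots, 2.5)),
                ci_hi=float(np.percentile(boots, 97.5)),
                n=int(vals.size),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def paired_significance(
    results: pd.DataFrame,
    config_a: str,
    config_b: str,
    metrics: Sequence[str] = ("dice", "iou", "hd95", "assd"),
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank per metric, BH-adjusted across the family.

    Scores must be paired: both configurations evaluated on the identical
    subject set. Identical columns (all zero differences) yield p = 1.
    """
    a = results[results["config"] == config_a].set_index("subject").sort_index()
    b = results[results["config"] == config_b].set_index("subject").sort_index()
    if list(a.index) != list(b.index):
        raise ValueError(
            f"unpaired subjects: {sorted(set(a.index) ^ set(b.index))} "
            f"not present under both configurations"
        )
    pvals = []
    for m in metrics:
        x = a[m].to_numpy(dtype=float)
        y = b[m].to_numpy(dtype=float)
        diff = x - y
        if np.allclose(diff, 0.0):
            pvals.append(1.0)
            continue
        res = stats.wilcoxon(x, y, alternative="two-sided")
        pvals.append(float(res.pvalue))
    reject, p_adj, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
    return pd.DataFrame(
        {
            "metric": list(metrics),
            "p": pvals,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )
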