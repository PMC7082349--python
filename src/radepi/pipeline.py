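"""End-to-end orchestration: generate -> reconcile -> extract -> split ->
select -> evaluate, with per-stage artifacts and resume support.

Also home to the two cohort-level operations the orchestration needs:
the chronological 1:1 cohort split and the ICC-based dual-rater
segmentation reconciliation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from radepi import __version__
from radepi.evaluation import (
    build_nomogram,
    compare_cohorts,
    decision_curve,
    fit_multivariable_aic,
    hosmer_lemeshow_calibration,
    nomogram_lookup_table,
    roc_auc_ci,
)
from radepi.features.extract import extract_all
from radepi.features.quantize import QuantizationConfig
from radepi.features.registry import registry_as_json
from radepi.selection import (
    FeatureTable,
    LassoConfig,
    SignatureModel,
    compute_signature,
    fit_lasso_loocv,
    signature_probability,
    univariate_screen,
    zscore_fit_apply,
)
from radepi.synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("radepi.pipeline")


# ---------------------------------------------------------------------------
# Cohort split
# ---------------------------------------------------------------------------

def split_cohort(records: pd.DataFrame, date_col: str = "surgery_date",
                 id_col: str = "patient_id") -> tuple[list[str], list[str]]:
    """Chronological 1:1 split: the earliest floor(n/2) cases form training.

    Duplicate surgery dates are tie-broken stably by patient id (and logged).
    """
    if records[date_col].duplicated().any():
        logger.warning("duplicate surgery dates; tie-breaking by %s", id_col)
    ordered = records.sort_values([date_col, id_col], kind="stable")
    n_train = len(ordered) // 2
    ids = ordered[id_col].tolist()
    return ids[:n_train], ids[n_train:]


# ---------------------------------------------------------------------------
# Dual-rater reconciliation
# ---------------------------------------------------------------------------

def icc_two_way_random_single(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    x = np.column_stack([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
    n, k = x.shape
    if n < 5:
        raise ValueError(f"ICC needs at least 5 paired observations, got {n}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # identical constant series
    return float((msr - mse) / denom)


class SegmentationDisagreement(RuntimeError):
    """Raised when the inter-rater ICC does not clear the agreement threshold."""


def icc_reconcile(
    masks_a: list[np.ndarray],
    masks_b: list[np.ndarray],
    seed: int,
    icc_threshold: float = 0.8,
    series: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Certify inter-rater agreement and pick one mask per patient.

    The ICC (two-way random, absolute agreement, single measure) is computed
    across patients on the per-rater ROI volume (voxel-count) series -- or on
    a caller-supplied per-rater quantity via ``series`` (e.g. a per-feature
    mode). If it exceeds the threshold, each patient receives one of the two
    masks chosen by a seeded uniform draw; otherwise the run halts with a
    disagreement report.
    """
    if len(masks_a) != len(masks_b):
        raise ValueError("rater series have different lengths")
    if series is not None:
        vols_a = np.asarray(series[0], dtype=float)
        vols_b = np.asarray(series[1], dtype=float)
    else:
        vols_a = np.array(
            [int(np.asarray(m).astype(bool).sum()) for m in masks_a], dtype=float
        )
        vols_b = np.array(
            [int(np.asarray(m).astype(bool).sum()) for m in masks_b], dtype=float
        )
    icc = icc_two_way_random_single(vols_a, vols_b)
    report = {
        "icc": icc,
        "threshold": icc_threshold,
        "n_patients": len(masks_a),
        "volumes_rater_a": vols_a.tolist(),
        "volumes_rater_b": vols_b.tolist(),
    }
    if icc <= icc_threshold:
        raise SegmentationDisagreement(
            f"inter-rater ICC {icc:.3f} <= {icc_threshold}; segmentations disagree"
        )
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, size=len(masks_a))
    chosen = [b if pick else a for a, b, pick in zip(masks_a, masks_b, picks)]
    report["rater_choice"] = picks.tolist()
    return chosen, report


def perturb_mask(mask: np.ndarray, rng: np.random.Generator,
                 flip_fraction: float = 0.03) -> np.ndarray:
    """A second-rater surrogate: jitter the mask boundary.

    Randomly toggles a fraction of the boundary voxels (erode/dilate noise)
    while guaranteeing a nonempty result.
    """
    m = np.asarray(mask).astype(bool)
    dilated = ndimage.binary_dilation(m)
    eroded = ndimage.binary_erosion(m)
    boundary = dilated & ~eroded
    out = m.copy()
    idx = np.argwhere(boundary)
    n_flip = int(len(idx) * flip_fraction)
    if n_flip > 0:
        pick = rng.choice(len(idx), size=n_flip, replace=False)
        for i, j, k in idx[pick]:
            out[i, j, k] = ~out[i, j, k]
    if not out.any():
        out = m.copy()
    return out


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    seed: int = 0
    simulate_raters: bool = True
    rater_flip_fraction: float = 0.03
    icc_threshold: float = 0.8

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        return json.dumps(dataclasses.asdict(self), default=str, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        import datetime

        syn = dict(d.get("synthetic", {}))
        for key in ("grid_shape", "voxel_spacing", "tumor_radius_range",
                    "texture_heterogeneity_range", "effect_coefficients"):
            if key in syn:
                syn[key] = tuple(syn[key])
        if "first_surgery" in syn and isinstance(syn["first_surgery"], str):
            syn["first_surgery"] = datetime.date.fromisoformat(syn["first_surgery"])
        return cls(
            synthetic=SyntheticConfig(**syn),
            quantization=QuantizationConfig(**d.get("quantization", {})),
            lasso=LassoConfig(**d.get("lasso", {})),
            seed=int(d.get("seed", 0)),
            simulate_raters=bool(d.get("simulate_raters", True)),
            rater_flip_fraction=float(d.get("rater_flip_fraction", 0.03)),
            icc_threshold=float(d.get("icc_threshold", 0.8)),
        )


STAGES = ("cohort", "reconcile", "extract", "select", "evaluate")


def _stage_done(out_dir: Path, stage: str) -> bool:
    return (out_dir / f".done_{stage}").exists()


def _mark_done(out_dir: Path, stage: str) -> None:
    (out_dir / f".done_{stage}").write_text(time.strftime("%Y-%m-%dT%H:%M:%S"))


def run_pipeline(config: RunConfig, out_dir: Path, resume: bool = False) -> Path:
    """Execute all stages, writing artifacts under ``out_dir``.

    Stages already marked complete are skipped when ``resume`` is true; the
    artifacts a resumed run reloads are exactly those an uninterrupted run
    would have produced, so outputs are identical either way.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    (out_dir / "feature_registry.json").write_text(registry_as_json())

    t_start = time.time()

    # --- stage: cohort -----------------------------------------------------
    manifest_path = out_dir / "manifest.csv"
    if not (resume and _stage_done(out_dir, "cohort")):
        studies, manifest = generate_cohort(config.synthetic)
        manifest.to_csv(manifest_path, index=False)
        _mark_done(out_dir, "cohort")
        logger.info("cohort: %d studies", len(studies))
    else:
        studies, _ = generate_cohort(config.synthetic)  # deterministic regeneration
        manifest = pd.read_csv(manifest_path)
        manifest["surgery_date"] = manifest["surgery_date"].astype(str)
        logger.info("cohort: resumed from %s", manifest_path)

    # --- stage: reconcile --------------------------------------------------
    if config.simulate_raters and not (resume and _stage_done(out_dir, "reconcile")):
        rater_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1_000_001,))
        )
        masks_a = [s.mask.support for s in studies]
        masks_b = [
            perturb_mask(m, rater_rng, config.rater_flip_fraction) for m in masks_a
        ]
        chosen, report = icc_reconcile(
            masks_a, masks_b, seed=config.seed, icc_threshold=config.icc_threshold
        )
        for s, m in zip(studies, chosen):
            s.mask = type(s.mask)(m)
        (out_dir / "icc_report.json").write_text(json.dumps(report, indent=2))
        _mark_done(out_dir, "reconcile")
        logger.info("reconcile: ICC=%.3f", report["icc"])
    elif config.simulate_raters and _stage_done(out_dir, "reconcile"):
        # regenerate deterministically, as above
        rater_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1_000_001,))
        )
        masks_a = [s.mask.support for s in studies]
        masks_b = [
            perturb_mask(m, rater_rng, config.rater_flip_fraction) for m in masks_a
        ]
        chosen, _ = icc_reconcile(
            masks_a, masks_b, seed=config.seed, icc_threshold=config.icc_threshold
        )
        for s, m in zip(studies, chosen):
            s.mask = type(s.mask)(m)

    # --- stage: extract ----------------------------------------------------
    features_path = out_dir / "features.csv"
    if resume and _stage_done(out_dir, "extract") and features_path.exists():
        feats = pd.read_csv(features_path, index_col="patient_id")
        logger.info("extract: resumed from %s", features_path)
    else:
        rows = {}
        for s in studies:
            rows[s.record.patient_id] = extract_all(
                s.volume, s.mask, s.ac_coordinate, config.quantization,
                study_id=s.record.patient_id,
            )
        feats = pd.DataFrame.from_dict(rows, orient="index")
        feats.index.name = "patient_id"
        feats.to_csv(features_path)
        # reload so fresh and resumed runs consume byte-identical inputs
        feats = pd.read_csv(features_path, index_col="patient_id")
        _mark_done(out_dir, "extract")
        logger.info("extract: %d x %d features", *feats.shape)

    # --- stage: select -----------------------------------------------------
    labels = manifest.set_index("patient_id")["epilepsy_type"].map(
        {"generalized": 1, "focal": 0}
    )
    train_ids, valid_ids = split_cohort(manifest)
    pd.DataFrame(
        {"patient_id": train_ids + valid_ids,
         "cohort": ["train"] * len(train_ids) + ["validation"] * len(valid_ids)}
    ).to_csv(out_dir / "split.csv", index=False)

    model_path = out_dir / "signature_model.json"
    if resume and _stage_done(out_dir, "select") and model_path.exists():
        model = SignatureModel.from_json(model_path.read_text())
        logger.info("select: resumed from %s", model_path)
    else:
        train = FeatureTable(train_ids, feats.loc[train_ids],
                             labels.loc[train_ids].to_numpy(), "train")
        (train_n,), params = zscore_fit_apply(train)
        screen = univariate_screen(train_n)
        screen.table.to_csv(out_dir / "screening.csv", index=False)
        kept = screen.kept
        if len(kept) < 2:
            raise RuntimeError(
                f"univariate screen kept only {len(kept)} features; "
                "cannot fit a LASSO signature"
            )
        train_kept = FeatureTable(train_n.patient_ids, train_n.features[kept],
                                  train_n.labels, "train")
        model = fit_lasso_loocv(train_kept, config.lasso, normalization=params)
        model_path.write_text(model.to_json())
        model = SignatureModel.from_json(model_path.read_text())
        _mark_done(out_dir, "select")
        logger.info("select: %d features at lambda*=%.4g",
                    len(model.feature_names), model.lambda_star)

    # --- stage: evaluate ---------------------------------------------------
    normalized = model.normalization.apply(feats)
    signature = pd.Series(compute_signature(model, normalized), index=feats.index,
                          name="signature")
    prob = pd.Series(signature_probability(model, normalized), index=feats.index,
                     name="probability")

    evaluation: dict = {}
    for name, ids in (("train", train_ids), ("validation", valid_ids)):
        roc = roc_auc_ci(prob.loc[ids].to_numpy(), labels.loc[ids].to_numpy())
        evaluation[name] = {
            "auc": roc.auc, "ci": [roc.ci_lower, roc.ci_upper],
            "accuracy": roc.accuracy, "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
        try:
            cal = hosmer_lemeshow_calibration(
                prob.loc[ids].to_numpy(), labels.loc[ids].to_numpy()
            )
            evaluation[name]["hosmer_lemeshow"] = {
                "statistic": cal.statistic, "dof": cal.dof, "p_value": cal.p_value,
            }
            pd.DataFrame({
                "mean_predicted": cal.bin_mean_predicted,
                "observed_frequency": cal.bin_observed_frequency,
                "bin_size": cal.bin_sizes,
            }).to_csv(out_dir / f"calibration_{name}.csv", index=False)
        except ValueError as exc:
            evaluation[name]["hosmer_lemeshow"] = {"error": str(exc)}

    dca = decision_curve(prob.to_numpy(), labels.loc[prob.index].to_numpy())
    pd.DataFrame({
        "threshold": dca.thresholds,
        "net_benefit_model": dca.net_benefit_model,
        "net_benefit_all": dca.net_benefit_all,
        "net_benefit_none": dca.net_benefit_none,
    }).to_csv(out_dir / "decision_curve.csv", index=False)

    # nomogram on all patients (pooled cohorts; optimism flagged in report)
    clin = manifest.set_index("patient_id").loc[feats.index]
    nomo_data = pd.DataFrame({
        "signature": signature,
        "age": clin["age"].astype(float),
        "gender": (clin["gender"] == "male").astype(float),
        "histopathology": (clin["histopathology"] == "astrocytoma").astype(float),
    })
    try:
        nomo = fit_multivariable_aic(nomo_data, labels.loc[feats.index].to_numpy())
        nomo = build_nomogram(nomo, nomo_data)
        nomo_roc = roc_auc_ci(nomo.probability(nomo_data), labels.loc[feats.index].to_numpy())
        evaluation["nomogram"] = {
            "predictors": nomo.predictors,
            "coefficients": nomo.coefficients,
            "intercept": nomo.intercept,
            "aic": nomo.aic,
            "auc_all_patients": nomo_roc.auc,
            "ci": [nomo_roc.ci_lower, nomo_roc.ci_upper],
            "note": "fit and evaluated on pooled train+validation; optimistic",
        }
        nomogram_lookup_table(nomo).to_csv(out_dir / "nomogram_lookup.csv", index=False)
    except ValueError as exc:
        evaluation["nomogram"] = {"error": str(exc)}

    comparison = compare_cohorts(
        pd.concat([clin[["age", "gender", "histopathology"]], signature,
                   clin["epilepsy_type"]], axis=1)
    )
    comparison.table.to_csv(out_dir / "cohort_comparison.csv", index=False)

    pd.concat([signature, prob, labels.loc[feats.index].rename("label")], axis=1).to_csv(
        out_dir / "signature_values.csv"
    )
    (out_dir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    _mark_done(out_dir, "evaluate")

    provenance = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out_dir
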