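"""End-to-end orchestration: cohorts → features → statistics → metrics → report.

Two entry points:

* :func:`run_demo` — desk-scale re-enactment of the three-way study design:
  a REGULAR cohort (normal-original analogue, "NO"), perturbed near-copies of
  it (normal-synthetic analogue, "NS"), and an IRREGULAR cohort
  (cancer-original analogue, "CO").  LASSO selects features on the phenotype
  contrast (NO vs CO), then all three pairwise Hotelling T² comparisons run
  on the selected features; a 5-component PCA radar table and mock-embedder
  FID/IS/RIS round out the bundle.
* :func:`run_compare` — the same pipeline on user-supplied image directories.

Every bundle is reproducible from its echoed configuration: features.csv is
byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .patch import ImagePatch, discover_images, load_patch
from .preprocess import remove_intensity_outliers
from .shrqa import ShrqaExtractor, feature_names
from .stats import (
    PCAProfile,
    hotelling_t2,
    lasso_select,
    qc_pass_rate,
    load_qc_table,
    radar_profile,
)
from .metrics import (
    fit_embedding_gaussian,
    frechet_distance,
    inception_score,
    mock_classifier_probs,
    mock_embedder,
    relative_inception_score,
)
from .texture import (
    LabeledPatchSet,
    default_templates,
    generate_cohort,
    perturb_cohort,
    write_patch_set,
)

__all__ = ["ResultsBundle", "run_demo", "run_compare", "summarize_qc"]

logger = logging.getLogger("spatialrqa")

#: demo group labels, mirroring the normal-original / normal-synthetic /
#: cancer-original three-way design
DEMO_LABELS = ("NO", "NS", "CO")


@dataclass
class ResultsBundle:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    features: pd.DataFrame
    selection: dict
    comparisons: dict[str, dict]
    radar: pd.DataFrame
    metrics: dict
    run_log: dict
    files: dict[str, Path] = field(default_factory=dict)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _pair_comparison(
    X: np.ndarray, labels: np.ndarray, a: str, b: str
) -> dict:
    """Hotelling T² between groups a and b, with the feature-space guards.

    Constant (zero-variance) columns within the pooled pair are dropped; if
    the remaining dimension is too high for the sample size the pair is
    reduced to principal components retaining 95% variance; a diagonal
    shrinkage of 0.1 is applied if the pooled covariance is near-singular.
    """
    A = X[labels == a]
    B = X[labels == b]
    pooled = np.vstack([A, B])
    usable = pooled.std(axis=0) > 1e-12
    A, B = A[:, usable], B[:, usable]
    method = "hotelling"
    n1, n2, p = A.shape[0], B.shape[0], A.shape[1]
    if n1 + n2 - 2 <= p:
        prof = PCAProfile(n_components=min(n1 + n2 - 4, p)).fit(np.vstack([A, B]))
        k = int(np.searchsorted(np.cumsum(prof.explained_variance_ratio_), 0.95) + 1)
        k = min(k, n1 + n2 - 4)
        A = prof.transform(A)[:, :k]
        B = prof.transform(B)[:, :k]
        method = f"hotelling_on_{k}_pcs"
    try:
        res = hotelling_t2(A, B)
    except np.linalg.LinAlgError:
        res = hotelling_t2(A, B, shrinkage=0.1)
        method += "_shrunk0.1"
    out = res.as_dict()
    out["method"] = method
    out["n_features_used"] = A.shape[1]
    return out


def _analyze(
    patches: list[ImagePatch],
    labels: list[str],
    out_dir: Path,
    *,
    seed: int,
    selection_groups: tuple[str, str] | None,
    n_folds: int,
    patch_size_px: int | None,
    config_echo: dict,
) -> ResultsBundle:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    labels_arr = np.asarray(labels)
    group_names = list(pd.unique(labels_arr))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups for comparison")

    extractor = ShrqaExtractor(patch_size_px=patch_size_px).fit()
    X = extractor.transform(patches)
    timings["extract_s"] = round(time.perf_counter() - t0, 3)

    names = list(extractor.get_feature_names_out())
    features = pd.DataFrame(X, columns=names)
    features.insert(0, "label", labels_arr)
    features.insert(0, "patch_id", [p.source_id for p in patches])
    features_path = out_dir / "features.csv"
    features.to_csv(features_path, index=False, float_format="%.12g")

    # --- LASSO selection on the phenotype contrast
    t1 = time.perf_counter()
    if selection_groups is None:
        selection_groups = (group_names[0], group_names[-1])
    sel_mask = np.isin(labels_arr, selection_groups)
    min_group = min(int((labels_arr == g).sum()) for g in selection_groups)
    if 2 * min_group < 2 * n_folds:
        logger.warning(
            "skipping LASSO: smallest selection group has %d rows (< %d needed "
            "for %d-fold CV); using all features",
            min_group, 2 * n_folds, n_folds,
        )
        selection = {
            "selected_indices": list(range(X.shape[1])),
            "lambda_used": None,
            "n_selected": X.shape[1],
            "seed": seed,
            "skipped": True,
            "groups": list(selection_groups),
        }
        selected = np.arange(X.shape[1])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-column notices are expected
            res = lasso_select(
                X[sel_mask], labels_arr[sel_mask], n_folds=n_folds, seed=seed
            )
        selection = {
            "selected_indices": res.selected_indices,
            "lambda_used": res.lambda_used,
            "n_selected": res.n_selected,
            "seed": seed,
            "skipped": False,
            "groups": list(selection_groups),
        }
        selected = np.asarray(res.selected_indices, dtype=int)
        if selected.size == 0:  # degenerate null selection: fall back to all
            logger.warning("LASSO selected 0 features; comparisons use all features")
            selected = np.arange(X.shape[1])
    selection_path = out_dir / "selection.json"
    selection_path.write_text(json.dumps(selection, indent=2))
    timings["selection_s"] = round(time.perf_counter() - t1, 3)

    # --- pairwise Hotelling comparisons on the selected features
    t2 = time.perf_counter()
    Xsel = X[:, selected]
    pairs = [
        (a, b)
        for i, a in enumerate(group_names)
        for b in group_names[i + 1 :]
    ]
    comparisons: dict[str, dict] = {}
    for a, b in pairs:
        comparisons[f"{a}_vs_{b}"] = _pair_comparison(Xsel, labels_arr, a, b)
    n_tests = len(comparisons)
    for res in comparisons.values():
        res["p_value_bonferroni"] = min(1.0, res["p_value"] * n_tests)
    comparison_path = out_dir / "comparison.json"
    comparison_path.write_text(json.dumps(comparisons, indent=2))
    timings["comparisons_s"] = round(time.perf_counter() - t2, 3)

    # --- PCA radar table
    t3 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = PCAProfile(n_components=5).fit(X)
    radar = radar_profile(prof.summary(), labels_arr, n_pcs=prof.n_components_)
    radar_path = out_dir / "pca_radar.csv"
    radar.to_csv(radar_path, index=False, float_format="%.12g")
    timings["pca_s"] = round(time.perf_counter() - t3, 3)

    # --- mock-embedder metrics between the first two groups
    t4 = time.perf_counter()
    g_real, g_syn = group_names[0], group_names[1]
    real = [p for p, l in zip(patches, labels_arr) if l == g_real]
    syn = [p for p, l in zip(patches, labels_arr) if l == g_syn]
    emb_real = mock_embedder(real, seed=0)
    emb_syn = mock_embedder(syn, seed=0)
    fid = frechet_distance(fit_embedding_gaussian(emb_real), fit_embedding_gaussian(emb_syn))
    n_splits = max(1, min(4, len(real) // 8))
    is_real = inception_score(mock_classifier_probs(real, seed=0), n_splits=n_splits)
    is_syn = inception_score(mock_classifier_probs(syn, seed=0), n_splits=n_splits)
    ris = relative_inception_score(is_syn, is_real)
    metrics = {
        "embedder": "mock (seeded random projection of downsampled intensity)",
        "groups": {"real": g_real, "synthetic": g_syn},
        "fid": fid.value,
        "is_real": is_real.value,
        "is_real_sd": is_real.sd,
        "is_synthetic": is_syn.value,
        "is_synthetic_sd": is_syn.sd,
        "ris": ris.value,
        "ris_sd": ris.sd,
    }
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2))
    timings["metrics_s"] = round(time.perf_counter() - t4, 3)

    run_log = {
        "config": config_echo,
        "config_hash": _config_hash(config_echo),
        "seed": seed,
        "groups": {g: int((labels_arr == g).sum()) for g in group_names},
        "timings": timings,
    }
    run_log_path = out_dir / "run_log.json"
    run_log_path.write_text(json.dumps(run_log, indent=2))

    return ResultsBundle(
        out_dir=out_dir,
        features=features,
        selection=selection,
        comparisons=comparisons,
        radar=radar,
        metrics=metrics,
        run_log=run_log,
        files={
            "features": features_path,
            "selection": selection_path,
            "comparison": comparison_path,
            "pca_radar": radar_path,
            "metrics": metrics_path,
            "run_log": run_log_path,
        },
    )


def build_demo_cohort(
    n_per_class: int = 100,
    patch_size_px: int = 128,
    seed: int = 1,
    perturb_noise_sd: float = 0.02,
    perturb_warp_px: float = 1.0,
) -> LabeledPatchSet:
    """The three demo cohorts: NO (REGULAR), NS (perturbed NO), CO (IRREGULAR)."""
    templates = default_templates(patch_size_px)
    base = generate_cohort(
        {"NO": templates["REGULAR"], "CO": templates["IRREGULAR"]}, n_per_class, seed
    )
    ns = perturb_cohort(
        base, "NO", "NS",
        noise_sd=perturb_noise_sd, warp_px=perturb_warp_px, seed=seed + 1,
    )
    order = {"NO": 0, "NS": 1, "CO": 2}
    patches = base.patches + ns.patches
    labels = base.labels + ns.labels
    manifest = pd.concat([base.manifest, ns.manifest], ignore_index=True)
    idx = sorted(range(len(labels)), key=lambda i: (order[labels[i]], patches[i].source_id))
    return LabeledPatchSet(
        [patches[i] for i in idx],
        [labels[i] for i in idx],
        manifest.iloc[idx].reset_index(drop=True),
    )


def run_demo(
    out_dir: str | Path,
    n_per_class: int = 100,
    patch_size_px: int = 128,
    seed: int = 1,
    n_folds: int = 10,
    perturb_noise_sd: float = 0.02,
    perturb_warp_px: float = 1.0,
    write_images: bool = False,
) -> ResultsBundle:
    """Generate the NO/NS/CO demo cohorts and run the full pipeline."""
    if n_per_class < 2 * n_folds:
        raise ValueError(
            f"n_per_class={n_per_class} too small for {n_folds}-fold CV; "
            f"need at least {2 * n_folds} patches per group (or lower n_folds)"
        )
    cohort = build_demo_cohort(
        n_per_class, patch_size_px, seed, perturb_noise_sd, perturb_warp_px
    )
    config_echo = {
        "mode": "SYNTHETIC_DEMO",
        "n_per_class": n_per_class,
        "patch_size_px": patch_size_px,
        "seed": seed,
        "n_folds": n_folds,
        "perturb_noise_sd": perturb_noise_sd,
        "perturb_warp_px": perturb_warp_px,
    }
    bundle = _analyze(
        cohort.patches,
        cohort.labels,
        Path(out_dir),
        seed=seed,
        selection_groups=("NO", "CO"),
        n_folds=n_folds,
        patch_size_px=patch_size_px,
        config_echo=config_echo,
    )
    if write_images:
        bundle.files["manifest"] = write_patch_set(cohort, Path(out_dir) / "patches")
    return bundle


def run_compare(
    group_dirs: dict[str, str | Path],
    out_dir: str | Path,
    seed: int = 1,
    n_folds: int = 10,
    selection_groups: tuple[str, str] | None = None,
    screen_outliers: bool = False,
    outlier_threshold_sd: float = 2.0,
) -> ResultsBundle:
    """Run the pipeline on user-supplied per-group image directories.

    Unreadable images are skipped with a warning; an empty group is an error.
    With ``screen_outliers`` the cohort-level RGB-mean screen runs first and
    flagged images are excluded.
    """
    patches: list[ImagePatch] = []
    labels: list[str] = []
    for label, directory in group_dirs.items():
        files = discover_images(directory)
        group_patches = []
        for f in files:
            try:
                group_patches.append(load_patch(f))
            except Exception as exc:  # unreadable file: skip, keep going
                warnings.warn(f"skipping unreadable image {f}: {exc}", stacklevel=2)
        if not group_patches:
            raise ValueError(f"group {label!r} has no readable images in {directory}")
        patches.extend(group_patches)
        labels.extend([label] * len(group_patches))

    if screen_outliers:
        report = remove_intensity_outliers(patches, threshold_sd=outlier_threshold_sd)
        keep = set(report.retained)
        kept = [(p, l) for p, l in zip(patches, labels) if p.source_id in keep]
        patches = [p for p, _ in kept]
        labels = [l for _, l in kept]

    config_echo = {
        "mode": "DIRECTORIES",
        "groups": {k: str(v) for k, v in group_dirs.items()},
        "seed": seed,
        "n_folds": n_folds,
        "selection_groups": list(selection_groups) if selection_groups else None,
        "screen_outliers": screen_outliers,
    }
    return _analyze(
        patches,
        labels,
        Path(out_dir),
        seed=seed,
        selection_groups=selection_groups,
        n_folds=n_folds,
        patch_size_px=None,
        config_echo=config_echo,
    )


def summarize_qc(qc_csv_path: str | Path, out_path: str | Path | None = None) -> dict:
    """Per-tissue and overall pass rates of a pathologist P/F QC table."""
    table = load_qc_table(qc_csv_path)
    overall = qc_pass_rate(table)
    per_tissue = {
        str(tissue): qc_pass_rate(table.loc[[tissue]]) for tissue in table.index
    }
    n_cells = int(table.size)
    summary = {
        "overall_pass_rate": overall,
        "per_tissue_pass_rate": per_tissue,
        "n_pass": int(round(overall * n_cells)),
        "n_fail": n_cells - int(round(overall * n_cells)),
        "n_cells": n_cells,
    }
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(json.dumps(summary, indent=2))
    return summary
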