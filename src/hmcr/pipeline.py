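"""End-to-end screening pipeline.

Orchestrates the two screening strategies and the longitudinal scenario:
select a representative subset (from subject metadata or from crudely
compressed analytical data), resolve the subset by H-MCR with A/B
stability validation into a reference table, predictively resolve every
remaining sample against that table, normalize by internal standards when
they are known, and model pre/post class membership with OPLS-DA
(cross-validation, external prediction, permutation-based pattern
extraction). All artifacts are JSON/CSV; the same configuration and seed
reproduce them byte for byte, which is what makes the save-now /
predict-months-later replay trustworthy.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .datatypes import GCMSDataset, PeakTable, ReferenceTable
from .design import fit_pca, maximin_select, diversity_select_metadata
from .oplsda import (
    OplsDaModel,
    cross_validate,
    fit_oplsda,
    permutation_test,
    predict_samples,
)
from .preprocess import align, compress, normalize_peaktable
from .resolve import (
    build_reference_table,
    compare_reference_tables,
    match_factor,
    quantify,
    split_windows,
    stability_validate,
)
from .simulate import SimulationConfig, simulate_dataset, simulate_metadata

__all__ = [
    "PipelineConfig",
    "run_screening",
    "compare_strategies",
    "identify_standards",
    "predict_only",
]

logger = logging.getLogger("hmcr")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one screening run. JSON round-trip stable."""

    strategy: str = "analytical"  # metadata | analytical | all-samples
    k_subjects: int = 8
    n_pca_components: int = 3
    window_width: int = 40
    max_shift: int = 5
    compress_windows: int = 20
    stability_threshold: float = 0.95
    match_factor_min: int = 700
    rt_tolerance_s: float = 1.0
    folds: int = 7
    n_ortho: int | str = "auto"
    n_perm: int = 500
    alpha: float = 0.05
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("metadata", "analytical", "all-samples"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.stability_threshold < 1:
            raise ValueError("stability_threshold must lie in (0, 1)")
        if not 0 <= self.match_factor_min <= 999:
            raise ValueError("match_factor_min must lie in [0, 999]")
        if self.rt_tolerance_s < 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("invalid threshold configuration")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def identify_standards(
    reference: ReferenceTable,
    standard_spectra: np.ndarray,
    standard_rts: np.ndarray,
    mf_min: int = 700,
    rt_tol: float = 1.0,
) -> list[str]:
    """Locate known internal standards among resolved profiles.

    Each standard spectrum is matched to the reference profile with the
    highest match factor among those within the retention tolerance;
    standards with no admissible match are skipped.
    """
    found = []
    for spec, rt in zip(np.atleast_2d(standard_spectra), np.atleast_1d(standard_rts)):
        best_id, best_mf = None, mf_min
        for p in reference.profiles:
            if abs(p.apex_rt - rt) > rt_tol:
                continue
            mf = match_factor(spec, p.spectrum, reference.mz_axis)
            if mf > best_mf:
                best_id, best_mf = p.profile_id, mf
        if best_id is not None:
            found.append(best_id)
    return found


def default_simulation(seed: int, overrides: dict | None = None) -> SimulationConfig:
    """Study conditions for the built-in simulation scenario.

    24 subjects sampled pre/post (48 samples), a two-class fold-change
    pattern on a third of the metabolites, internal standards, mild drift
    and noise — the structure the screening design assumes.
    """
    sim = dict(
        n_samples=48,
        n_components=15,
        n_scans=360,
        mz_channels=100,
        noise_sd=0.02,
        drift_max=3,
        n_standards=3,
        bio_cv=0.15,
        seed=seed,
    )
    sim.update(overrides or {})
    sim.setdefault(
        "effect_sizes",
        _default_effects(sim["n_components"], sim["n_standards"]),
    )
    return SimulationConfig(**sim)


def _default_simulation(config: PipelineConfig) -> SimulationConfig:
    return default_simulation(config.seed, config.simulation)


def _default_effects(n_components: int, n_standards: int) -> np.ndarray:
    """Fold changes: every third metabolite regulated, alternating up/down."""
    eff = np.ones(n_components)
    n_bio = n_components - n_standards
    for j in range(0, n_bio, 3):
        eff[j] = 1.8 if (j // 3) % 2 == 0 else 0.55
    return eff


def _select_samples(
    config: PipelineConfig,
    dataset: GCMSDataset,
    subject_metadata: pd.DataFrame | None,
):
    md = dataset.metadata
    if config.strategy == "all-samples":
        return list(range(len(dataset))), {"strategy": "all-samples"}
    if config.strategy == "metadata":
        if subject_metadata is None:
            raise StageError("selection: metadata strategy needs a subject table")
        res = diversity_select_metadata(
            subject_metadata,
            config.n_pca_components,
            config.k_subjects,
            sample_metadata=md,
        )
        return res.selected_indices, {"strategy": "metadata", **res.to_dict()}
    # analytical: compress -> PCA -> subject-wise maximin
    vectors = np.vstack([v.values for v in compress(dataset, config.compress_windows)])
    keep = vectors.std(axis=0, ddof=1) > 0
    if not keep.any():
        raise StageError("selection: compression vectors carry no variation")
    model = fit_pca(vectors[:, keep], min(config.n_pca_components, len(dataset) - 1))
    res = maximin_select(
        model.scores,
        config.k_subjects,
        groups=md["subject"].to_numpy(),
        space="compressed",
    )
    return res.selected_indices, {"strategy": "analytical", **res.to_dict()}


def run_screening(
    config: PipelineConfig,
    dataset: GCMSDataset | None = None,
    subject_metadata: pd.DataFrame | None = None,
    truth=None,
) -> dict:
    """Run one screening strategy end to end; returns the report bundle.

    With no dataset, the built-in simulation scenario is generated from
    the config seed. Artifacts (reference table, peak table, model,
    report) are written under ``config.output_dir`` when set.
    """
    if dataset is None:
        sim_cfg = _default_simulation(config)
        dataset, truth = simulate_dataset(sim_cfg)
        if config.strategy == "metadata" and subject_metadata is None:
            n_subjects = len(dataset.metadata["subject"].unique())
            subject_metadata = simulate_metadata(n_subjects, 34, seed=config.seed + 1)
            subject_metadata.index = list(dataset.metadata["subject"].unique())
    elif config.strategy == "metadata" and subject_metadata is None:
        raise StageError("selection: metadata strategy needs a subject table")

    try:
        aligned = align(dataset, config.max_shift)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"alignment: {exc}") from exc

    model_idx, selection_info = _select_samples(config, aligned, subject_metadata)
    test_idx = [i for i in range(len(aligned)) if i not in set(model_idx)]
    subset = aligned.subset(model_idx)

    # --- resolution of the model samples -----------------------------------
    try:
        windows = split_windows(subset, config.window_width)
        profiles = [
            stability_validate(subset, w, threshold=config.stability_threshold)
            for w in windows
        ]
        reference = build_reference_table(
            profiles,
            mz_axis=subset.mz_axis,
            window_ranges={w.window_id: w.scan_range for w in windows},
            provenance={
                "model_samples": subset.sample_ids,
                "strategy": config.strategy,
                "seed": config.seed,
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"resolution: {exc}") from exc
    if len(reference) == 0:
        raise StageError("resolution: no stable profiles survived validation")

    # --- predictive quantification of every sample -------------------------
    peaks = quantify(aligned, reference)

    standard_ids: list[str] = []
    if truth is not None and truth.standard_ids:
        n_std = len(truth.standard_ids)
        standard_ids = identify_standards(
            reference,
            truth.true_spectra[-n_std:],
            aligned.rt_axis[np.rint(truth.true_retention[-n_std:]).astype(int)],
            mf_min=config.match_factor_min,
            rt_tol=config.rt_tolerance_s,
        )
    if standard_ids:
        peaks = normalize_peaktable(peaks, standard_ids)

    # --- classification -----------------------------------------------------
    y = aligned.metadata["class"].to_numpy(dtype=float)
    pt_model = PeakTable(
        areas=peaks.areas[model_idx],
        sample_ids=[peaks.sample_ids[i] for i in model_idx],
        profile_ids=list(peaks.profile_ids),
        normalized=peaks.normalized,
    )
    try:
        model = fit_oplsda(pt_model, y[model_idx], n_ortho=config.n_ortho, folds=config.folds)
        cv_report, q2 = cross_validate(pt_model, y[model_idx], model.n_ortho, config.folds)
        perm = permutation_test(
            pt_model,
            y[model_idx],
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
            n_ortho=model.n_ortho,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"modeling: {exc}") from exc

    test_report = None
    if test_idx:
        pt_test = PeakTable(
            areas=peaks.areas[test_idx],
            sample_ids=[peaks.sample_ids[i] for i in test_idx],
            profile_ids=list(peaks.profile_ids),
            normalized=peaks.normalized,
        )
        test_report = predict_samples(model, pt_test, y_true=y[test_idx])

    report = {
        "config": config.to_dict(),
        "selection": selection_info,
        "n_model_samples": len(model_idx),
        "n_test_samples": len(test_idx),
        "n_profiles": len(reference),
        "standards_used": standard_ids,
        "model": {
            "r2x": model.r2x,
            "r2y": model.r2y,
            "q2": q2,
            "n_ortho": model.n_ortho,
        },
        "accuracy_cv": cv_report.accuracy_cv,
        "accuracy_test": None if test_report is None else test_report.accuracy_test,
        "predicted_y": {
            **dict(zip(cv_report.sample_ids, map(float, cv_report.predicted_y))),
            **(
                {}
                if test_report is None
                else dict(zip(test_report.sample_ids, map(float, test_report.predicted_y)))
            ),
        },
        "test_sample_ids": [peaks.sample_ids[i] for i in test_idx],
        "significant_profiles": perm.significant_ids(),
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_reference_table(reference, out / "reference_table.json")
        apex = [p.apex_rt for p in reference.profiles]
        hio.write_peaktable(peaks, out / "peak_table.csv", apex_rts=apex)
        hio.write_json(model.to_dict(), out / "oplsda_model.json")
        hio.write_json(report, out / "report.json")

    report["_objects"] = {
        "reference": reference,
        "peaks": peaks,
        "model": model,
        "permutation": perm,
        "dataset": aligned,
        "truth": truth,
    }
    return report


def predict_only(
    dataset: GCMSDataset, reference: ReferenceTable, model: OplsDaModel, y_true=None
):
    """Replay a saved reference table + model against new raw data.

    This is the diagnostic-use contract: samples measured later are
    predictively resolved against the frozen reference table and
    classified by the frozen model, with no refitting anywhere.
    """
    peaks = quantify(dataset, reference)
    cols = [peaks.profile_ids.index(p) for p in model.profile_ids]
    pt = PeakTable(
        areas=peaks.areas[:, cols],
        sample_ids=list(peaks.sample_ids),
        profile_ids=list(model.profile_ids),
    )
    return peaks, predict_samples(model, pt, y_true=y_true)


def compare_strategies(report_a: dict, report_b: dict, shared_test_ids=None) -> dict:
    """Prediction-similarity of two screening runs on a shared test set.

    The statistic is the Pearson correlation of the two models' predicted
    y over samples held out of BOTH selections (or an explicit ID list).
    """
    ya, yb = report_a["predicted_y"], report_b["predicted_y"]
    if shared_test_ids is None:
        shared_test_ids = sorted(
            set(report_a.get("test_sample_ids", ya))
            & set(report_b.get("test_sample_ids", yb))
        )
    shared = [s for s in shared_test_ids if s in ya and s in yb]
    if not shared:
        raise ValueError("no shared test samples between the two reports")
    va = np.array([ya[s] for s in shared])
    vb = np.array([yb[s] for s in shared])
    r = float(np.corrcoef(va, vb)[0, 1]) if len(shared) > 1 else float("nan")
    agree = [
        {
            "sample_id": s,
            "y_a": float(a),
            "y_b": float(b),
            "class_a": int(a >= 0.5),
            "class_b": int(b >= 0.5),
            "agree": bool((a >= 0.5) == (b >= 0.5)),
        }
        for s, a, b in zip(shared, va, vb)
    ]
    return {
        "pearson_r": r,
        "n_shared": len(shared),
        "agreement_fraction": float(np.mean([row["agree"] for row in agree])),
        "per_sample": agree,
    }
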