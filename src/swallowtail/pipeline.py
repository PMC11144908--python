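"""End-to-end orchestration of the three pipeline variants.

``run_pipeline`` executes simulate -> preprocess -> detect -> extract ->
select -> train -> fuse -> fit -> evaluate for the requested variant:

* ``radiomics`` — IBSI features, ICC + LASSO selection, six classifiers;
* ``cnn``       — brainstem patches, modified LeNet, 3-of-4 patient vote;
* ``hybrid``    — radiomics + CNN, MDI-ranked deep features fused into
  1x30 vectors, six classifiers, NRI/IDI against the radiomics-only
  models.

All randomness flows from one master seed expanded into fixed per-stage
seeds recorded in the run manifest, alongside input/output checksums of
every stage, so a rerun with the same config is bit-reproducible and
test data can be shown never to enter any fitted component.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deepnet import (
    LABEL_TO_INT,
    TrainedModelBundle,
    extract_deep_features,
    train_cnn,
)
from .evaluate import EvalReport, confusion_metrics, idi, nri, roc_auc, vote_patient
from .fusion import aggregate_case_features, fuse, fused_table, mdi_rank, train_classifiers
from .localizer import detect_brainstem, train_detector
from .phantom import PhantomParams, SyntheticCase, generate_cohort
from .preprocess import SetMagVolume, reconstruct_setmag, resample
from .radiomics import ExtractionConfig, extract_all, feature_table
from .selection import FeatureScaler, icc_filter, lasso_select

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult",
           "split_cases", "run_pipeline", "external_validate"]

VARIANTS = ("radiomics", "cnn", "hybrid")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on; defaults mirror the study
    conditions (65 HC + 73 PD, 8:2 split, five folds, 10 + 20 fusion)."""

    n_hc: int = 65
    n_pd: int = 73
    phantom: PhantomParams = field(default_factory=PhantomParams)
    split_ratio: float = 0.8
    n_folds: int = 5
    seed: int = 0
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    icc_threshold: float = 0.8
    n_rater2: int = 30
    lasso_cap: int | None = 10
    fusion_k: int = 20
    detector_epochs: int = 15
    cnn_epochs: int = 25
    cnn_patience: int = 6
    cnn_lr: float = 1e-3
    cnn_batch: int = 32

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")


class RunManifest:
    """Per-stage seeds, wall time and input/output checksums."""

    def __init__(self) -> None:
        self.stages: dict[str, dict] = {}

    @staticmethod
    def checksum(*objects) -> str:
        h = hashlib.sha256()
        for obj in objects:
            if isinstance(obj, np.ndarray):
                h.update(np.ascontiguousarray(obj).tobytes())
            elif isinstance(obj, pd.DataFrame):
                h.update(obj.to_csv().encode())
            else:
                h.update(repr(obj).encode())
        return h.hexdigest()[:16]

    def record(self, stage: str, seconds: float, seed: int | None = None,
               inputs: str = "", outputs: str = "") -> None:
        self.stages[stage] = {
            "seconds": round(seconds, 3),
            "seed": seed,
            "inputs": inputs,
            "outputs": outputs,
        }

    def to_json(self) -> str:
        return json.dumps(self.stages, indent=2)


@dataclass
class PipelineResult:
    config: PipelineConfig
    variant: str
    train_ids: list[str]
    test_ids: list[str]
    reports: dict[str, dict[str, EvalReport]]  # variant -> model -> report
    patient_probs: dict[str, dict[str, np.ndarray]]  # variant -> model -> probs
    truth: np.ndarray
    nri_idi: dict[str, dict[str, float]]
    manifest: RunManifest
    selection: object | None = None
    cnn_bundle: TrainedModelBundle | None = None
    ranking: object | None = None
    models: dict[str, dict[str, object]] = field(default_factory=dict)
    fused_columns: list[str] = field(default_factory=list)
    deep_mu: np.ndarray | None = None
    deep_sd: np.ndarray | None = None
    detector: object | None = None
    stacks: dict[str, object] = field(default_factory=dict)
    radiomics_selected: pd.DataFrame | None = None  # z-scored, train + test rows
    deep_standardized: pd.DataFrame | None = None  # z-scored, train + test rows

    def table2(self) -> pd.DataFrame:
        """Per-model metric table shaped like a clinical results table."""
        rows = []
        for variant, models in self.reports.items():
            for name, rep in models.items():
                row = {"Feature": variant, "Model": name, **rep.as_dict()}
                comp = self.nri_idi.get(name, {})
                if variant == "hybrid" and comp:
                    row["NRI"] = comp["nri"]
                    row["NRI_p"] = comp["nri_p"]
                    row["IDI"] = comp["idi"]
                    row["IDI_p"] = comp["idi_p"]
                rows.append(row)
        return pd.DataFrame(rows)


def split_cases(cases: list[SyntheticCase], ratio: float = 0.8, seed: int = 0):
    """Stratified case-level split; the test share is floor(n * (1 - ratio)),
    apportioned across classes by largest remainder (138 at 0.8 -> 111/27)."""
    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    rng = np.random.default_rng(seed)
    # floor of the test share, guarded against float repr of (1 - ratio)
    n_test_total = int(np.floor(len(cases) * (1.0 - ratio) + 1e-9))
    by_label: dict[str, list[int]] = {}
    for i, case in enumerate(cases):
        by_label.setdefault(case.label, []).append(i)
    if any(len(v) < 2 for v in by_label.values()):
        raise ValueError("every class needs at least 2 cases to stratify")
    quotas = {lab: n_test_total * len(v) / len(cases) for lab, v in by_label.items()}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    short = n_test_total - sum(base.values())
    for lab in sorted(quotas, key=lambda l: quotas[l] - base[l], reverse=True)[:short]:
        base[lab] += 1
    test_idx: set[int] = set()
    for lab, members in by_label.items():
        chosen = rng.choice(members, size=base[lab], replace=False)
        test_idx.update(int(i) for i in chosen)
    train = [c for i, c in enumerate(cases) if i not in test_idx]
    test = [c for i, c in enumerate(cases) if i in test_idx]
    return train, test


def _preprocess_case(case: SyntheticCase, target_spacing) -> tuple[SetMagVolume, np.ndarray, np.ndarray]:
    from scipy import ndimage

    setmag = resample(reconstruct_setmag(case.echoes), target_spacing)
    src = case.echoes.voxel_spacing
    if tuple(src) == tuple(target_spacing):
        return setmag, case.snpc_mask.copy(), case.rater2_mask.copy()
    zoom = [s / t for s, t in zip(src, target_spacing)]
    mask = ndimage.zoom(case.snpc_mask.astype(np.uint8), zoom, order=0) > 0
    mask2 = ndimage.zoom(case.rater2_mask.astype(np.uint8), zoom, order=0) > 0
    return setmag, mask, mask2


def _patient_report(probs: np.ndarray, truth: np.ndarray, seed: int) -> EvalReport:
    rep = confusion_metrics((probs >= 0.5).astype(int), truth)
    rep.auc, rep.auc_ci = roc_auc(probs, truth, seed=seed)
    return rep


def run_pipeline(config: PipelineConfig, variant: str = "hybrid") -> PipelineResult:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    manifest = RunManifest()
    seeds = {name: config.seed + off for off, name in enumerate(
        ("simulate", "split", "detector", "cnn", "mdi", "lasso", "classifiers", "auc"),
    )}

    t0 = time.perf_counter()
    cases = generate_cohort(config.n_hc, config.n_pd, config.phantom, seeds["simulate"])
    manifest.record("simulate", time.perf_counter() - t0, seeds["simulate"],
                    outputs=manifest.checksum(*[c.case_id for c in cases]))

    train_cases, test_cases = split_cases(cases, config.split_ratio, seeds["split"])
    manifest.record("split", 0.0, seeds["split"],
                    outputs=manifest.checksum([c.case_id for c in train_cases],
                                              [c.case_id for c in test_cases]))

    t0 = time.perf_counter()
    prepped = {c.case_id: _preprocess_case(c, config.target_spacing) for c in cases}
    manifest.record("preprocess", time.perf_counter() - t0)

    truth = np.array([LABEL_TO_INT[c.label] for c in test_cases])
    train_y = np.array([LABEL_TO_INT[c.label] for c in train_cases])
    reports: dict[str, dict[str, EvalReport]] = {}
    patient_probs: dict[str, dict[str, np.ndarray]] = {}
    result = PipelineResult(
        config=config, variant=variant,
        train_ids=[c.case_id for c in train_cases],
        test_ids=[c.case_id for c in test_cases],
        reports=reports, patient_probs=patient_probs, truth=truth,
        nri_idi={}, manifest=manifest,
    )

    # ---------------- radiomics branch ----------------
    selected_train = selected_test = None
    if variant in ("radiomics", "hybrid"):
        t0 = time.perf_counter()
        rows = {c.case_id: extract_all(prepped[c.case_id][0], prepped[c.case_id][1],
                                       config.extraction, c.case_id)
                for c in cases}
        table = feature_table([rows[c.case_id] for c in cases])
        train_table = table.loc[result.train_ids]
        test_table = table.loc[result.test_ids]
        manifest.record("extract", time.perf_counter() - t0,
                        inputs=manifest.checksum(*result.train_ids),
                        outputs=manifest.checksum(table))

        t0 = time.perf_counter()
        n_r2 = min(config.n_rater2, len(train_cases))
        r2_cases = train_cases[:n_r2]
        r2_rows = [
            extract_all(prepped[c.case_id][0], prepped[c.case_id][2],
                        config.extraction, c.case_id)
            for c in r2_cases
        ]
        r2_table = feature_table(r2_rows)
        retained, icc_values = icc_filter(
            train_table.loc[r2_table.index], r2_table, config.icc_threshold
        )
        manifest.record("icc_filter", time.perf_counter() - t0,
                        inputs=manifest.checksum(r2_table),
                        outputs=manifest.checksum(retained))

        t0 = time.perf_counter()
        scaler = FeatureScaler.fit(train_table[retained])
        z_train = scaler.transform(train_table[retained])
        z_test = scaler.transform(test_table[retained])
        sel = lasso_select(z_train, train_y, config.n_folds, seeds["lasso"],
                           cap_to_k=config.lasso_cap)
        sel.icc_per_feature = icc_values
        sel.retained_after_icc = retained
        sel.scaler = scaler
        result.selection = sel
        selected_train = z_train[sel.selected_features]
        selected_test = z_test[sel.selected_features]
        result.radiomics_selected = pd.concat([selected_train, selected_test])
        manifest.record("select", time.perf_counter() - t0, seeds["lasso"],
                        inputs=manifest.checksum(z_train),
                        outputs=manifest.checksum(sel.selected_features))

        t0 = time.perf_counter()
        rad_models = train_classifiers(selected_train, train_y, seeds["classifiers"])
        reports["radiomics"] = {}
        patient_probs["radiomics"] = {}
        for name, model in rad_models.items():
            probs = model.predict_proba(selected_test.to_numpy())[:, 1]
            patient_probs["radiomics"][name] = probs
            reports["radiomics"][name] = _patient_report(probs, truth, seeds["auc"])
        result.models["radiomics"] = rad_models
        manifest.record("fit_radiomics", time.perf_counter() - t0, seeds["classifiers"])

    # ---------------- CNN branch ----------------
    deep_train = deep_test = None
    if variant in ("cnn", "hybrid"):
        t0 = time.perf_counter()
        detector = train_detector(train_cases, seeds["detector"],
                                  epochs=config.detector_epochs)
        result.detector = detector
        manifest.record("detect_train", time.perf_counter() - t0, seeds["detector"],
                        inputs=manifest.checksum(*result.train_ids))

        t0 = time.perf_counter()
        stacks = {}
        for c in cases:
            vol = prepped[c.case_id][0]
            mask = prepped[c.case_id][1]
            slices = sorted(np.unique(np.nonzero(mask)[2]).tolist())[:4]
            stacks[c.case_id] = detect_brainstem(vol, slices, detector, c.case_id)
        result.stacks = stacks
        manifest.record("detect", time.perf_counter() - t0)

        t0 = time.perf_counter()
        bundle = train_cnn(
            [(stacks[c.case_id], c.label) for c in train_cases],
            n_folds=config.n_folds, seed=seeds["cnn"], epochs=config.cnn_epochs,
            batch_size=config.cnn_batch, lr=config.cnn_lr,
            patience=config.cnn_patience,
        )
        result.cnn_bundle = bundle
        manifest.record("train_cnn", time.perf_counter() - t0, seeds["cnn"],
                        inputs=manifest.checksum(*result.train_ids))

        image_probs_test = np.stack([
            bundle.model.predict_proba(stacks[cid].patches)[:, 1]
            for cid in result.test_ids
        ])
        votes = np.array([
            vote_patient((p >= 0.5).astype(int)) for p in image_probs_test
        ])
        probs = image_probs_test.mean(axis=1)
        rep = confusion_metrics(votes, truth)
        rep.auc, rep.auc_ci = roc_auc(probs, truth, seed=seeds["auc"])
        reports.setdefault("cnn", {})["CNN"] = rep
        patient_probs.setdefault("cnn", {})["CNN"] = probs

        if variant == "hybrid":
            deep = {
                cid: aggregate_case_features(
                    extract_deep_features(bundle.model, stacks[cid])
                )
                for cid in result.train_ids + result.test_ids
            }
            deep_train = np.stack([deep[cid] for cid in result.train_ids])
            deep_test = np.stack([deep[cid] for cid in result.test_ids])

    # ---------------- hybrid fusion ----------------
    if variant == "hybrid":
        t0 = time.perf_counter()
        mu, sd = deep_train.mean(axis=0), deep_train.std(axis=0)
        sd[sd == 0] = 1.0
        result.deep_mu, result.deep_sd = mu, sd
        z_deep_train = (deep_train - mu) / sd
        z_deep_test = (deep_test - mu) / sd
        result.deep_standardized = pd.DataFrame(
            np.vstack([z_deep_train, z_deep_test]),
            index=result.train_ids + result.test_ids,
        )
        ranking = mdi_rank(z_deep_train, train_y, n_runs=100, seed=seeds["mdi"])
        result.ranking = ranking
        manifest.record("mdi_rank", time.perf_counter() - t0, seeds["mdi"],
                        inputs=manifest.checksum(z_deep_train),
                        outputs=manifest.checksum(ranking.rank_order))

        t0 = time.perf_counter()
        vec_train = [
            fuse(selected_train.loc[cid].to_dict(), z_deep_train[i], ranking,
                 config.fusion_k, cid)
            for i, cid in enumerate(result.train_ids)
        ]
        vec_test = [
            fuse(selected_test.loc[cid].to_dict(), z_deep_test[i], ranking,
                 config.fusion_k, cid)
            for i, cid in enumerate(result.test_ids)
        ]
        fused_train = fused_table(vec_train)
        fused_test = fused_table(vec_test)
        result.fused_columns = list(fused_train.columns)
        hyb_models = train_classifiers(fused_train, train_y, seeds["classifiers"])
        reports["hybrid"] = {}
        patient_probs["hybrid"] = {}
        for name, model in hyb_models.items():
            probs = model.predict_proba(fused_test.to_numpy())[:, 1]
            patient_probs["hybrid"][name] = probs
            reports["hybrid"][name] = _patient_report(probs, truth, seeds["auc"])
            old = patient_probs["radiomics"][name]
            nri_v, nri_p = nri(old, probs, truth)
            idi_v, idi_p = idi(old, probs, truth)
            result.nri_idi[name] = {
                "nri": nri_v, "nri_p": nri_p, "idi": idi_v, "idi_p": idi_p,
            }
        result.models["hybrid"] = hyb_models
        manifest.record("fuse_fit", time.perf_counter() - t0, seeds["classifiers"],
                        inputs=manifest.checksum(fused_train),
                        outputs=manifest.checksum(fused_test))

    return result


def external_validate(result: PipelineResult, n_hc: int = 12, n_pd: int = 12,
                      phantom: PhantomParams | None = None,
                      seed: int = 10_000) -> dict[str, EvalReport]:
    """Evaluate frozen hybrid-variant models on a freshly generated cohort.

    Emulates an external validation center: a different master seed and
    (optionally) slightly different phantom parameters; no component is
    refit.
    """
    if result.variant != "hybrid" or result.cnn_bundle is None:
        raise ValueError("external validation requires a completed hybrid run")
    config = result.config
    phantom = phantom or replace(config.phantom, noise_sigma=config.phantom.noise_sigma * 1.2)
    cases = generate_cohort(n_hc, n_pd, phantom, seed)
    truth = np.array([LABEL_TO_INT[c.label] for c in cases])
    sel = result.selection
    detector = result.detector  # frozen, trained on the original training set
    reports: dict[str, EvalReport] = {}

    prepped = {c.case_id: _preprocess_case(c, config.target_spacing) for c in cases}
    rows = [extract_all(prepped[c.case_id][0], prepped[c.case_id][1],
                        config.extraction, c.case_id) for c in cases]
    table = feature_table(rows)
    z = sel.scaler.transform(table[sel.retained_after_icc])[sel.selected_features]

    stacks = {}
    for c in cases:
        vol, mask, _ = prepped[c.case_id]
        slices = sorted(np.unique(np.nonzero(mask)[2]).tolist())[:4]
        stacks[c.case_id] = detect_brainstem(vol, slices, detector, c.case_id)
    deep = np.stack([
        aggregate_case_features(extract_deep_features(result.cnn_bundle.model, stacks[c.case_id]))
        for c in cases
    ])
    mu, sd = result.deep_mu, result.deep_sd  # training-set statistics, frozen
    z_deep = (deep - mu) / sd
    vecs = [fuse(z.loc[c.case_id].to_dict(), z_deep[i], result.ranking,
                 config.fusion_k, c.case_id) for i, c in enumerate(cases)]
    fused = fused_table(vecs)[result.fused_columns]
    for name, model in result.models["hybrid"].items():
        probs = model.predict_proba(fused.to_numpy())[:, 1]
        reports[name] = _patient_report(probs, truth, seed)
    return reports
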