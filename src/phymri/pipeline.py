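"""End-to-end orchestration: simulate → maps → features → select → classify.

Two entry points:

* :func:`run_synthetic_experiment` — in-memory study on a synthetic
  cohort: simulate, map, extract, stability-filter, consensus-select and
  cross-validate/test classifiers.  Used by the worked examples and the
  reproduction script.
* :func:`run_pipeline` — file-based staged pipeline driven by a
  :class:`PipelineConfig`: each stage writes its outputs under the work
  directory and records checksums in a :class:`RunManifest`; a rerun with
  an unchanged config skips completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import (ClassifierSpec, cross_validate, default_grid_specs,
                       evaluate_test, run_model_grid, build_classifier)
from .cohort import (AcquisitionConfig, cohort_case_plan, default_profiles,
                     perturb_mask, simulate_case)
from .constants import DATASET_IMAGES, ENTITY_LABELS
from .maps import compute_case_maps
from .radiomics import extract_feature_table
from .radiomics.preprocess import resample_isotropic, znormalize
from .selection import (compute_icc, consensus_select, rank_filters,
                        smote_balance, stability_filter)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "prepare_feature_case", "cohort_feature_table",
           "run_synthetic_experiment", "PAPER_TRAIN_COUNTS",
           "PAPER_TEST_COUNTS"]

#: Training-cohort class counts of the emulated study (167 cases).
PAPER_TRAIN_COUNTS = {"GBM": 77, "AG": 17, "MNG": 28, "PCNSL": 16, "META": 29}
#: Independent test-cohort class counts (20 cases, no PCNSL).
PAPER_TEST_COUNTS = {"GBM": 9, "AG": 3, "MNG": 3, "PCNSL": 0, "META": 5}

_ANATOMICAL = ("CET1w", "FLAIR")


def prepare_feature_case(case, maps: dict, image_names, tumor_mask=None,
                         out_spacing: float = 1.0) -> dict:
    """Resample one case to isotropic 1 mm and package it for extraction.

    Anatomical images are z-normalized before resampling; quantitative
    maps carry their validity masks (physiological thresholding) along.
    ``tumor_mask`` overrides the case's own tumor VOI (used for the
    stability re-segmentations).
    """
    spacing = case.spacing
    images, valid = {}, {}
    for name in image_names:
        if name in _ANATOMICAL:
            img = znormalize(case.series[name])
            images[name], _ = resample_isotropic(img, spacing, out_spacing)
        else:
            bm = maps[name]
            images[name], _ = resample_isotropic(bm.values, spacing, out_spacing)
            vmask, _ = resample_isotropic(bm.valid, spacing, out_spacing,
                                          is_mask=True)
            valid[name] = vmask
    tmask = case.tumor_mask if tumor_mask is None else tumor_mask
    tumor, _ = resample_isotropic(tmask, spacing, out_spacing, is_mask=True)
    edema, _ = resample_isotropic(case.edema_mask, spacing, out_spacing,
                                  is_mask=True)
    return {
        "images": images, "valid": valid,
        "masks": {"tumor": tumor, "edema": edema},
        "spacing": (out_spacing,) * 3,
        "label": case.entity_label,
    }


def lesion_roi(case, dilate: int = 2) -> np.ndarray:
    """Tumor + edema, dilated: the region where per-voxel perfusion and
    qBOLD mapping is evaluated (features only read the VOIs)."""
    from scipy import ndimage

    return ndimage.binary_dilation(case.tumor_mask | case.edema_mask,
                                   iterations=dilate)


def case_maps(case, config):
    """Mapping chain restricted to the lesion region of interest."""
    return compute_case_maps(case, config, roi=lesion_roi(case))


def cohort_feature_table(cases, config, data_set: str, vois: str = "both",
                         maps_per_case: list | None = None) -> pd.DataFrame:
    """Maps + feature extraction for a whole cohort, one data set."""
    image_names = DATASET_IMAGES[data_set]
    prepared = []
    for i, case in enumerate(cases):
        maps = (maps_per_case[i] if maps_per_case is not None
                else case_maps(case, config))
        prepared.append(prepare_feature_case(case, maps, image_names))
    return extract_feature_table(prepared, data_set, vois=vois)


def run_synthetic_experiment(
    seed: int = 1,
    n_train: dict | None = None,
    n_test: dict | None = None,
    data_set: str = "phyMRI",
    vois: str = "tumor",
    config: AcquisitionConfig | None = None,
    separation: float = 1.0,
    families: tuple = ("RF", "AdaBoost"),
    n_icc_cases: int = 50,
    icc_threshold: float = 0.9,
    folds: int = 10,
    smote: str = "fold",
) -> dict:
    """Full synthetic study: cohort → maps → features → selection → models.

    Returns a dict with the feature tables, ICC report, consensus set, and
    per-family cross-validation and independent-test
    :class:`~phymri.classify.EvaluationReport` objects.  Deterministic for
    a fixed seed.
    """
    if config is None:
        config = AcquisitionConfig()
    n_train = dict(PAPER_TRAIN_COUNTS if n_train is None else n_train)
    n_test = dict(PAPER_TEST_COUNTS if n_test is None else n_test)
    n_test = {k: v for k, v in n_test.items() if v > 0}
    profiles = default_profiles(separation)
    image_names = DATASET_IMAGES[data_set]

    train_plan = cohort_case_plan(n_train, seed)
    test_plan = cohort_case_plan(n_test, seed + 1)

    # pick the stability subset up front so each case is simulated once
    do_icc = bool(n_icc_cases) and vois in ("tumor", "both")
    icc_idx: set = set()
    if do_icc:
        rng = np.random.default_rng(seed + 2)
        icc_idx = set(rng.choice(len(train_plan),
                                 size=min(n_icc_cases, len(train_plan)),
                                 replace=False).tolist())

    def one_case(label, case_seed, i=None):
        # stream: simulate → maps → features, discard the raw series
        case = simulate_case(profiles[label], config, case_seed)
        maps = case_maps(case, config)
        prepared = [prepare_feature_case(case, maps, image_names)]
        reread = None
        if i is not None and i in icc_idx:
            prepared.append(prepare_feature_case(
                case, maps, image_names,
                tumor_mask=perturb_mask(case.tumor_mask,
                                        seed=int(seed + 100 + i),
                                        spacing=case.spacing)))
        rows = extract_feature_table(prepared, data_set, vois=vois)
        if len(rows) > 1:
            reread = rows.iloc[[1]]
        return rows.iloc[[0]], reread

    train_rows, icc_pairs = [], []
    for i, (label, case_seed) in enumerate(train_plan):
        row, reread = one_case(label, case_seed, i)
        train_rows.append(row)
        if reread is not None:
            icc_pairs.append((i, row, reread))
    test_rows = [one_case(label, case_seed)[0]
                 for label, case_seed in test_plan]

    train_table = pd.concat(train_rows, ignore_index=True)
    test_table = pd.concat(test_rows, ignore_index=True)
    y_train = train_table.pop("entity")
    y_test = test_table.pop("entity")

    out: dict = {"train_table": train_table, "test_table": test_table,
                 "y_train": y_train, "y_test": y_test}
    features = train_table
    if icc_pairs:
        first = pd.concat([p[1] for p in icc_pairs],
                          ignore_index=True).drop(columns="entity")
        second = pd.concat([p[2] for p in icc_pairs],
                           ignore_index=True).drop(columns="entity")
        icc = compute_icc(first, second)
        out["icc"] = icc
        features = stability_filter(train_table, icc.fillna(-1.0),
                                    threshold=icc_threshold)

    rankings = rank_filters(features, y_train)
    consensus = consensus_select(rankings)
    out["rankings"] = rankings
    out["consensus"] = consensus
    selected = consensus.features

    out["cv_reports"], out["test_reports"] = {}, {}
    for fam in families:
        spec = ClassifierSpec(fam, seed=seed)
        out["cv_reports"][fam] = cross_validate(
            spec, features[selected], y_train, folds=folds, seed=seed,
            smote=smote)
        Xtr, ytr = smote_balance(features[selected], y_train, seed=seed)
        model = build_classifier(spec, n_features=len(selected),
                                 n_classes=y_train.nunique())
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model.fit(Xtr.to_numpy(), np.asarray(ytr))
        out["test_reports"][fam] = evaluate_test(
            model, test_table, y_test, feature_list=selected)
    return out


# ---------------------------------------------------------------------------
# file-based staged pipeline


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    workdir: str = "phymri_run"
    seed: int = 1
    n_train: dict = field(default_factory=lambda: dict(PAPER_TRAIN_COUNTS))
    n_test: dict = field(default_factory=lambda: dict(PAPER_TEST_COUNTS))
    data_sets: list = field(default_factory=lambda: ["phyMRI"])
    vois: str = "tumor"
    separation: float = 1.0
    families: list = field(default_factory=lambda: ["RF", "AdaBoost"])
    folds: int = 10
    smote: str = "fold"
    n_icc_cases: int = 50
    icc_threshold: float = 0.9
    stages: list = field(default_factory=lambda: [
        "simulate", "features", "select", "classify", "evaluate"])
    acquisition: dict = field(default_factory=dict)

    def acquisition_config(self) -> AcquisitionConfig:
        kw = dict(self.acquisition)
        for key in ("shape", "spacing", "echo_times_ge", "echo_times_se",
                    "b_values"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return AcquisitionConfig(**kw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, stage outputs, timings."""

    config_digest: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha}, seconds}
    version: str = "0.1.0"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config_digest=d["config_digest"], stages=d["stages"],
                   version=d.get("version", "?"))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_complete(manifest: RunManifest, stage: str, root: Path) -> bool:
    entry = manifest.stages.get(stage)
    if not entry:
        return False
    for rel, digest in entry["files"].items():
        p = root / rel
        if not p.exists() or _sha(p) != digest:
            return False
    return True


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages, skipping stages whose outputs are
    present and unchanged (checksum match against the manifest)."""
    root = Path(config.workdir)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.json"
    old = (RunManifest.load(manifest_path) if manifest_path.exists() else None)
    manifest = RunManifest(config_digest=config.digest())
    if old is not None and old.config_digest == manifest.config_digest:
        manifest.stages = dict(old.stages)

    acq = config.acquisition_config()

    def record(stage, files, t0):
        manifest.stages[stage] = {
            "files": {str(f.relative_to(root)): _sha(f) for f in files},
            "seconds": round(time.time() - t0, 2),
        }
        manifest.save(manifest_path)

    def wants(stage):
        return stage in config.stages

    if wants("simulate") and not _stage_complete(manifest, "simulate", root):
        t0 = time.time()
        profiles = default_profiles(config.separation)
        files = []
        manifest_rows = []
        for split, counts, seed in (("train", config.n_train, config.seed),
                                    ("test", config.n_test, config.seed + 1)):
            counts = {k: v for k, v in counts.items() if v > 0}
            for i, (label, case_seed) in enumerate(
                    cohort_case_plan(counts, seed)):
                case = simulate_case(profiles[label], acq, case_seed)
                d = pio.write_case(case, root / "cases" / f"{split}_{i:03d}")
                files.extend(sorted(d.glob("*")))
                manifest_rows.append({"split": split, "case": d.name,
                                      "entity": label, "seed": case_seed})
        cohort_csv = root / "cohort.csv"
        pd.DataFrame(manifest_rows).to_csv(cohort_csv, index=False)
        files.append(cohort_csv)
        record("simulate", files, t0)

    def load_split(split):
        dirs = sorted((root / "cases").glob(f"{split}_*"))
        return [pio.read_case(d) for d in dirs]

    if wants("features") and not _stage_complete(manifest, "features", root):
        t0 = time.time()
        files = []
        for split in ("train", "test"):
            cases = load_split(split)
            if not cases:
                continue
            for ds in config.data_sets:
                table = cohort_feature_table(cases, acq, ds, vois=config.vois)
                out = root / f"features_{split}_{ds.replace('+', '_')}.csv"
                table.to_csv(out, index=False)
                files.append(out)
        record("features", files, t0)

    if wants("select") and not _stage_complete(manifest, "select", root):
        t0 = time.time()
        files = []
        for ds in config.data_sets:
            table = pd.read_csv(root / f"features_train_{ds.replace('+', '_')}.csv")
            y = table.pop("entity")
            rankings = rank_filters(table, y)
            consensus = consensus_select(rankings)
            out = root / f"selected_{ds.replace('+', '_')}.json"
            out.write_text(json.dumps({
                "features": consensus.features,
                "filter_counts": consensus.filter_counts}, indent=1))
            files.append(out)
        record("select", files, t0)

    if wants("classify") and not _stage_complete(manifest, "classify", root):
        t0 = time.time()
        files = []
        for ds in config.data_sets:
            stem = ds.replace("+", "_")
            table = pd.read_csv(root / f"features_train_{stem}.csv")
            y = table.pop("entity")
            selected = json.loads(
                (root / f"selected_{stem}.json").read_text())["features"]
            for fam in config.families:
                rep = cross_validate(ClassifierSpec(fam, seed=config.seed),
                                     table[selected], y, folds=config.folds,
                                     seed=config.seed, smote=config.smote)
                rep.dataset, rep.voi = ds, config.vois
                out = pio.write_report(rep, root / f"cv_{fam}_{stem}.json")
                files.append(out)
        record("classify", files, t0)

    if wants("evaluate") and not _stage_complete(manifest, "evaluate", root):
        t0 = time.time()
        files = []
        for ds in config.data_sets:
            stem = ds.replace("+", "_")
            test_path = root / f"features_test_{stem}.csv"
            if not test_path.exists():
                continue
            train = pd.read_csv(root / f"features_train_{stem}.csv")
            y_train = train.pop("entity")
            test = pd.read_csv(test_path)
            y_test = test.pop("entity")
            selected = json.loads(
                (root / f"selected_{stem}.json").read_text())["features"]
            for fam in config.families:
                spec = ClassifierSpec(fam, seed=config.seed)
                Xb, yb = smote_balance(train[selected], y_train,
                                       seed=config.seed)
                model = build_classifier(spec, n_features=len(selected),
                                         n_classes=y_train.nunique())
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    model.fit(Xb.to_numpy(), np.asarray(yb))
                rep = evaluate_test(model, test, y_test, feature_list=selected)
                rep.dataset, rep.voi = ds, config.vois
                out = pio.write_report(rep, root / f"test_{fam}_{stem}.json")
                files.append(out)
        record("evaluate", files, t0)

    return manifest
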