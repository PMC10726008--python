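"""End-to-end orchestration: simulate -> preprocess -> align -> screen ->
annotate -> select -> train -> evaluate -> vote.

One :class:`PipelineConfig` drives the whole run; every stage is also
callable on its own through the module API, and all artifacts are stamped
with the config hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from maldisub import annotate as annotate_mod
from maldisub.align import build_reference_peaks, featurize
from maldisub.models import (
    CLASSIFIER_KINDS,
    SplitSpec,
    evaluate_scores,
    fit_predict,
    permutation_importance,
    rfecv_select,
    scale_minmax,
    split_dataset,
    youden_threshold_cv,
)
from maldisub.preprocess import (
    condition_spectrum,
    deduplicate_peaks,
    pick_peaks,
    read_spectrum_txt,
    spectrum_to_peaklist,
)
from maldisub.screen import biomarker_table, heatmap_matrix, pca_scores
from maldisub.simulate import SimConfig, simulate_cohort, write_cohort
from maldisub.voting import summarize_strain_calls, vote_strain


@dataclass
class PipelineConfig:
    """Parameters for every pipeline stage plus the global seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    smooth_window: int = 7
    baseline_window: float = 500.0
    snr_min: float = 3.0
    min_rel_intensity: float = 0.01
    dedup_tol_ppm: float = 500.0
    align_tol_ppm: float = 500.0
    min_support_frac: float = 0.05
    specific_hi: float = 0.95
    specific_lo: float = 0.05
    protein_fasta: str | None = None
    annotate_tol_da: float = 5.0
    train_frac: float = 0.7
    group_by_strain: bool = True
    rfecv_step: int = 1
    rfecv_folds: int = 5
    vote_threshold: float | None = None  # default: Youden threshold from training scores
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["markers"] = [dataclasses.asdict(m) for m in self.sim.markers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from maldisub.markers import MarkerDef

        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            markers = sim.pop("markers", None)
            sim_cfg = SimConfig(**sim)
            if markers is not None:
                sim_cfg.markers = [MarkerDef(**m) for m in markers]
        else:
            sim_cfg = sim
        return cls(sim=sim_cfg, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def peaklists_from_spectra(spectra, config: PipelineConfig):
    """Condition + pick (profile) or pass through (centroid), then deduplicate."""
    out = []
    for s in spectra:
        if s.centroid:
            pl = spectrum_to_peaklist(s)
        else:
            cond = condition_spectrum(
                s, smooth_window=config.smooth_window, baseline_window=config.baseline_window
            )
            pl = pick_peaks(cond, snr_min=config.snr_min, min_rel_intensity=config.min_rel_intensity)
        out.append(deduplicate_peaks(pl, tol_ppm=config.dedup_tol_ppm))
    return out


def load_cohort(manifest_path, centroid: bool = False):
    """Read a written cohort back: (manifest, spectra)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"manifest is empty: {manifest_path}")
    base = manifest_path.parent
    missing = [p for p in manifest["path"] if not (base / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing spectrum files listed in manifest: {missing[:5]}")
    spectra = [
        read_spectrum_txt(
            base / r.path,
            strain_id=r.strain_id,
            replicate=int(r.replicate),
            label=int(r.label),
            centroid=centroid,
        )
        for r in manifest.itertuples()
    ]
    return manifest, spectra


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full pipeline on a simulated cohort and return the run report.

    The report carries, per classifier: selected features, the RFECV curve,
    spectrum-level test metrics (sensitivity, specificity, accuracy, Youden,
    AUC at the Youden cutoff of the test scores), permutation importances,
    and the strain-level voting summary (confusion matrix and accuracy)
    using the Youden threshold learned on the training scores.
    """
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    manifest, spectra = simulate_cohort(sim_cfg)

    peaklists = peaklists_from_spectra(spectra, config)
    refset = build_reference_peaks(
        peaklists, tol_ppm=config.align_tol_ppm, min_support_frac=config.min_support_frac
    )
    fm = featurize(peaklists, refset, manifest)

    bt = biomarker_table(fm, specific_hi=config.specific_hi, specific_lo=config.specific_lo)
    scores_pca, evr = pca_scores(fm)
    heat = heatmap_matrix(bt, fm)

    assignments = None
    if config.protein_fasta:
        proteins = annotate_mod.read_protein_fasta(config.protein_fasta)
        matches = annotate_mod.match_peaks_to_proteins(refset, proteins, tol_da=config.annotate_tol_da)
        assignments = annotate_mod.assignments_to_frame(matches)
        primary = assignments[assignments["primary"]].set_index("ref_mz")["protein_id"]
        bt["assignment"] = [primary.get(m, "") for m in bt["ref_mz"]]

    split = SplitSpec(
        train_frac=config.train_frac, group_by_strain=config.group_by_strain, seed=config.seed
    )
    train_fm, test_fm = split_dataset(fm, split)
    X_train_all, X_test_all, _params = scale_minmax(
        train_fm.rel_intensity, test_fm.rel_intensity
    )
    y_train = train_fm.labels.to_numpy()
    y_test = test_fm.labels.to_numpy()
    selected, cv_curve = rfecv_select(
        X_train_all, y_train, feature_names=fm.feature_names,
        step=config.rfecv_step, folds=config.rfecv_folds,
    )
    sel_idx = [fm.feature_names.index(f) for f in selected]
    X_train = X_train_all[:, sel_idx]
    X_test = X_test_all[:, sel_idx]

    truth = test_fm.strain_labels()
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_spectra": fm.n_spectra,
        "n_reference_peaks": len(refset),
        "selected_features": selected,
        "cv_curve": cv_curve,
        "pca_explained_variance": [float(v) for v in evr],
        "models": {},
    }
    per_model_calls = {}
    train_groups = train_fm.presence.index.get_level_values("strain_id").to_numpy()
    for kind in CLASSIFIER_KINDS:
        test_scores, model = fit_predict(kind, X_train, y_train, X_test, seed=config.seed)
        train_threshold = youden_threshold_cv(
            kind, X_train, y_train, groups=train_groups, seed=config.seed
        )
        test_eval = evaluate_scores(test_scores, y_test)
        test_eval.classifier_kind = kind
        test_eval.selected_features = selected
        test_eval.cv_curve = cv_curve
        test_eval.grouped_split = config.group_by_strain

        vote_thr = config.vote_threshold if config.vote_threshold is not None else train_threshold
        score_series = pd.Series(test_scores, index=test_fm.presence.index)
        calls = [
            vote_strain(grp.to_numpy(), vote_thr, strain_id=sid)
            for sid, grp in score_series.groupby(level="strain_id")
        ]
        confusion, accuracy, table = summarize_strain_calls(calls, truth)
        per_model_calls[kind] = table
        importances = permutation_importance(model, X_test, y_test, n_repeats=10, seed=config.seed)
        report["models"][kind] = {
            **test_eval.to_dict(),
            "train_threshold": train_threshold,
            "vote_threshold": vote_thr,
            "strain_confusion": confusion.tolist(),
            "strain_accuracy_pct": accuracy,
            "permutation_importance": {
                f: float(v) for f, v in zip(selected, importances)
            },
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(manifest, spectra, outdir)
        fm.to_csv(outdir / "features.csv")
        bt.to_csv(outdir / "biomarker_table.csv", index=False)
        heat.to_csv(outdir / "heatmap_matrix.csv")
        scores_pca.to_csv(outdir / "pca_scores.csv")
        if assignments is not None:
            assignments.to_csv(outdir / "assignments.csv", index=False)
        for kind, table in per_model_calls.items():
            table.to_csv(outdir / f"strain_calls_{kind}.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
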