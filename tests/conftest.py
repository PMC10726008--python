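"""Shared fixtures: small fast cohorts for unit tests, and one full-size
default cohort (session-scoped) for the recovery checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from maldisub.align import FeatureMatrix, build_reference_peaks, featurize
from maldisub.models import (
    CLASSIFIER_KINDS,
    SplitSpec,
    evaluate_scores,
    fit_predict,
    rfecv_select,
    scale_minmax,
    split_dataset,
    youden_threshold_cv,
)
from maldisub.pipeline import PipelineConfig, peaklists_from_spectra
from maldisub.screen import biomarker_table
from maldisub.simulate import SimConfig, simulate_cohort
from maldisub.voting import summarize_strain_calls, vote_strain


@pytest.fixture
def centroid_cohort():
    """Small, fast centroid-mode cohort (12 + 8 strains x 4 replicates)."""
    cfg = SimConfig(n_longum=12, n_infantis=8, mode="centroid", seed=7)
    manifest, spectra = simulate_cohort(cfg)
    return cfg, manifest, spectra


def make_feature_matrix(presence: np.ndarray, labels, rel_intensity=None,
                        replicates: int = 1) -> FeatureMatrix:
    """Hand-build a FeatureMatrix from a strains x features presence array,
    replicating each strain's row ``replicates`` times."""
    presence = np.asarray(presence)
    n_strains, n_feat = presence.shape
    if rel_intensity is None:
        rel_intensity = presence.astype(float)
    rel_intensity = np.asarray(rel_intensity, dtype=float)
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i:03d}", r) for i in range(n_strains) for r in range(replicates)],
        names=["strain_id", "replicate"],
    )
    pres_rows = np.repeat(presence, replicates, axis=0)
    rel_rows = np.repeat(rel_intensity, replicates, axis=0)
    cols = [str(3000 + 100 * j) for j in range(n_feat)]
    labels_rows = np.repeat(np.asarray(labels), replicates)
    return FeatureMatrix(
        pd.DataFrame(pres_rows, index=idx, columns=cols),
        pd.DataFrame(rel_rows, index=idx, columns=cols),
        pd.Series(labels_rows, index=idx, name="label"),
        np.array([3000.0 + 100 * j for j in range(n_feat)]),
    )


@pytest.fixture(scope="session")
def default_cohort_run():
    """Full default cohort (59+41 strains x 4 replicates, profile mode) taken
    through every stage once; shared by the recovery tests."""
    config = PipelineConfig(seed=1)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    manifest, spectra = simulate_cohort(sim_cfg)
    peaklists = peaklists_from_spectra(spectra, config)
    refset = build_reference_peaks(peaklists)
    fm = featurize(peaklists, refset, manifest)
    bt = biomarker_table(fm)

    train_fm, test_fm = split_dataset(fm, SplitSpec(seed=config.seed))
    X_tr, X_te, _ = scale_minmax(train_fm.rel_intensity, test_fm.rel_intensity)
    y_tr, y_te = train_fm.labels.to_numpy(), test_fm.labels.to_numpy()
    selected, cv_curve = rfecv_select(X_tr, y_tr, feature_names=fm.feature_names)
    idx = [fm.feature_names.index(f) for f in selected]
    groups = train_fm.presence.index.get_level_values("strain_id").to_numpy()
    truth = test_fm.strain_labels()
    models = {}
    for kind in CLASSIFIER_KINDS:
        scores, model = fit_predict(kind, X_tr[:, idx], y_tr, X_te[:, idx], seed=config.seed)
        thr = youden_threshold_cv(kind, X_tr[:, idx], y_tr, groups=groups, seed=config.seed)
        ev = evaluate_scores(scores, y_te)
        ss = pd.Series(scores, index=test_fm.presence.index)
        calls = [vote_strain(g.to_numpy(), thr, strain_id=s)
                 for s, g in ss.groupby(level="strain_id")]
        _conf, vote_acc, _table = summarize_strain_calls(calls, truth)
        models[kind] = {"eval": ev, "vote_accuracy_pct": vote_acc, "threshold": thr}
    return {
        "config": config,
        "sim": sim_cfg,
        "refset": refset,
        "fm": fm,
        "bt": bt,
        "selected": selected,
        "cv_curve": cv_curve,
        "models": models,
    }
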