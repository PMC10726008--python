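"""Univariate biomarker screening.

Per reference peak: strain-level presence frequencies in both subspecies,
a two-sided Fisher exact test on the 2x2 presence table, the
single-feature ROC AUC (infantis = positive class), and a
subspecies-specificity call. Also provides strain-level PCA scores and
the clustered binary heatmap matrix used for unsupervised inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from maldisub.align import FeatureMatrix

_TIE_REL_TOL = 1e-7  # relative tolerance when comparing hypergeometric masses


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities (margins fixed) of all
    tables whose probability does not exceed the observed one, with a 1e-7
    relative tolerance on the comparison. An all-zero table has p = 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers; {name} = {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 - (n_total - c1)), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n_total, c1, r1)
    p_obs = hypergeom.pmf(a, n_total, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(p, 1.0)


def feature_auc(values, labels) -> float:
    """Rank-based AUC of one feature, P(score_pos > score_neg) + 0.5 P(tie).

    Positive class is infantis (label 1). Raises when only one class is
    present.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("feature_auc needs both classes present in labels")
    return float(roc_auc_score(labels, values))


def biomarker_table(
    fm: FeatureMatrix,
    specific_hi: float = 0.95,
    specific_lo: float = 0.05,
) -> pd.DataFrame:
    """One row per reference peak with the screening statistics.

    Columns: ``ref_mz``, per-class strain counts and frequencies, two-sided
    Fisher p on the strain-level 2x2 presence table, single-feature AUC on
    strain-average relative intensity, and ``specific_to`` — the subspecies
    whose presence frequency is at least ``specific_hi`` while the other
    class stays at or below ``specific_lo`` (else "none"). The
    ``assignment`` column is empty until filled by the annotation step.
    """
    pres = fm.strain_presence()
    inten = fm.strain_intensity()
    strain_labels = fm.strain_labels().loc[pres.index]
    y = strain_labels.to_numpy()
    n_lon = int((y == 0).sum())
    n_inf = int((y == 1).sum())
    both_classes = n_lon > 0 and n_inf > 0
    rows = []
    for j, col in enumerate(pres.columns):
        p_col = pres[col].to_numpy()
        k_lon = int(p_col[y == 0].sum())
        k_inf = int(p_col[y == 1].sum())
        p_fisher = fisher_exact(k_lon, n_lon - k_lon, k_inf, n_inf - k_inf)
        f_lon = k_lon / n_lon if n_lon else 0.0
        f_inf = k_inf / n_inf if n_inf else 0.0
        vals = inten[col].to_numpy()
        auc = feature_auc(vals, y) if (both_classes and np.unique(vals).size > 1) else 0.5
        if f_lon >= specific_hi and f_inf <= specific_lo:
            specific = "longum"
        elif f_inf >= specific_hi and f_lon <= specific_lo:
            specific = "infantis"
        else:
            specific = "none"
        rows.append(
            {
                "ref_mz": float(fm.ref_mz[j]),
                "feature": col,
                "n_longum_present": k_lon,
                "n_longum_total": n_lon,
                "n_infantis_present": k_inf,
                "n_infantis_total": n_inf,
                "freq_longum": f_lon,
                "freq_infantis": f_inf,
                "fisher_p": p_fisher,
                "auc": auc,
                "specific_to": specific,
                "assignment": "",
            }
        )
    return pd.DataFrame(rows)


def pca_scores(fm: FeatureMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Strain-level 2-D PCA of the average relative-intensity fingerprints.

    Each strain contributes its replicate-average feature vector; columns
    are mean-centered and projected on the top-2 right singular vectors.
    Returns (scores indexed by strain with columns PC1/PC2, explained
    variance fractions, non-increasing).
    """
    inten = fm.strain_intensity()
    if len(inten) < 3:
        raise ValueError("pca_scores needs at least 3 strains")
    n_comp = min(2, inten.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(inten.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(scores, index=inten.index, columns=cols), pca.explained_variance_ratio_


def heatmap_matrix(bt: pd.DataFrame, fm: FeatureMatrix) -> pd.DataFrame:
    """Binary strain x peak matrix for the top half of peaks by Fisher p.

    Keeps the 50% of reference peaks with the smallest Fisher p, then orders
    strains (rows) and peaks (columns) by average-linkage agglomerative
    clustering on Hamming distance.
    """
    k = max(1, int(round(0.5 * len(bt))))
    kept = bt.nsmallest(k, "fisher_p", keep="first")["feature"].tolist()
    mat = fm.strain_presence()[kept]
    arr = mat.to_numpy()
    row_order = np.arange(arr.shape[0])
    col_order = np.arange(arr.shape[1])
    if arr.shape[0] > 2:
        row_order = leaves_list(linkage(arr, method="average", metric="hamming"))
    if arr.shape[1] > 2:
        col_order = leaves_list(linkage(arr.T, method="average", metric="hamming"))
    return mat.iloc[row_order, col_order]
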