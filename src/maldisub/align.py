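"""Cohort-level peak alignment and feature-matrix construction.

Peaks pooled across all spectra are clustered by single linkage with a
ppm gap threshold; each cluster becomes one reference peak (at the
arithmetic mean of its members). Spectra are then featurized against the
reference set: presence (a peak within tolerance of the reference) and
relative intensity (peak intensity over the spectrum's base peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from maldisub.preprocess import PeakList


@dataclass
class ReferencePeakSet:
    """Consensus peak positions for a cohort.

    ``ref_mz`` ascending; adjacent references are separated by more than the
    clustering tolerance. ``support`` counts the spectra contributing at
    least one peak to each cluster.
    """

    ref_mz: np.ndarray
    support: np.ndarray
    tol_ppm: float

    def __post_init__(self) -> None:
        self.ref_mz = np.asarray(self.ref_mz, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.ref_mz.size > 1 and not np.all(np.diff(self.ref_mz) > 0):
            raise ValueError("ref_mz must be strictly ascending")

    def __len__(self) -> int:
        return self.ref_mz.size

    def column_names(self) -> list[str]:
        """Reference peaks named by rounded integer Da (the field convention)."""
        names = [str(int(round(m))) for m in self.ref_mz]
        seen: dict[str, int] = {}
        out = []
        for n in names:
            if n in seen:
                seen[n] += 1
                out.append(f"{n}.{seen[n]}")
            else:
                seen[n] = 0
                out.append(n)
        return out


@dataclass
class FeatureMatrix:
    """Spectra x reference-peaks matrix with labels.

    ``presence`` is binary; ``rel_intensity`` holds the matched peak's
    intensity divided by the spectrum's base-peak intensity (0 where absent).
    Rows are indexed by (strain_id, replicate).
    """

    presence: pd.DataFrame
    rel_intensity: pd.DataFrame
    labels: pd.Series  # per row, aligned with presence.index
    ref_mz: np.ndarray

    def __post_init__(self) -> None:
        if not self.presence.index.equals(self.rel_intensity.index):
            raise ValueError("presence and rel_intensity must share a row index")
        if ((self.presence.to_numpy() == 0) & (self.rel_intensity.to_numpy() != 0)).any():
            raise ValueError("rel_intensity must be 0 wherever presence is 0")

    @property
    def n_spectra(self) -> int:
        return len(self.presence)

    @property
    def feature_names(self) -> list[str]:
        return list(self.presence.columns)

    def strain_labels(self) -> pd.Series:
        """Ground-truth label per strain."""
        return self.labels.groupby(level="strain_id").first()

    def strain_presence(self) -> pd.DataFrame:
        """Strain-level presence: a peak counts as present in a strain when it
        is detected in at least half of the strain's replicates."""
        counts = self.presence.groupby(level="strain_id").mean()
        return (counts >= 0.5).astype(int)

    def strain_intensity(self) -> pd.DataFrame:
        """Strain-average relative intensity per reference peak."""
        return self.rel_intensity.groupby(level="strain_id").mean()

    def subset_strains(self, strain_ids) -> "FeatureMatrix":
        mask = self.presence.index.get_level_values("strain_id").isin(set(strain_ids))
        return FeatureMatrix(
            self.presence.loc[mask],
            self.rel_intensity.loc[mask],
            self.labels.loc[mask],
            self.ref_mz,
        )

    def subset_rows(self, row_mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.presence.loc[row_mask],
            self.rel_intensity.loc[row_mask],
            self.labels.loc[row_mask],
            self.ref_mz,
        )

    def to_csv(self, path) -> None:
        """Serialize relative intensities (presence = value > 0) with labels."""
        df = self.rel_intensity.copy()
        df.columns = [f"{m:.4f}" for m in self.ref_mz]
        df.insert(0, "label", self.labels.to_numpy())
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=[0, 1])
        df.index.names = ["strain_id", "replicate"]
        labels = df.pop("label").astype(int)
        ref_mz = np.array([float(c) for c in df.columns])
        rel = df.astype(float)
        names = ReferencePeakSet(ref_mz, np.zeros(ref_mz.size, int), 0.0).column_names()
        rel.columns = names
        presence = (rel > 0).astype(int)
        return cls(presence, rel, labels, ref_mz)


def build_reference_peaks(
    all_peaklists: list[PeakList],
    tol_ppm: float = 500.0,
    min_support_frac: float = 0.05,
) -> ReferencePeakSet:
    """Cluster pooled peaks into cohort reference peaks.

    Single-linkage clustering of the pooled, sorted m/z list with a gap
    threshold of ``tol_ppm``; the reference position is the arithmetic mean
    of cluster members. Clusters supported by fewer than
    ``min_support_frac`` of the spectra are dropped as noise.
    """
    if not all_peaklists:
        raise ValueError("build_reference_peaks needs at least one peak list")
    n_spectra = len(all_peaklists)
    mz = np.concatenate([p.mz for p in all_peaklists]) if any(len(p) for p in all_peaklists) else np.empty(0)
    spec_idx = np.concatenate(
        [np.full(len(p), i) for i, p in enumerate(all_peaklists)]
    ) if mz.size else np.empty(0, int)
    if mz.size == 0:
        return ReferencePeakSet(np.empty(0), np.empty(0, int), tol_ppm)
    order = np.argsort(mz, kind="stable")
    mz, spec_idx = mz[order], spec_idx[order]
    gaps = np.diff(mz)
    breaks = np.nonzero(gaps > tol_ppm * 1e-6 * 0.5 * (mz[:-1] + mz[1:]))[0] + 1
    groups = np.split(np.arange(mz.size), breaks)
    ref, support = [], []
    min_support = min_support_frac * n_spectra
    for g in groups:
        n_sup = np.unique(spec_idx[g]).size
        if n_sup >= min_support:
            ref.append(float(mz[g].mean()))
            support.append(n_sup)
    return ReferencePeakSet(np.asarray(ref), np.asarray(support, int), tol_ppm)


def featurize(
    all_peaklists: list[PeakList],
    refset: ReferencePeakSet,
    manifest: pd.DataFrame,
) -> FeatureMatrix:
    """Build the spectra x reference-peaks presence / relative-intensity matrix.

    A spectrum's peak matches reference j when it lies within the reference
    set's tolerance of ``ref_mz[j]``; when several peaks of one spectrum
    qualify, the nearest in m/z wins. Relative intensity is the matched
    peak's intensity divided by the spectrum's base-peak intensity. Labels
    are joined from the manifest on (strain_id, replicate).
    """
    required = {"strain_id", "label", "replicate"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    label_map = {
        (r.strain_id, int(r.replicate)): int(r.label) for r in manifest.itertuples()
    }
    missing = [
        (p.strain_id, p.replicate)
        for p in all_peaklists
        if (p.strain_id, p.replicate) not in label_map
    ]
    if missing:
        raise ValueError(f"manifest is missing rows for spectra: {missing[:5]}")

    names = refset.column_names()
    n_ref = len(refset)
    pres = np.zeros((len(all_peaklists), n_ref), dtype=int)
    rel = np.zeros((len(all_peaklists), n_ref), dtype=float)
    index = []
    labels = []
    for i, p in enumerate(all_peaklists):
        index.append((p.strain_id, p.replicate))
        labels.append(label_map[(p.strain_id, p.replicate)])
        if len(p) == 0:
            continue
        base = p.intensity.max()
        for j, rmz in enumerate(refset.ref_mz):
            tol = refset.tol_ppm * 1e-6 * rmz
            lo = np.searchsorted(p.mz, rmz - tol)
            hi = np.searchsorted(p.mz, rmz + tol)
            if hi > lo:
                k = lo + int(np.argmin(np.abs(p.mz[lo:hi] - rmz)))
                pres[i, j] = 1
                rel[i, j] = p.intensity[k] / base if base > 0 else 0.0
    idx = pd.MultiIndex.from_tuples(index, names=["strain_id", "replicate"])
    return FeatureMatrix(
        pd.DataFrame(pres, index=idx, columns=names),
        pd.DataFrame(rel, index=idx, columns=names),
        pd.Series(labels, index=idx, name="label"),
        refset.ref_mz.copy(),
    )
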