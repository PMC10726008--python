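"""Simulate a two-subspecies MALDI-TOF cohort and write it to disk.

Each of the 100 strains (59 B. longum, 41 B. infantis) carries each of the
18 discriminatory marker peaks by a strain-level Bernoulli draw at that
marker's published presence frequency, plus 30 backbone peaks shared by
everyone; four replicate spectra per strain with mass jitter and intensity
variation.
"""

from maldisub import SimConfig, simulate_cohort, write_cohort

config = SimConfig(mode="centroid", seed=1)
manifest, spectra = simulate_cohort(config)
manifest = write_cohort(manifest, spectra, "scratch/example_cohort")

n_strains = manifest["strain_id"].nunique()
print(f"{len(spectra)} spectra from {n_strains} strains "
      f"({(manifest.groupby('strain_id')['label'].first() == 0).sum()} longum, "
      f"{(manifest.groupby('strain_id')['label'].first() == 1).sum()} infantis)")
print(f"replicates per strain: {manifest.groupby('strain_id').size().iloc[0]}")
s = spectra[0]
print(f"first spectrum: {len(s)} peaks in [{s.mz.min():.0f}, {s.mz.max():.0f}] Da")
# ~48 sticks per spectrum: 30 backbone peaks plus the markers this strain carries
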