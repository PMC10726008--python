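"""Subspecies-discriminatory marker peaks and their published presence frequencies.

The default marker table lists the 18 peaks that discriminate
*B. longum* subsp. *longum* from subsp. *infantis* in linear-mode
MALDI-TOF fingerprints, with the strain-level presence frequency of each
peak in either subspecies (fractions of 59 longum and 41 infantis
strains), the theoretical [M+H]+ of the best-matching protein, and the
protein assignment. These frequencies parameterize the synthetic-cohort
generator and anchor the biomarker-screening tests.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MarkerDef:
    """One discriminatory peak: nominal position and per-class presence probabilities.

    Parameters
    ----------
    mz_true : float
        Nominal [M+H]+ position in Da; must lie in the acquired 2-20 kDa window.
    p_longum, p_infantis : float
        Strain-level probability that a strain of the given subspecies
        carries the peak.
    mean_rel_intensity : float
        Mean peak amplitude in arbitrary units (> 0).
    theoretical_mz : float | None
        Theoretical [M+H]+ of the assigned protein, if known.
    protein : str | None
        Free-text protein assignment, if known.
    """

    mz_true: float
    p_longum: float
    p_infantis: float
    mean_rel_intensity: float = 1.0
    theoretical_mz: float | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_longum <= 1.0 and 0.0 <= self.p_infantis <= 1.0):
            raise ValueError(
                f"presence probabilities must lie in [0, 1]; got "
                f"p_longum={self.p_longum}, p_infantis={self.p_infantis}"
            )
        if not (2000.0 <= self.mz_true <= 20000.0):
            raise ValueError(f"mz_true must lie in [2000, 20000] Da; got {self.mz_true}")
        if self.mean_rel_intensity <= 0:
            raise ValueError(f"mean_rel_intensity must be > 0; got {self.mean_rel_intensity}")


# (m/z, present longum strains / 59, present infantis strains / 41,
#  theoretical [M+H]+, protein assignment)
_MARKER_ROWS: list[tuple[int, int, int, int, str]] = [
    (2929, 46, 3, 2932, "Hypothetical protein"),
    (3088, 14, 34, 3088, "NAD(P)-binding domain-containing protein"),
    (3152, 41, 5, 3150, "Integrase partial"),
    (3573, 18, 39, 3573, "Restriction endonuclease"),
    (4408, 0, 39, 4406, "30S ribosomal protein S5 partial"),
    (4448, 33, 12, 4447, "50S ribosomal protein L9 partial"),
    (4479, 44, 8, 4480, "DUF600 family protein partial"),
    (5338, 4, 33, 5338, "Permease"),
    (5381, 6, 41, 5377, "50S ribosomal"),
    (5394, 48, 0, 5391, "Protein L34"),
    (6820, 17, 32, 6822, "Transporter drug/metabolite exporter family"),
    (6910, 23, 40, 6910, "Transposase"),
    (7051, 40, 6, 7051, "50S ribosomal protein L30"),
    (8131, 0, 26, 8135, "IS3 family transposase partial"),
    (8817, 8, 36, 8816, "50S ribosomal protein L27"),
    (8789, 47, 1, 8789, "DUF905 domain-containing protein"),
    (9963, 17, 38, 9963, "DUF4244 domain-containing protein"),
    (10360, 18, 38, 10364, "50S ribosomal protein L13 partial"),
]

N_LONGUM_STRAINS = 59
N_INFANTIS_STRAINS = 41

#: The five peaks retained by recursive feature elimination as the optimal
#: discriminatory set (2,929 and 5,394 specific to longum; the rest to infantis).
SELECTED_PEAKS: tuple[int, ...] = (2929, 4408, 5381, 5394, 8817)


def default_marker_table() -> list[MarkerDef]:
    """Return the 18 published discriminatory peaks as :class:`MarkerDef` rows.

    Presence frequencies are exact strain-count fractions (n/59 and n/41).
    """
    return [
        MarkerDef(
            mz_true=float(mz),
            p_longum=n_lon / N_LONGUM_STRAINS,
            p_infantis=n_inf / N_INFANTIS_STRAINS,
            mean_rel_intensity=1.0,
            theoretical_mz=float(theo),
            protein=protein,
        )
        for mz, n_lon, n_inf, theo, protein in _MARKER_ROWS
    ]


def marker_counts() -> list[tuple[int, int, int, int, int]]:
    """Published strain counts per marker: (mz, present_longum, absent_longum, present_infantis, absent_infantis)."""
    return [
        (mz, n_lon, N_LONGUM_STRAINS - n_lon, n_inf, N_INFANTIS_STRAINS - n_inf)
        for mz, n_lon, n_inf, _theo, _prot in _MARKER_ROWS
    ]


def marker_mass_pairs() -> list[tuple[float, float]]:
    """(experimental m/z, theoretical m/z) for each of the 18 markers."""
    return [(float(mz), float(theo)) for mz, _l, _i, theo, _p in _MARKER_ROWS]
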