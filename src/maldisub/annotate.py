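"""Peak-to-protein annotation via theoretical average masses.

Average molecular weights are computed from amino-acid sequences, and each
reference peak is matched to candidate proteins whose singly protonated
ion ([M+H]+ = average mass + 1.008) lies within a Dalton tolerance.
Because ribosomal proteins frequently lose their N-terminal methionine
in vivo, Met-loss variants are generated as additional candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

WATER_MASS = 18.0153
PROTON_MASS = 1.008
MET_RESIDUE_MASS = 131.1926  # average mass removed by N-terminal Met cleavage

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def average_mass(sequence: str) -> float:
    """Average (isotope-abundance weighted) molecular mass of a protein, in Da.

    Sum of standard average residue masses plus one water. Raises on an
    empty sequence or any non-standard letter, naming the offending symbol
    and its position.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _STANDARD_AA:
            raise ValueError(
                f"non-standard amino acid {ch!r} at position {i} (0-based) in sequence"
            )
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


@dataclass
class ProteinRecord:
    """A candidate protein with its computed average mass."""

    id: str
    sequence: str
    description: str = ""
    avg_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.avg_mass == 0.0:
            self.avg_mass = average_mass(self.sequence)
        if self.avg_mass <= 0:
            raise ValueError(f"avg_mass must be > 0; got {self.avg_mass}")


@dataclass(frozen=True)
class PeakAssignment:
    """One candidate protein for one reference peak."""

    ref_mz: float
    protein_id: str
    theoretical_mz: float  # [M+H]+ of the (possibly Met-cleaved) species
    delta: float  # observed - theoretical
    variant: str  # "intact" or "met-loss"
    primary: bool  # nearest candidate for this peak


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read protein records from FASTA (standard 20-letter alphabet)."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def match_peaks_to_proteins(
    refset,
    proteins: list[ProteinRecord],
    tol_da: float = 5.0,
) -> list[PeakAssignment]:
    """Match reference peaks to proteins by [M+H]+ within ``tol_da``.

    All candidates within tolerance are reported per peak, ordered by
    |observed - theoretical|; the nearest is flagged ``primary``. For each
    protein starting with Met, an additional Met-loss candidate is
    considered. An empty protein list yields an empty result.
    """
    candidates: list[tuple[str, float, str]] = []
    for prot in proteins:
        candidates.append((prot.id, prot.avg_mass + PROTON_MASS, "intact"))
        if prot.sequence[:1].upper() == "M":
            candidates.append((prot.id, prot.avg_mass - MET_RESIDUE_MASS + PROTON_MASS, "met-loss"))
    out: list[PeakAssignment] = []
    for rmz in refset.ref_mz:
        hits = [
            (abs(rmz - theo), pid, theo, variant)
            for pid, theo, variant in candidates
            if abs(rmz - theo) <= tol_da
        ]
        hits.sort(key=lambda h: (h[0], h[1], h[3]))
        for k, (_d, pid, theo, variant) in enumerate(hits):
            out.append(
                PeakAssignment(
                    ref_mz=float(rmz),
                    protein_id=pid,
                    theoretical_mz=float(theo),
                    delta=float(rmz - theo),
                    variant=variant,
                    primary=(k == 0),
                )
            )
    return out


def assignments_to_frame(assignments: list[PeakAssignment]) -> pd.DataFrame:
    """Tabulate assignments (ref_mz, protein_id, theoretical_mz, delta, variant, primary)."""
    return pd.DataFrame(
        [
            {
                "ref_mz": a.ref_mz,
                "protein_id": a.protein_id,
                "theoretical_mz": a.theoretical_mz,
                "delta": a.delta,
                "variant": a.variant,
                "primary": a.primary,
            }
            for a in assignments
        ],
        columns=["ref_mz", "protein_id", "theoretical_mz", "delta", "variant", "primary"],
    )
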