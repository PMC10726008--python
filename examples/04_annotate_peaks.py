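"""Assign reference peaks to candidate proteins by average [M+H]+ mass.

Uses a small synthetic protein set (sequences invented for the demo, not
the organisms' real proteins) to show mass computation, tolerance
matching, and N-terminal Met-loss variants.
"""

import numpy as np

from maldisub import ProteinRecord, average_mass, match_peaks_to_proteins
from maldisub.align import ReferencePeakSet
from maldisub.annotate import assignments_to_frame

# synthetic stand-ins: sequences chosen only for their masses
proteins = [
    ProteinRecord(id="demo_L34", sequence="MKRTYQPSKLVRARRHGFRARMATKNGRKVLARRRAKGRKSLSA"),
    ProteinRecord(id="demo_small", sequence="MAGNTSAKGDEW"),
]
for p in proteins:
    print(f"{p.id}: {len(p.sequence)} aa, average mass {p.avg_mass:.2f} Da, "
          f"[M+H]+ {p.avg_mass + 1.008:.2f}")

# pretend the cohort produced reference peaks near these masses
refset = ReferencePeakSet(
    np.sort([proteins[0].avg_mass + 1.008 + 2.0,  # 2 Da high: within tolerance
             proteins[1].avg_mass - 131.1926 + 1.008]),  # matches the Met-loss form
    np.array([40, 40]),
    500.0,
)
assignments = match_peaks_to_proteins(refset, proteins, tol_da=5.0)
print()
print(assignments_to_frame(assignments).to_string(index=False))
print("\ndelta = observed - theoretical; 'met-loss' marks the Met-cleaved form.")
print("GG dipeptide average mass check:", round(average_mass("GG"), 2), "Da")
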