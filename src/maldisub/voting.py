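"""Replicate-vote strain identification.

Each strain contributes several replicate spectra; every replicate is
called by thresholding its classifier score and the strain-level call is
the majority. An exact tie falls back to the mean score against the same
threshold (flagged). The summary reports the 2x2 strain-level confusion
matrix and accuracy in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StrainCall:
    """Aggregated subspecies call for one strain."""

    strain_id: str
    replicate_scores: list[float]
    replicate_calls: list[int]
    mean_score: float
    final_call: int
    tie_broken: bool


def vote_strain(replicate_scores, threshold: float, strain_id: str = "") -> StrainCall:
    """Majority vote over replicate calls, mean-score tie-break.

    Each replicate is called infantis (1) when its score >= threshold; the
    final call is the majority. On an exact tie the strain is called
    infantis iff the mean replicate score >= threshold, and ``tie_broken``
    is set.
    """
    scores = [float(s) for s in replicate_scores]
    if not scores:
        raise ValueError("vote_strain needs at least one replicate score")
    calls = [1 if s >= threshold else 0 for s in scores]
    mean_score = float(np.mean(scores))
    ones = sum(calls)
    zeros = len(calls) - ones
    if ones > zeros:
        final, tie = 1, False
    elif zeros > ones:
        final, tie = 0, False
    else:
        final, tie = (1 if mean_score >= threshold else 0), True
    return StrainCall(strain_id, scores, calls, mean_score, final, tie)


def summarize_strain_calls(
    calls: list[StrainCall],
    truth: dict[str, int] | pd.Series,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Confusion matrix and accuracy of strain-level calls against ground truth.

    Returns (confusion, accuracy, table): confusion[i, j] counts strains of
    true class i called j (0 = longum, 1 = infantis); accuracy is
    correct/n in percent, rounded to two decimals; the table lists one row
    per strain with scores, calls, truth and a correctness flag.
    """
    truth = dict(truth)
    missing = [c.strain_id for c in calls if c.strain_id not in truth]
    if missing:
        raise ValueError(f"missing ground-truth label for strains: {missing}")
    confusion = np.zeros((2, 2), dtype=int)
    rows = []
    for c in calls:
        t = int(truth[c.strain_id])
        confusion[t, c.final_call] += 1
        rows.append(
            {
                "strain_id": c.strain_id,
                "scores": ";".join(f"{s:.4f}" for s in c.replicate_scores),
                "mean_score": c.mean_score,
                "final_call": c.final_call,
                "truth": t,
                "correct": c.final_call == t,
                "tie_broken": c.tie_broken,
            }
        )
    n = len(calls)
    accuracy = round(100.0 * (confusion[0, 0] + confusion[1, 1]) / n, 2) if n else 0.0
    return confusion, accuracy, pd.DataFrame(rows)
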