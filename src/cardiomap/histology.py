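"""Semiquantitative histopathology scoring emulation.

Implements the blinded ordinal rubrics used to grade cardiac damage:

* a global macroscopic hemorrhage score 0-4 driven by the fraction of the
  heart surface covered by lesions (0: none; 1: <10%; 2: 10-30%; 3: 30-50%;
  4: >50%);
* per-segment 0-3 scores (none / mild / moderate / severe) for immune-cell
  infiltration, fibrosis, red-blood-cell extravasation and iron deposition,
  derived here from phantom ground-truth severity fields through configurable
  cutpoints, with optional inter-observer scorer noise.

Scores are produced for 12 segments per mid-ventricular slice across a
configurable number of cross-sections (default 4) and aggregated by the
per-segment mean across sections, rounded back to the ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import PhantomGroundTruth, lesion_surface_fraction
from .segmentation import SegmentLabelMap

__all__ = [
    "DEFAULT_CUTPOINTS",
    "SCORE_PARAMETERS",
    "HistologyScoreSet",
    "score_macroscopic",
    "score_ordinal",
    "derive_histology_scores",
]

#: Severity thresholds mapping a 0-1 quantity onto mild/moderate/severe.
DEFAULT_CUTPOINTS = (0.05, 0.35, 0.65)

#: Damage parameters scored per segment, in table column order.
SCORE_PARAMETERS = ("infiltration", "fibrosis", "rbc", "iron")


def score_macroscopic(fraction: float) -> int:
    """Macroscopic hemorrhage rubric: lesion-covered surface fraction -> 0-4.

    Boundary handling: [0.10, 0.30) -> 2, [0.30, 0.50] -> 3, (0.50, 1] -> 4.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"surface fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0:
        return 0
    if fraction < 0.10:
        return 1
    if fraction < 0.30:
        return 2
    if fraction <= 0.50:
        return 3
    return 4


def score_ordinal(quantity: float, cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS) -> int:
    """Count how many severity cutpoints the 0-1 quantity reaches (0-3)."""
    if len(cutpoints) != 3 or not (0 < cutpoints[0] < cutpoints[1] < cutpoints[2] < 1):
        raise ValueError("cutpoints must be 3 strictly increasing values in (0, 1)")
    if not (0.0 <= quantity <= 1.0):
        raise ValueError(f"quantity must be in [0, 1], got {quantity}")
    return int(sum(quantity >= c for c in cutpoints))


@dataclass
class HistologyScoreSet:
    """Per-segment ordinal scores plus the global macroscopic score.

    ``scores`` has one row per segment with integer 0-3 columns for each
    damage parameter; ``macroscopic`` is the 0-4 surface rubric result.
    """

    scores: pd.DataFrame
    macroscopic: int
    n_sections: int = 4
    scorer_seed: int = 0

    def __post_init__(self) -> None:
        required = {"segment_id", "name", *SCORE_PARAMETERS}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        for p in SCORE_PARAMETERS:
            col = self.scores[p]
            if not ((col >= 0) & (col <= 3)).all():
                raise ValueError(f"{p} scores out of the 0-3 range")
        if not (0 <= self.macroscopic <= 4):
            raise ValueError("macroscopic score out of the 0-4 range")


def _segment_severity(field: np.ndarray, labels: np.ndarray, seg_id: int) -> float:
    sel = labels == seg_id
    if not sel.any():
        raise ValueError(f"segment {seg_id} has no pixels in the labelmap")
    return float(np.clip(field[sel].mean(), 0.0, 1.0))


def derive_histology_scores(
    phantom: PhantomGroundTruth,
    labelmap: SegmentLabelMap,
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS,
    scorer_noise_p: float = 0.0,
    seed: int = 0,
    n_sections: int = 4,
    iron_reference: float = 1.0,
) -> HistologyScoreSet:
    """Blinded-scorer emulation: phantom truth -> per-segment ordinal scores.

    Per segment and damage parameter, severity is the mean of the matching
    ground-truth field over the segment's pixels (iron concentration is
    rescaled by ``iron_reference`` and clipped to [0, 1]). Each of the
    ``n_sections`` cross-sections is scored through :func:`score_ordinal`;
    with probability ``scorer_noise_p`` a section's score is perturbed by
    +/-1 (clipped to 0-3), emulating inter-observer variation. Section
    scores are aggregated by their mean, rounded to the nearest integer.
    Deterministic for a fixed seed.
    """
    if not (0.0 <= scorer_noise_p <= 1.0):
        raise ValueError("scorer_noise_p must be in [0, 1]")
    fields = {
        "infiltration": phantom.infiltration_map,
        "fibrosis": phantom.fibrosis_map,
        "rbc": phantom.rbc_map,
        "iron": np.clip(phantom.iron_map / iron_reference, 0.0, 1.0),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for seg_id in sorted(labelmap.names):
        row: dict = {"segment_id": seg_id, "name": labelmap.names[seg_id]}
        for param in SCORE_PARAMETERS:
            severity = _segment_severity(fields[param], labelmap.labels, seg_id)
            base = score_ordinal(severity, cutpoints)
            section_scores = np.full(n_sections, base)
            if scorer_noise_p > 0:
                flip = rng.random(n_sections) < scorer_noise_p
                delta = rng.choice((-1, 1), size=n_sections)
                section_scores = np.clip(section_scores + flip * delta, 0, 3)
            row[param] = int(np.rint(section_scores.mean()))
        rows.append(row)
    scores = pd.DataFrame(rows, columns=["segment_id", "name", *SCORE_PARAMETERS])
    macro = score_macroscopic(lesion_surface_fraction(phantom))
    return HistologyScoreSet(
        scores=scores, macroscopic=macro, n_sections=n_sections, scorer_seed=seed,
    )
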