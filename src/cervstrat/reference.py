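"""Reference constants of the cervical tumor single-cell atlas the
pipeline defaults emulate, plus small composition arithmetic helpers."""

from __future__ import annotations

import math
from typing import Mapping

#: Reported per-cell-type counts of the cervical atlas (tumor + NAT, post-QC).
ATLAS_CELL_TYPE_COUNTS: dict[str, int] = {
    "epithelial": 20547,
    "endothelial": 8617,
    "fibroblast": 15304,
    "smooth_muscle": 7429,
    "lymphocyte": 4490,
    "macrophage": 571,
    "neutrophil": 741,
}

#: Reported total cell count after quality filtering.  Note the per-type
#: counts sum to 30 more; percentages are conventionally taken over this
#: reported denominator.
ATLAS_TOTAL_CELLS: int = 57669

#: The fold-change encoded by the default marker threshold |log2fc| > 0.585.
MARKER_FOLD_CHANGE: float = 1.5


def composition_percentages(
    counts: Mapping[str, int] | None = None, total: int | None = None, ndigits: int = 1
) -> dict[str, float]:
    """Per-type percentage of ``total``, rounded to ``ndigits`` decimals."""
    counts = ATLAS_CELL_TYPE_COUNTS if counts is None else counts
    total = ATLAS_TOTAL_CELLS if total is None else total
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


def marker_threshold_log2fc(fold_change: float = MARKER_FOLD_CHANGE) -> float:
    """The |log2 fold change| threshold corresponding to a linear fold change."""
    return math.log2(fold_change)
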