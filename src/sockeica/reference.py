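"""Reference cohort classification counts.

Per-subject (total ICA components, components classified artifact) from
the 14-subject reference EEG-fMRI cohort. These printed counts serve as
inputs for arithmetic consistency checks of the rejected-fraction
bookkeeping; the raw imaging data itself is not distributed.
"""

from __future__ import annotations

import math

# subject id -> (n_components, n_artifact)
COHORT_COMPONENT_COUNTS: dict[int, tuple[int, int]] = {
    1: (97, 43),
    2: (75, 29),
    3: (81, 31),
    4: (105, 45),
    5: (57, 30),
    6: (122, 50),
    7: (80, 29),
    8: (161, 56),
    9: (154, 51),
    10: (108, 49),
    11: (285, 78),
    12: (99, 44),
    13: (120, 50),
    14: (106, 44),
}


def rejected_percentage(n_components: int, n_artifact: int) -> int:
    """Percentage of components rejected, rounded to the nearest integer."""
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if not 0 <= n_artifact <= n_components:
        raise ValueError("n_artifact must be in [0, n_components]")
    return int(math.floor(100.0 * n_artifact / n_components + 0.5))


def cohort_rejected_percentages(
    counts: dict[int, tuple[int, int]] | None = None,
) -> dict[int, int]:
    """Per-subject rejected percentages for a counts table."""
    counts = COHORT_COMPONENT_COUNTS if counts is None else counts
    return {
        sid: rejected_percentage(total, artifact)
        for sid, (total, artifact) in counts.items()
    }
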