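"""Segmentation-quality metrics: Dice overlap, mutual information, error rate.

All metrics compare a test mask ``St`` against a ground-truth mask ``Sg``
of the same shape.  Mutual information is computed on the joint
distribution of the two binary pixel labels, in bits.  Because "overall
error rate" admits more than one reading, both the union-normalized
disagreement (1 - Jaccard) and the whole-image disagreement fraction are
exposed under separate names; the former is the default.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice", "mutual_information", "overall_error_rate", "pixel_error_rate", "evaluate_masks"]


def _as_pair(sg, st) -> tuple[np.ndarray, np.ndarray]:
    sg = np.asarray(sg, dtype=bool)
    st = np.asarray(st, dtype=bool)
    if sg.shape != st.shape:
        raise ValueError(f"mask shapes differ: {sg.shape} vs {st.shape}")
    return sg, st


def dice(sg, st) -> float:
    """Dice overlap 2|Sg ∩ St| / (|Sg| + |St|); 1.0 when both masks are empty."""
    sg, st = _as_pair(sg, st)
    denom = int(sg.sum()) + int(st.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((sg & st).sum()) / denom


def mutual_information(sg, st) -> float:
    """Mutual information (bits) between the two binary pixel labelings."""
    sg, st = _as_pair(sg, st)
    n = sg.size
    mi = 0.0
    for a in (False, True):
        pa = int((sg == a).sum()) / n
        if pa == 0:
            continue
        for b in (False, True):
            pb = int((st == b).sum()) / n
            pab = int(((sg == a) & (st == b)).sum()) / n
            if pab > 0 and pb > 0:
                mi += pab * np.log2(pab / (pa * pb))
    return max(float(mi), 0.0)


def overall_error_rate(sg, st) -> float:
    """Disagreeing pixels over the union of the two foregrounds (1 - Jaccard).

    0 for identical masks, 1 for disjoint nonempty masks; 0 when both are
    empty.
    """
    sg, st = _as_pair(sg, st)
    union = int((sg | st).sum())
    if union == 0:
        return 0.0
    return int((sg ^ st).sum()) / union


def pixel_error_rate(sg, st) -> float:
    """Whole-image disagreement fraction |Sg xor St| / n_pixels."""
    sg, st = _as_pair(sg, st)
    return int((sg ^ st).sum()) / sg.size


def evaluate_masks(sg, st) -> dict[str, float]:
    """All metrics at once, as emitted by the ``evaluate-seg`` command."""
    return {
        "dice": dice(sg, st),
        "mi_bits": mutual_information(sg, st),
        "overall_error": overall_error_rate(sg, st),
        "pixel_error": pixel_error_rate(sg, st),
    }
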