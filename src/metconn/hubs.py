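"""Hub identification and the lost / preserved / reconfigured taxonomy.

A hub is a node whose centrality strictly exceeds the network mean by one
standard deviation (sample sd).  Comparing hub sets between a control-like
group and a target group partitions nodes into:

* ``lost`` — hub in control only,
* ``preserved`` — hub in both,
* ``reconfigured`` — hub in target only,
* ``non-hub`` — hub in neither.

The default centrality criterion is degree; the participation coefficient
is available as an alternative criterion upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("lost", "preserved", "reconfigured", "non-hub")


def identify_hubs(criterion: np.ndarray, sd_multiplier: float = 1.0) -> np.ndarray:
    """Flag nodes whose criterion exceeds mean + sd_multiplier * sample sd.

    Strict inequality; a constant criterion vector therefore yields no
    hubs (sd = 0 and nothing strictly exceeds the mean).
    """
    criterion = np.asarray(criterion, dtype=float)
    if criterion.ndim != 1 or criterion.size < 3:
        raise ValueError("criterion must be a vector of length >= 3")
    if not np.isfinite(criterion).all():
        raise ValueError("criterion contains non-finite values")
    thr = criterion.mean() + sd_multiplier * criterion.std(ddof=1)
    return criterion > thr


@dataclass
class HubTaxonomy:
    """Per-ROI hub status in two groups and the resulting category."""

    roi_labels: list
    hub_in_control: np.ndarray
    hub_in_target: np.ndarray
    category: np.ndarray  # strings from CATEGORIES
    criterion_control: np.ndarray | None = None
    criterion_target: np.ndarray | None = None
    context: str = ""  # e.g. "degree AUC over densities 0.10-0.40"
    counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "roi": self.roi_labels,
                "hub_control": self.hub_in_control,
                "hub_target": self.hub_in_target,
                "category": self.category,
            }
        )
        if self.criterion_control is not None:
            df["criterion_control"] = self.criterion_control
        if self.criterion_target is not None:
            df["criterion_target"] = self.criterion_target
        return df


def classify_hubs(
    hubs_control: np.ndarray,
    hubs_target: np.ndarray,
    roi_labels=None,
    criterion_control: np.ndarray | None = None,
    criterion_target: np.ndarray | None = None,
    context: str = "",
) -> HubTaxonomy:
    """Classify every node as lost / preserved / reconfigured / non-hub."""
    hc = np.asarray(hubs_control, dtype=bool)
    ht = np.asarray(hubs_target, dtype=bool)
    if hc.shape != ht.shape:
        raise ValueError("hub flag vectors must have equal length")
    if roi_labels is None:
        roi_labels = list(range(1, hc.size + 1))
    if len(roi_labels) != hc.size:
        raise ValueError("roi_labels length mismatch")
    category = np.where(
        hc & ~ht, "lost", np.where(hc & ht, "preserved", np.where(ht, "reconfigured", "non-hub"))
    )
    counts = {c: int((category == c).sum()) for c in CATEGORIES}
    return HubTaxonomy(
        roi_labels=list(roi_labels),
        hub_in_control=hc,
        hub_in_target=ht,
        category=category,
        criterion_control=criterion_control,
        criterion_target=criterion_target,
        context=context,
        counts=counts,
    )
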