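"""The AAL-116 parcellation table used for node labels and hub reporting."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_atlas", "roi_labels"]


@lru_cache(maxsize=1)
def load_atlas() -> pd.DataFrame:
    """116-row table: index (1-based ROI number), label, hemisphere, network.

    Network tags are coarse resting-state assignments (FPN, DMN, Cerebellum,
    Visual, ...) suitable for hub reports; they are approximate for regions
    that straddle networks.
    """
    with resources.files("braingraph.data").joinpath("aal116.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def roi_labels(n_roi: int = 116) -> list[str]:
    """First ``n_roi`` AAL labels; synthetic ``ROI_k`` names beyond 116."""
    atlas = load_atlas()
    labels = list(atlas["label"])
    if n_roi <= len(labels):
        return labels[:n_roi]
    return labels + [f"ROI_{i}" for i in range(len(labels) + 1, n_roi + 1)]
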