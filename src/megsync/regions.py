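"""AAL-90 region metadata (names, MNI centroids, lobe grouping).

The parcellation covers 90 cortical and subcortical regions (cerebellum
excluded), ordered by lobe with each left-hemisphere region immediately
followed by its right-hemisphere homologue. Coordinates are display/labeling
metadata only; no computation depends on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LOBES = ("Frontal", "Temporal", "Limbic", "Parietal", "Occipital")


def load_region_table() -> pd.DataFrame:
    """Packaged AAL-90 region table: order, name, MNI x/y/z (mm), lobe."""
    with resources.files("megsync.data").joinpath("aal90_regions.csv").open() as fh:
        df = pd.read_csv(fh)
    if len(df) != 90:
        raise RuntimeError(f"region fixture corrupted: {len(df)} rows, expected 90")
    if set(df["lobe"]) != set(LOBES):
        raise RuntimeError("region fixture corrupted: unexpected lobe set")
    return df


def region_names(n_regions: int = 90) -> list[str]:
    """First ``n_regions`` region names in display order.

    For reduced-scale synthetic work (n_regions < 90) the leading subset is
    used; for n_regions > 90 generic labels are generated.
    """
    if n_regions <= 90:
        return list(load_region_table()["name"].iloc[:n_regions])
    return [f"region_{i:03d}" for i in range(n_regions)]
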