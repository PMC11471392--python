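"""Bundled example data.

``load_lgm_sites`` returns the published paleoclimate-reconstruction table
for seven North American Last Glacial Maximum fossil sites: fossil and
modern community trait summaries (carnassial relative blade length mean
and SD), habitat labels, and the model-predicted vs modern mean annual
temperature (degC) and annual precipitation (mm) at each site.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_lgm_sites"]


def load_lgm_sites() -> pd.DataFrame:
    with resources.files(__package__).joinpath("data/lgm_sites.csv").open() as fh:
        return pd.read_csv(fh)
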