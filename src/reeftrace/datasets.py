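"""Packaged reference data.

``load_cayman_summary`` returns the published per-shark summary of the
2010-2019 Cayman Islands Caribbean reef shark acoustic-telemetry study
(one row per detected shark, n = 39 of 66 tagged individuals): tag
metadata, detection tallies, Residency Index, residency classification,
minimum linear displacement and the primary-receiver Site-Fidelity
Index. The raw detection logs of that study are not public; this
summary table is the study-level ground for validating the package's
metric arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Sharks tagged over the study, including 27 never-detected individuals.
CAYMAN_N_TAGGED = 66

_SUMMARY_FILE = "cayman_sharks_2010_2019.csv"

#: Island centroids (lat, lon) of the three-island study system.
CAYMAN_ISLAND_CENTROIDS = {
    "GC": (19.3222, -81.2409),
    "LC": (19.6897, -80.0367),
    "CB": (19.7235, -79.8017),
}


def load_cayman_summary() -> pd.DataFrame:
    """Per-shark summary table of the Cayman study (39 detected sharks).

    Columns: ``tag_id, sex, maturity, tl_cm, tagging_year,
    tagging_island, tag_life_days, detection_period_days, n_detections,
    n_detection_days, n_detection_months, ri, cr, mld_km, n_receivers,
    n_islands, primary_sfi_pct``. ``tag_life_days`` is the monitoring
    period actually used as the RI denominator (battery life, truncated
    at study end for tags deployed in the final year).
    """
    with resources.files("reeftrace").joinpath("data", _SUMMARY_FILE).open() as fh:
        df = pd.read_csv(fh, dtype={"tag_id": str})
    return df
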