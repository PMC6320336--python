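"""Readers for external intensity-table dialects."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_proteingroups_wide"]

_INTENSITY_RE = re.compile(r"^Intensity\s+(?P<sample>.+)_(?P<rep>\d+)$")


def read_proteingroups_wide(source: str | Path | pd.DataFrame,
                            compartment: str = "albumen",
                            id_column: str = "Protein IDs") -> pd.DataFrame:
    """Reshape a proteinGroups-style wide table into the long dialect.

    Expects one ``Intensity <sample>_<rep>`` column per run (the layout of
    MaxQuant's proteinGroups.txt export); zero intensities are treated as
    not detected (missing). Returns columns (protein_id, compartment,
    sample_id, replicate_id, batch_id, intensity) with a single batch label
    when none is encoded.
    """
    if isinstance(source, pd.DataFrame):
        wide = source
    else:
        wide = pd.read_csv(source, sep="\t")
    if id_column not in wide.columns:
        raise ValueError(f"missing id column {id_column!r}")
    runs = []
    for col in wide.columns:
        m = _INTENSITY_RE.match(col)
        if m:
            runs.append((col, m["sample"], int(m["rep"])))
    if not runs:
        raise ValueError("no 'Intensity <sample>_<rep>' columns found")
    frames = []
    for col, sample, rep in runs:
        vals = pd.to_numeric(wide[col], errors="coerce")
        frames.append(pd.DataFrame({
            "protein_id": wide[id_column],
            "compartment": compartment,
            "sample_id": sample,
            "replicate_id": rep,
            "batch_id": 1,
            "intensity": np.where(vals > 0, vals, np.nan),
        }))
    return pd.concat(frames, ignore_index=True)
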