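"""Shared paths and loaders for the numbered analysis scripts.

Small summary tables land in results/; the simulated raw data and bulky
per-sample intermediates go to scratch/ (regenerable by rerunning
01_simulate.py onwards).
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = ROOT / "scratch" / "data"
WORK = ROOT / "scratch" / "analysis"
SEED = 2014


def load(name: str, where: Path = DATA) -> pd.DataFrame:
    return pd.read_csv(where / f"{name}.tsv", sep="\t")


def save(df: pd.DataFrame, name: str, where: Path = RESULTS) -> Path:
    where.mkdir(parents=True, exist_ok=True)
    p = where / f"{name}.tsv"
    df.to_csv(p, sep="\t", index=False)
    return p
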