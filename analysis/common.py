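"""Shared paths and loaders for the numbered analysis scripts.

Scripts run from the repository root and write everything under
results/analysis/.  Each script reads the previous script's outputs, so the
sequence 01 -> 05 is reproducible end to end from a single seed.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path("results/analysis")
SEED = 2026
N_PARTICIPANTS = 20_000
START_AGE = 64.0


def out_path(name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS / name


def load(name: str) -> pd.DataFrame:
    path = RESULTS / name
    if not path.exists():
        raise SystemExit(f"{path} missing - run the earlier scripts first")
    return pd.read_csv(path)
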