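"""CSV input/output with commented header blocks, and seed derivation."""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import DiscreteDistribution

__all__ = [
    "read_distribution",
    "write_distribution",
    "write_table",
    "derive_seed",
]


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-component child seed below 2**31.

    Mixes the global seed with a CRC of the component label through a
    SeedSequence, so sub-simulations are independently reproducible from
    (global seed, component name) alone.
    """
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def write_table(path, df: pd.DataFrame, header: dict | None = None) -> None:
    """Write a CSV preceded by '# key: value' comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_distribution(path, dist: DiscreteDistribution, log: bool = False,
                       header: dict | None = None) -> None:
    """Two-column CSV (support, value); ``log`` selects log-probabilities."""
    values = dist.log_mass if log else dist.probs
    df = pd.DataFrame({"support": dist.support, "value": values})
    meta = {"values": "log-probability" if log else "probability"}
    meta.update(header or {})
    write_table(path, df, meta)


def read_distribution(path, log: bool = False) -> DiscreteDistribution:
    df = read_table(path)
    if not {"support", "value"} <= set(df.columns):
        raise ValueError("distribution CSV needs 'support' and 'value' columns")
    support = df["support"].to_numpy()
    values = df["value"].to_numpy(dtype=float)
    if log:
        return DiscreteDistribution(support, values)
    return DiscreteDistribution.from_probs(support, values)
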