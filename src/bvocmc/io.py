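"""Delimited-table output with provenance headers.

All results are written as comma-separated tables with a header row,
preceded by '#'-prefixed metadata comments (package version, seed, resolved
settings) so every output file can be re-run from its own header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_table", "read_table"]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a DataFrame as CSV with '#' metadata comment lines."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(f"# bvocmc {__version__}\n")
        for key, val in (meta or {}).items():
            for line in str(val).splitlines():
                fh.write(f"# {key}: {line}\n")
        df.to_csv(fh, index=False)
    return p


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")
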