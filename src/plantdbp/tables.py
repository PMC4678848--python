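"""Tab-separated artifact tables with '#'-prefixed comment metadata."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a DataFrame as TSV with a commented metadata preamble.

    Every artifact table carries the tool version plus whatever run
    parameters (seed, thresholds, inputs) the caller supplies, so results
    are traceable without a separate manifest.
    """
    path = Path(path)
    lines = [f"# plantdbp {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    with path.open("w") as handle:
        handle.write("\n".join(lines) + "\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
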