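"""Plain-TSV readers and writers.

All tables are tab-delimited UTF-8 with a header row and the sample (or
ASV) identifier in the first column; dates are ISO-8601 strings.  Floats
round-trip exactly because pandas writes shortest-repr decimal strings
and parses them back to the identical IEEE-754 double.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CommunityTable, validate_metadata, validate_traits


def _require_parent(path: Path) -> None:
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    path = Path(path)
    _require_parent(path)
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_community_table(path: str | Path, state: str = "raw") -> CommunityTable:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such community table: {path}")
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index.name = None
    return CommunityTable(data=data, state=state)


def write_frame(frame: pd.DataFrame, path: str | Path, index_name: str = "sample_id") -> None:
    path = Path(path)
    _require_parent(path)
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such table: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = None
    return frame


def read_metadata(path: str | Path) -> pd.DataFrame:
    metadata = read_frame(path)
    validate_metadata(metadata)
    return metadata


def read_traits(path: str | Path) -> pd.DataFrame:
    traits = read_frame(path)
    validate_traits(traits)
    return traits
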