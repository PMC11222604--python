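"""Small helpers."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd


def expand_counts(rows: Iterable[tuple[Mapping, int]]) -> pd.DataFrame:
    """Expand a count table into one record per participant.

    ``rows`` is an iterable of (column-values mapping, count); useful for
    reconstructing record-level data from published cross-tabulations.
    """
    records = []
    for values, count in rows:
        records.extend([dict(values)] * int(count))
    return pd.DataFrame(records)
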