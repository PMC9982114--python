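"""Shared CSV writing helper.

Floats are written with ``repr`` (shortest round-tripping form) so that a
write/load cycle reproduces every numeric field to full precision.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence


def write_csv(
    records: Sequence[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            writer.writerow(
                [
                    repr(v) if isinstance(v, float) else v
                    for v in (rec[c] for c in columns)
                ]
            )
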