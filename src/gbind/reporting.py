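"""Table rendering and parsing for binding free energy summaries.

The display convention: seven columns ΔE_vdw, ΔE_ele, ΔG_gb, ΔG_np,
ΔH, −TΔS, ΔG_bind, each "mean ± SEM" at two decimals, one row per
replica plus an Average row; full precision lives in JSON twins.
"""

from __future__ import annotations

import json
from typing import Sequence

from .free_energy import FreeEnergySummary, replica_average

__all__ = [
    "TABLE_COLUMNS",
    "render_summary_table",
    "parse_summary_table",
    "summary_to_json",
]

TABLE_COLUMNS = (
    ("e_vdw", "dE_vdw"),
    ("e_ele", "dE_ele"),
    ("g_gb", "dG_gb"),
    ("g_np", "dG_np"),
    ("dh", "dH"),
    ("minus_tds", "-TdS"),
    ("dg", "dG_bind"),
)


def _cell(value: float, sem: float) -> str:
    return f"{value:.2f} ± {sem:.2f}"


def render_summary_table(replica_rows: Sequence[FreeEnergySummary],
                         average: FreeEnergySummary | None = None) -> str:
    """Render replica rows plus an Average row as TSV text (kcal/mol)."""
    if average is None:
        average = replica_average(replica_rows)
    header = "Replica\t" + "\t".join(label for _, label in TABLE_COLUMNS)
    lines = [header]
    for i, row in enumerate(replica_rows):
        label = row.label or f"No. {i + 1}"
        cells = [_cell(getattr(row, f), getattr(row, f"sem_{f}"))
                 for f, _ in TABLE_COLUMNS]
        lines.append(label + "\t" + "\t".join(cells))
    cells = [_cell(getattr(average, f), getattr(average, f"sem_{f}"))
             for f, _ in TABLE_COLUMNS]
    lines.append((average.label or "Average") + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def parse_summary_table(text: str) -> list[FreeEnergySummary]:
    """Parse rendered TSV back into summary rows (two-decimal precision)."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    out = []
    for line in lines[1:]:
        parts = line.split("\t")
        label, cells = parts[0], parts[1:]
        kwargs = {"label": label}
        for (field_name, _), cell in zip(TABLE_COLUMNS, cells):
            value, sem = cell.split("±")
            kwargs[field_name] = float(value)
            kwargs[f"sem_{field_name}"] = float(sem)
        out.append(FreeEnergySummary(**kwargs))
    return out


def summary_to_json(replica_rows: Sequence[FreeEnergySummary],
                    average: FreeEnergySummary | None = None,
                    **metadata) -> str:
    """Full-precision JSON twin of the rendered table."""
    if average is None:
        average = replica_average(replica_rows)

    def row_dict(row: FreeEnergySummary) -> dict:
        d = {f: getattr(row, f) for f, _ in TABLE_COLUMNS}
        d.update({f"sem_{f}": getattr(row, f"sem_{f}")
                  for f, _ in TABLE_COLUMNS})
        d["label"] = row.label
        return d

    payload = {
        "replicas": [row_dict(r) for r in replica_rows],
        "average": row_dict(average),
    }
    payload.update(metadata)
    return json.dumps(payload, indent=1, sort_keys=True)
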