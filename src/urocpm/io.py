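"""Snapshot and time-series persistence.

Label maps are written both as lossless integer CSV and as an 8-bit PNG type
map (one colour per cell type); the cell table goes to CSV so a snapshot can
be re-scored without re-running the simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from urocpm import constants as C
from urocpm.engine.state import SimulationState


def write_label_csv(state: SimulationState, path) -> None:
    np.savetxt(path, state.labels, fmt="%d", delimiter=",")


def write_cell_table_csv(state: SimulationState, path) -> None:
    rows = []
    for cell in state.cells():
        rows.append(
            {
                "id": cell.id,
                "type": C.TYPE_NAMES[cell.type],
                "actual_volume": cell.actual_volume,
                "target_volume": cell.target_volume,
                "actual_surface": cell.actual_surface,
                "target_surface": cell.target_surface,
                "age_days": cell.age_days,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "id", "type", "actual_volume", "target_volume",
            "actual_surface", "target_surface", "age_days",
        ],
    ).to_csv(path, index=False)


def write_type_png(state: SimulationState, path) -> None:
    """8-bit RGB type map; the origin (basal membrane) is at the bottom."""
    h, w = state.labels.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    type_field = state.ctype[state.labels]
    for code, color in C.TYPE_COLORS.items():
        img[type_field == code] = color
    Image.fromarray(img[::-1]).save(path)


def write_snapshot(state: SimulationState, out_dir, tag: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_label_csv(state, out_dir / f"{tag}_labels.csv")
    write_cell_table_csv(state, out_dir / f"{tag}_cells.csv")
    write_type_png(state, out_dir / f"{tag}_types.png")


def load_snapshot(config, label_csv, cell_csv) -> SimulationState:
    """Rebuild a scoreable state from a label CSV + cell-table CSV."""
    state = SimulationState(config)
    labels = np.loadtxt(label_csv, delimiter=",", dtype=np.int64)
    if labels.shape != state.labels.shape:
        raise ValueError(
            f"snapshot shape {labels.shape} does not match configured lattice "
            f"{state.labels.shape}"
        )
    state.labels = labels
    table = pd.read_csv(cell_csv)
    max_label = int(table["id"].max()) if len(table) else C.FIRST_CELL_LABEL
    state._grow_tables(max_label + 1)
    for _, row in table.iterrows():
        lab = int(row["id"])
        state.alive[lab] = True
        state.ctype[lab] = C.TYPE_CODES[row["type"]]
        state.vt[lab] = float(row["target_volume"])
        state.st[lab] = float(row["target_surface"])
        state.age[lab] = float(row.get("age_days", 0.0))
    state.next_label = max_label + 1
    state.refresh_geometry(prune=True)
    return state


def write_series_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
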