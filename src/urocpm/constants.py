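"""Integer codes shared by the lattice kernel, cell table and scoring code."""

import numpy as np

# Region/cell type codes. MEDIUM and BM are non-cell regions; the four cell
# types follow the one-way differentiation path P -> B -> I -> U.
MEDIUM = 0
BM = 1
PROGENITOR = 2
BASAL = 3
INTERMEDIATE = 4
UMBRELLA = 5

N_TYPES = 6

CELL_TYPES = (PROGENITOR, BASAL, INTERMEDIATE, UMBRELLA)

TYPE_NAMES = {
    MEDIUM: "medium",
    BM: "bm",
    PROGENITOR: "progenitor",
    BASAL: "basal",
    INTERMEDIATE: "intermediate",
    UMBRELLA: "umbrella",
}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

TYPE_LETTER = {PROGENITOR: "P", BASAL: "B", INTERMEDIATE: "I", UMBRELLA: "U"}

# Reserved lattice labels. Cells get labels >= FIRST_CELL_LABEL.
MEDIUM_LABEL = 0
BM_LABEL = 1
FIRST_CELL_LABEL = 2

# 2nd-order (Moore) neighbourhood, used for both copy-attempt proposals and
# contact/surface counting.
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# RGB palette for type-map snapshots (one colour per region/type).
TYPE_COLORS = {
    MEDIUM: (0, 0, 0),
    BM: (120, 120, 120),
    PROGENITOR: (220, 50, 50),
    BASAL: (240, 160, 40),
    INTERMEDIATE: (60, 140, 220),
    UMBRELLA: (90, 200, 90),
}
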