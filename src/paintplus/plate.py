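"""384-well reference plate layouts for phenotypic profiling screens.

The reference design places ``n_compounds`` compounds at ``n_conc`` serial
half-log dilutions in ``n_blocks`` technical-replicate blocks, plus DMSO
solvent-control wells used to define baseline activity.  The default
geometry is a 16 x 24 (384-well) plate: 15 compounds x 8 concentrations
x 3 blocks + 24 controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24
PLATE_CAPACITY = N_ROWS * N_COLS

ROLE_COMPOUND = "compound"
ROLE_CONTROL = "solvent_control"

HALF_LOG = 10.0 ** 0.5  # dilution ratio between adjacent concentrations


def well_name(row: int, col: int) -> str:
    """A01..P24 naming; row 0 -> 'A', col 0 -> '01'."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well ({row}, {col}) outside 16x24 plate")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def parse_well_name(name: str) -> tuple[int, int]:
    row = ord(name[0].upper()) - ord("A")
    col = int(name[1:]) - 1
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well name {name!r} outside 16x24 plate")
    return row, col


def half_log_series(top_conc_uM: float, n_conc: int) -> np.ndarray:
    """Descending half-log dilution series starting at ``top_conc_uM``."""
    return top_conc_uM * HALF_LOG ** -np.arange(n_conc)


@dataclass(frozen=True)
class Well:
    row: int
    col: int
    role: str
    compound_id: str | None
    concentration_uM: float
    tech_block: int

    @property
    def name(self) -> str:
        return well_name(self.row, self.col)


@dataclass
class PlateLayout:
    plate_id: str
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = {(w.row, w.col) for w in self.wells}
        if len(seen) != len(self.wells):
            raise ValueError("duplicate well positions in layout")

    @property
    def control_wells(self) -> list[Well]:
        return [w for w in self.wells if w.role == ROLE_CONTROL]

    @property
    def compound_wells(self) -> list[Well]:
        return [w for w in self.wells if w.role == ROLE_COMPOUND]

    @property
    def compounds(self) -> list[str]:
        return sorted({w.compound_id for w in self.compound_wells})

    def concentrations(self, compound_id: str) -> np.ndarray:
        concs = sorted({w.concentration_uM for w in self.compound_wells
                        if w.compound_id == compound_id})
        return np.asarray(concs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": self.plate_id,
                "well": [w.name for w in self.wells],
                "row": [w.row for w in self.wells],
                "col": [w.col for w in self.wells],
                "role": [w.role for w in self.wells],
                "compound_id": [w.compound_id or "" for w in self.wells],
                "concentration_uM": [w.concentration_uM for w in self.wells],
                "tech_block": [w.tech_block for w in self.wells],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlateLayout":
        plate_ids = df["plate_id"].unique()
        if len(plate_ids) != 1:
            raise ValueError(f"expected one plate_id, found {list(plate_ids)}")
        wells = []
        for rec in df.itertuples(index=False):
            row, col = parse_well_name(rec.well)
            compound = rec.compound_id if isinstance(rec.compound_id, str) and rec.compound_id else None
            wells.append(Well(row, col, rec.role, compound,
                              float(rec.concentration_uM), int(rec.tech_block)))
        return cls(plate_id=str(plate_ids[0]), wells=wells)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False,
                                              na_values=[]))

    def validate_reference_design(self) -> None:
        """Check the combinatorial invariants of the reference design."""
        if len(self.wells) != PLATE_CAPACITY:
            raise ValueError(f"{len(self.wells)} wells, expected {PLATE_CAPACITY}")
        for cmpd in self.compounds:
            concs = self.concentrations(cmpd)
            ratios = np.diff(np.log10(concs))
            if not np.allclose(ratios, 0.5, atol=1e-9):
                raise ValueError(f"{cmpd}: concentrations are not a half-log series")
            blocks: dict[tuple[str, float], set[int]] = {}
            for w in self.compound_wells:
                blocks.setdefault((w.compound_id, w.concentration_uM), set()).add(w.tech_block)
            n_blocks = {len(b) for b in blocks.values()}
            counts: dict[tuple[str, float, int], int] = {}
            for w in self.compound_wells:
                key = (w.compound_id, w.concentration_uM, w.tech_block)
                counts[key] = counts.get(key, 0) + 1
            if any(c != 1 for c in counts.values()):
                raise ValueError("a compound x concentration repeats within a block")
            if len(n_blocks) != 1:
                raise ValueError("inconsistent technical-block coverage")


def generate_plate_layout(
    n_compounds: int = 15,
    n_conc: int = 8,
    n_blocks: int = 3,
    n_controls: int = 24,
    top_concs_uM: Mapping[str, float] | float | None = None,
    seed: int = 0,
    plate_id: str = "plate01",
    compound_ids: Sequence[str] | None = None,
) -> PlateLayout:
    """Generate a reference compound plate layout.

    Compound wells are arranged in ``n_blocks`` column bands (technical
    blocks); between blocks the compound sequence is rotated by one position
    so that the dispensing order alternates, guarding against plate-position
    effects.  Solvent-control wells are scattered within each block at
    seeded positions.  Deterministic for a given seed.
    """
    n_wells = n_compounds * n_conc * n_blocks + n_controls
    if n_wells != PLATE_CAPACITY:
        raise ValueError(
            f"capacity mismatch: {n_compounds}*{n_conc}*{n_blocks} + {n_controls} "
            f"= {n_wells} != {PLATE_CAPACITY}"
        )
    if n_controls % n_blocks:
        raise ValueError("n_controls must divide evenly across blocks")
    if compound_ids is None:
        compound_ids = [f"C{i + 1:02d}" for i in range(n_compounds)]
    if top_concs_uM is None:
        top_concs_uM = 100.0
    if not isinstance(top_concs_uM, Mapping):
        top_concs_uM = {c: float(top_concs_uM) for c in compound_ids}

    rng = np.random.default_rng(seed)
    cols_per_block = N_COLS // n_blocks if n_blocks <= N_COLS and N_COLS % n_blocks == 0 else None

    # Positions per block: contiguous column bands when they tile evenly,
    # otherwise a row-major split of all wells.
    all_positions = [(r, c) for c in range(N_COLS) for r in range(N_ROWS)]
    if cols_per_block is not None:
        blocks_positions = [
            [(r, c) for c in range(b * cols_per_block, (b + 1) * cols_per_block)
             for r in range(N_ROWS)]
            for b in range(n_blocks)
        ]
    else:
        per = PLATE_CAPACITY // n_blocks
        blocks_positions = [all_positions[b * per:(b + 1) * per] for b in range(n_blocks)]
        blocks_positions[-1] = all_positions[(n_blocks - 1) * per:]

    controls_per_block = n_controls // n_blocks
    wells: list[Well] = []
    for b, positions in enumerate(blocks_positions):
        positions = list(positions)
        ctrl_idx = set(rng.choice(len(positions), size=controls_per_block, replace=False))
        compound_positions = [p for i, p in enumerate(positions) if i not in ctrl_idx]
        control_positions = [p for i, p in enumerate(positions) if i in ctrl_idx]
        # alternate order between blocks: rotate the compound sequence
        order = list(compound_ids[b % n_compounds:]) + list(compound_ids[:b % n_compounds])
        assignments = [
            (cmpd, conc)
            for cmpd in order
            for conc in half_log_series(top_concs_uM[cmpd], n_conc)
        ]
        if len(assignments) > len(compound_positions):
            raise ValueError("block does not hold its compound assignments")
        for (cmpd, conc), (r, c) in zip(assignments, compound_positions):
            wells.append(Well(r, c, ROLE_COMPOUND, cmpd, float(conc), b + 1))
        for r, c in control_positions:
            wells.append(Well(r, c, ROLE_CONTROL, None, 0.0, b + 1))

    layout = PlateLayout(plate_id=plate_id, wells=wells)
    return layout
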