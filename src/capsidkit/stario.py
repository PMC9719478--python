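"""Minimal STAR (loop-format) reader/writer for particle metadata tables.

Covers the single-block, loop-format dialect used for cryo-EM particle
tables (RELION 3.0 column names).  Column names and order are preserved
byte-exactly on round trip; numeric values are written with six decimal
places.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .localrec import ParticleRecord, SubParticleRecord

__all__ = [
    "StarTable",
    "read_star",
    "write_star",
    "particles_to_table",
    "table_to_particles",
    "subparticles_to_table",
]

#: RELION 3.0 particle-table columns required to expand sub-particles.
REQUIRED_PARTICLE_COLUMNS = (
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnOriginX",
    "rlnOriginY",
    "rlnDefocusU",
    "rlnDefocusV",
    "rlnImageName",
)


@dataclass
class StarTable:
    block_name: str
    columns: list
    rows: list = field(default_factory=list)  # list of dicts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)

    def __len__(self) -> int:
        return len(self.rows)


class StarParseError(ValueError):
    pass


def _coerce(token: str):
    try:
        return int(token)
    except ValueError:
        try:
            return float(token)
        except ValueError:
            return token


def read_star(path) -> StarTable:
    """Parse the first loop-format block of a STAR file."""
    block_name = ""
    columns: list = []
    rows: list = []
    state = "preamble"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                if state != "preamble":
                    break  # only the first block
                block_name = line[len("data_") :]
                state = "block"
            elif line == "loop_":
                if state != "block":
                    raise StarParseError(f"{path}:{lineno}: loop_ outside a data block")
                state = "header"
            elif line.startswith("_"):
                if state != "header":
                    raise StarParseError(f"{path}:{lineno}: column label outside loop header")
                columns.append(line.split()[0].lstrip("_"))
            else:
                if state == "header":
                    state = "rows"
                if state != "rows":
                    raise StarParseError(f"{path}:{lineno}: data row outside a loop")
                tokens = line.split()
                if len(tokens) != len(columns):
                    raise StarParseError(
                        f"{path}:{lineno}: {len(tokens)} fields for {len(columns)} columns"
                    )
                rows.append(dict(zip(columns, map(_coerce, tokens))))
    if not columns:
        raise StarParseError(f"{path}: no loop-format block found")
    return StarTable(block_name=block_name, columns=columns, rows=rows)


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_star(table: StarTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"data_{table.block_name}\n\nloop_\n")
        for i, col in enumerate(table.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for row in table.rows:
            fh.write(" ".join(_fmt(row[c]) for c in table.columns) + "\n")


def particles_to_table(particles: list, block_name: str = "particles") -> StarTable:
    columns = list(REQUIRED_PARTICLE_COLUMNS) + ["rlnDetectorPixelSize"]
    rows = [
        {
            "rlnAngleRot": p.euler_rot,
            "rlnAngleTilt": p.euler_tilt,
            "rlnAnglePsi": p.euler_psi,
            "rlnOriginX": p.origin_x,
            "rlnOriginY": p.origin_y,
            "rlnDefocusU": p.defocus_u,
            "rlnDefocusV": p.defocus_v,
            "rlnImageName": p.image_ref or p.id,
            "rlnDetectorPixelSize": p.pixel_size,
        }
        for p in particles
    ]
    return StarTable(block_name=block_name, columns=columns, rows=rows)


def table_to_particles(table: StarTable, pixel_size: float | None = None) -> list:
    """Build ParticleRecords, erroring on any missing required column."""
    missing = [c for c in REQUIRED_PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise StarParseError(
            "particle table lacks required column(s): " + ", ".join(missing)
        )
    out = []
    for i, row in enumerate(table.rows):
        out.append(
            ParticleRecord(
                id=f"p{i:06d}",
                euler_rot=float(row["rlnAngleRot"]),
                euler_tilt=float(row["rlnAngleTilt"]),
                euler_psi=float(row["rlnAnglePsi"]),
                origin_x=float(row["rlnOriginX"]),
                origin_y=float(row["rlnOriginY"]),
                defocus_u=float(row["rlnDefocusU"]),
                defocus_v=float(row["rlnDefocusV"]),
                image_ref=str(row["rlnImageName"]),
                pixel_size=float(
                    pixel_size if pixel_size is not None else row.get("rlnDetectorPixelSize", 1.0)
                ),
            )
        )
    return out


def subparticles_to_table(subparticles: list, block_name: str = "subparticles") -> StarTable:
    columns = [
        "rlnImageName",
        "rlnSymmetryIndex",
        "rlnAngleRot",
        "rlnAngleTilt",
        "rlnAnglePsi",
        "rlnOriginX",
        "rlnOriginY",
        "rlnDefocusU",
        "rlnDefocusV",
        "rlnCenteredCoordinateZAngst",
    ]
    rows = [
        {
            "rlnImageName": s.parent_id,
            "rlnSymmetryIndex": s.sym_index,
            "rlnAngleRot": s.euler_rot,
            "rlnAngleTilt": s.euler_tilt,
            "rlnAnglePsi": s.euler_psi,
            "rlnOriginX": s.offset_x,
            "rlnOriginY": s.offset_y,
            "rlnDefocusU": s.defocus_u,
            "rlnDefocusV": s.defocus_v,
            "rlnCenteredCoordinateZAngst": s.z_shift,
        }
        for s in subparticles
    ]
    return StarTable(block_name=block_name, columns=columns, rows=rows)
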