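"""File-format plumbing: TPS and long-format CSV landmark files, limb and
metadata CSVs, trait-table CSV with a sidecar JSON of block labels, and
modularity hypotheses as YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .modularity import ModuleHypothesis
from .morphodata import LandmarkConfiguration, SpecimenRecord, TraitTable

__all__ = [
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_limb_csv",
    "read_metadata_csv",
    "assemble_specimens",
    "write_trait_table",
    "read_trait_table",
    "read_hypotheses",
]


def read_tps(
    path: str | Path,
    structure: str,
    sides: dict[str, str] | None = None,
    default_side: str = "left",
) -> list[LandmarkConfiguration]:
    """Parse a 3D TPS file (``LM3=k`` count lines, ``ID=`` keys)."""
    configs = []
    coords: list[list[float]] = []
    expected = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM3="):
                coords = []
                expected = int(line.split("=", 1)[1])
            elif up.startswith("ID="):
                sid = line.split("=", 1)[1].strip()
                if len(coords) != expected:
                    raise ValueError(
                        f"{sid}: expected {expected} landmarks, got {len(coords)}"
                    )
                side = (sides or {}).get(sid, default_side)
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=sid,
                        structure=structure,
                        side=side,
                        coords=np.asarray(coords),
                    )
                )
            elif up.startswith(("LM=", "IMAGE=", "SCALE=")):
                continue
            else:
                coords.append([float(x) for x in line.split()])
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={c.coords.shape[0]}\n")
            for row in c.coords:
                fh.write(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")
            fh.write(f"ID={c.specimen_id}\n")


LANDMARK_CSV_COLUMNS = [
    "specimen_id", "structure", "side", "landmark_index", "x", "y", "z",
]


def read_landmarks_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Long-format landmark CSV: one row per landmark, columns
    specimen_id, structure, side, landmark_index, x, y, z."""
    df = pd.read_csv(path)
    missing = set(LANDMARK_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    configs = []
    for (sid, structure, side), g in df.groupby(
        ["specimen_id", "structure", "side"], sort=True
    ):
        g = g.sort_values("landmark_index")
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                structure=structure,
                side=side,
                coords=g[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return configs


def write_landmarks_csv(
    configs: list[LandmarkConfiguration], path: str | Path
) -> None:
    rows = []
    for c in configs:
        for i, (x, y, z) in enumerate(c.coords, start=1):
            rows.append(
                {
                    "specimen_id": c.specimen_id,
                    "structure": c.structure.value,
                    "side": c.side.value,
                    "landmark_index": i,
                    "x": x, "y": y, "z": z,
                }
            )
    pd.DataFrame(rows, columns=LANDMARK_CSV_COLUMNS).to_csv(path, index=False)


def read_limb_csv(path: str | Path) -> pd.DataFrame:
    """Limb-length CSV: specimen_id column + one column per element (mm);
    empty cells are missing."""
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise ValueError("limb CSV needs a specimen_id column")
    return df.set_index("specimen_id").astype(float)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Specimen metadata CSV: specimen_id, species_id, group, sex
    (optional ecomorph)."""
    df = pd.read_csv(path)
    need = {"specimen_id", "species_id", "group"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    if "ecomorph" not in df.columns:
        df["ecomorph"] = None
    return df.set_index("specimen_id")


def assemble_specimens(
    landmarks: list[LandmarkConfiguration],
    limb: pd.DataFrame,
    metadata: pd.DataFrame,
) -> list[SpecimenRecord]:
    """Join landmark configurations, limb lengths, and metadata into
    SpecimenRecords (one per specimen in the metadata table)."""
    by_spec: dict[str, dict[str, LandmarkConfiguration]] = {}
    for c in landmarks:
        by_spec.setdefault(c.specimen_id, {})[c.structure.value] = c
    out = []
    for sid, row in metadata.iterrows():
        lm = by_spec.get(str(sid), {})
        lengths = {}
        if str(sid) in limb.index:
            lengths = {
                e: float(v)
                for e, v in limb.loc[str(sid)].items()
                if np.isfinite(v)
            }
        out.append(
            SpecimenRecord(
                specimen_id=str(sid),
                species_id=str(row["species_id"]),
                group=str(row["group"]),
                sex=str(row.get("sex", "unknown")),
                ecomorph=row.get("ecomorph"),
                limb_lengths=lengths,
                pectoral=lm.get("pectoral"),
                pelvic=lm.get("pelvic"),
            )
        )
    return out


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Trait table as CSV plus a ``<path>.blocks.json`` sidecar with the
    block labels and standardization flag."""
    path = Path(path)
    table.values.to_csv(path)
    sidecar = {
        "standardized": bool(table.standardized),
        "block_of": table.block_of,
    }
    with open(path.with_suffix(path.suffix + ".blocks.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trait_table(path: str | Path) -> TraitTable:
    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    with open(path.with_suffix(path.suffix + ".blocks.json")) as fh:
        sidecar = json.load(fh)
    return TraitTable(
        values=values,
        block_of=sidecar["block_of"],
        standardized=sidecar["standardized"],
    )


def read_hypotheses(path: str | Path) -> dict[str, ModuleHypothesis]:
    """Hypotheses file (YAML or JSON): mapping of hypothesis name →
    {module name → list of blocks}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        module_of = {}
        for module, blocks in spec.items():
            for b in blocks:
                module_of[b] = module
        out[name] = ModuleHypothesis(name=name, module_of=module_of)
    return out
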