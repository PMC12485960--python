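"""Delimited-text readers and writers for patch-survey tables.

Schema: one header row, comma-delimited, UTF-8, missing values as empty
fields.  The fixed metadata columns come first; every additional column is
read as a species name whose cells are identified-worm counts (blank = 0).
``write_patch_table`` emits species columns in sorted order, so a
read -> write -> read cycle is lossless and byte-stable for tables the
package itself wrote.
"""

from __future__ import annotations

import csv
from typing import List, Optional, Sequence

from patchdemes.records import PatchRecord, ValidationError

#: Fixed metadata columns, in file order.  Anything else is a species column.
META_COLUMNS = [
    "patch_id",
    "region",
    "forest_type",
    "substrate_class",
    "substrate_name",
    "elevation",
    "substrate_temp",
    "elevated_position",
    "density_rank",
    "quadrat",
    "grid_row",
    "grid_col",
    "color_stage",
]

_REQUIRED = {"patch_id", "region", "forest_type", "substrate_class"}


def _parse_opt_int(raw: str, row: int, col: str) -> Optional[int]:
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError:
        raise ValidationError(f"row {row}: field {col!r} is not an integer: {raw!r}")


def _parse_opt_float(raw: str, row: int, col: str) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: field {col!r} is not a number: {raw!r}")


def read_patch_table(path, delimiter: str = ",") -> List[PatchRecord]:
    """Read a survey table into validated :class:`PatchRecord` rows."""
    records: List[PatchRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = _REQUIRED - set(header)
        if missing:
            raise ValidationError(
                f"{path}: header missing required columns {sorted(missing)}"
            )
        species_cols = [c for c in header if c not in META_COLUMNS]
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            counts = {}
            for sp in species_cols:
                raw = (row.get(sp) or "").strip()
                if raw == "":
                    continue
                try:
                    cnt = int(raw)
                except ValueError:
                    raise ValidationError(
                        f"row {i}: count for species {sp!r} is not an "
                        f"integer: {raw!r}"
                    )
                if cnt < 0:
                    raise ValidationError(
                        f"row {i}: count for species {sp!r} is negative"
                    )
                counts[sp] = cnt
            elevated = (row.get("elevated_position") or "").strip().lower()
            try:
                rec = PatchRecord(
                    patch_id=row["patch_id"],
                    region=row["region"],
                    forest_type=row["forest_type"],
                    substrate_class=row["substrate_class"],
                    substrate_name=row.get("substrate_name") or "",
                    elevation=_parse_opt_float(
                        (row.get("elevation") or "").strip(), i, "elevation"
                    ) or 0.0,
                    substrate_temp=_parse_opt_float(
                        (row.get("substrate_temp") or "").strip(), i,
                        "substrate_temp"),
                    elevated_position=elevated in ("true", "1", "yes"),
                    species_counts=counts,
                    density_rank=_parse_opt_int(
                        (row.get("density_rank") or "").strip(), i,
                        "density_rank"),
                    quadrat=_parse_opt_int(
                        (row.get("quadrat") or "").strip(), i, "quadrat"),
                    grid_row=_parse_opt_int(
                        (row.get("grid_row") or "").strip(), i, "grid_row"),
                    grid_col=_parse_opt_int(
                        (row.get("grid_col") or "").strip(), i, "grid_col"),
                    color_stage=_parse_opt_int(
                        (row.get("color_stage") or "").strip(), i,
                        "color_stage"),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_patch_table(records: Sequence[PatchRecord], path,
                      delimiter: str = ",") -> None:
    """Write records to a delimited table (species columns sorted)."""
    species = sorted({sp for r in records for sp in r.species_counts})
    header = META_COLUMNS + species
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for r in records:
            row = [
                r.patch_id, r.region, r.forest_type, r.substrate_class,
                r.substrate_name, _fmt(r.elevation), _fmt(r.substrate_temp),
                _fmt(r.elevated_position), _fmt(r.density_rank),
                _fmt(r.quadrat), _fmt(r.grid_row), _fmt(r.grid_col),
                _fmt(r.color_stage),
            ]
            row += [_fmt(r.species_counts.get(sp)) for sp in species]
            writer.writerow(row)
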