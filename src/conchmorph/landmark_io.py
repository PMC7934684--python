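"""Reading and writing landmark data in the TPS dialect of tpsDig.

TPS records look like::

    LM=16
    1.234 5.678
    ...            (16 coordinate lines)
    IMAGE=spec01.jpg
    ID=spec01_2.5
    SCALE=0.01

Coordinates in the file follow the digitizer's image convention (row axis
pointing down); on read they are converted to mathematical y-up Cartesian
coordinates and multiplied by SCALE when present, so everything downstream
works in mm with y increasing towards the venter.  Specimen and stage
identity is encoded in the ID key as ``<specimen>_<stage>``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .scheme import (
    DEFAULT_SCHEME,
    N_LANDMARKS,
    STAGES,
    IncompleteSeriesError,
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    SpecimenSeries,
    is_even_stage,
    is_valid_stage,
)

__all__ = [
    "read_tps",
    "write_tps",
    "read_metadata",
    "write_metadata",
    "mirror_even_whorls",
    "validate_scheme",
    "TPSParseError",
    "MetadataError",
]


class TPSParseError(ValueError):
    """A TPS record could not be parsed; the message names the record."""


class MetadataError(KeyError):
    """A specimen id has no species entry in the metadata table."""


def _parse_records(text: str, path: str) -> list[dict]:
    records: list[dict] = []
    current: dict | None = None
    n_expected = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if current is not None:
                records.append(current)
            try:
                n_expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSParseError(f"{path}:{lineno}: bad LM= line {line!r}") from exc
            current = {"lm": n_expected, "coords": [], "keys": {}, "line": lineno}
        elif "=" in line and not _looks_like_coords(line):
            if current is None:
                raise TPSParseError(f"{path}:{lineno}: key line outside a record")
            key, value = line.split("=", 1)
            current["keys"][key.strip().upper()] = value.strip()
        else:
            if current is None:
                raise TPSParseError(f"{path}:{lineno}: coordinates outside a record")
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}:{lineno}: expected 'x y' pair, got {line!r}"
                )
            try:
                current["coords"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"{path}:{lineno}: non-numeric coordinates {line!r}"
                ) from exc
    if current is not None:
        records.append(current)
    for rec in records:
        if len(rec["coords"]) != rec["lm"]:
            ident = rec["keys"].get("ID", f"record at line {rec['line']}")
            raise TPSParseError(
                f"{path}: record {ident!r} declares LM={rec['lm']} but has "
                f"{len(rec['coords'])} coordinate lines"
            )
    return records


def _looks_like_coords(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def _split_id(ident: str, path: str) -> tuple[str, float]:
    """Split ``<specimen>_<stage>`` at the last underscore."""
    if "_" not in ident:
        raise TPSParseError(f"{path}: ID {ident!r} lacks a '_<stage>' suffix")
    specimen, stage_str = ident.rsplit("_", 1)
    try:
        stage = float(stage_str)
    except ValueError as exc:
        raise TPSParseError(f"{path}: ID {ident!r} has non-numeric stage") from exc
    if not is_valid_stage(stage):
        raise TPSParseError(
            f"{path}: ID {ident!r} has stage {stage} off the 0.5..5.5 grid"
        )
    return specimen, stage


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read the specimen metadata CSV (columns ``specimen_id``, ``species``)."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "specimen_id",
            "species",
        } <= set(reader.fieldnames):
            raise MetadataError(
                f"{path}: metadata CSV needs 'specimen_id' and 'species' columns"
            )
        for row in reader:
            table[row["specimen_id"]] = row["species"]
    return table


def write_metadata(dataset: LandmarkDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "species"])
        for s in dataset.specimens:
            writer.writerow([s.specimen_id, s.species])


def read_tps(
    path: str | Path,
    metadata_path: str | Path | None = None,
    scheme: LandmarkScheme = DEFAULT_SCHEME,
    allow_incomplete: bool = False,
) -> LandmarkDataset:
    """Read a TPS file (and species metadata) into a :class:`LandmarkDataset`.

    Records are grouped into specimens via their ``ID=<specimen>_<stage>``
    key.  SCALE is applied when present; the image row axis is flipped to
    y-up.  Specimens missing any of the 11 stages raise
    :class:`~conchmorph.scheme.IncompleteSeriesError` unless
    ``allow_incomplete`` drops them instead.
    """
    path = Path(path)
    records = _parse_records(path.read_text(), str(path))
    species_of = read_metadata(metadata_path) if metadata_path else None

    by_specimen: dict[str, dict[float, LandmarkConfiguration]] = {}
    for rec in records:
        ident = rec["keys"].get("ID")
        if ident is None:
            raise TPSParseError(
                f"{path}: record at line {rec['line']} has no ID= key"
            )
        specimen, stage = _split_id(ident, str(path))
        pts = np.asarray(rec["coords"], dtype=float)
        scale = float(rec["keys"].get("SCALE", 1.0))
        pts = pts * scale
        pts[:, 1] = -pts[:, 1]  # image rows increase downward
        if pts.shape[0] != scheme.n_landmarks:
            raise TPSParseError(
                f"{path}: record {ident!r} has {pts.shape[0]} landmarks, "
                f"scheme expects {scheme.n_landmarks}"
            )
        by_specimen.setdefault(specimen, {})[stage] = LandmarkConfiguration(
            pts, stage, specimen
        )

    specimens: list[SpecimenSeries] = []
    for specimen_id in sorted(by_specimen):
        configs = by_specimen[specimen_id]
        if species_of is not None:
            if specimen_id not in species_of:
                raise MetadataError(
                    f"specimen {specimen_id!r} has no species in the metadata table"
                )
            species = species_of[specimen_id]
        else:
            species = "unknown"
        try:
            specimens.append(SpecimenSeries(specimen_id, species, configs))
        except IncompleteSeriesError:
            if not allow_incomplete:
                raise
    return LandmarkDataset(
        scheme=scheme,
        specimens=specimens,
        provenance={"tps_path": str(path), "metadata_path": str(metadata_path or "")},
    )


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write one TPS record per half-whorl, readable by :func:`read_tps`.

    Coordinates are written with enough digits that a read/write round trip
    is loss-free well below 1e-5 of centroid size.
    """
    lines: list[str] = []
    for specimen in dataset.specimens:
        for stage in STAGES:
            config = specimen.stage(stage)
            lines.append(f"LM={config.points.shape[0]}")
            for x, y in config.points:
                lines.append(f"{x:.10g} {-y:.10g}")
            lines.append(f"ID={specimen.specimen_id}_{stage:.1f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def mirror_even_whorls(
    dataset: LandmarkDataset, axis_tol: float = 1e-9
) -> LandmarkDataset:
    """Reflect every even-stage (integer) configuration about its axial line.

    Half whorls on the far side of the protoconch are digitized as mirror
    images and cannot be superimposed on the odd whorls by rotation alone.
    Each even-stage configuration is reflected about the symmetry axis
    estimated from the two midline landmarks, and paired landmarks are
    relabelled (swapped within each pair) so left/right homology is kept.
    The operation is an involution: applying it twice restores the input.
    """
    scheme = dataset.scheme
    m1, m2 = scheme.midline_ids
    perm = scheme.pair_permutation
    new_specimens = []
    for specimen in dataset.specimens:
        configs = {}
        for stage, config in specimen.configurations.items():
            if is_even_stage(stage):
                pts = config.points
                a, b = pts[m1 - 1], pts[m2 - 1]
                d = b - a
                norm = np.hypot(*d)
                scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
                if norm < axis_tol * scale:
                    raise ValueError(
                        f"axis undefined for specimen {specimen.specimen_id!r} "
                        f"stage {stage}: midline landmarks coincide"
                    )
                d = d / norm
                # householder reflection across the line through a with direction d
                H = 2.0 * np.outer(d, d) - np.eye(2)
                reflected = (pts - a) @ H.T + a
                configs[stage] = LandmarkConfiguration(
                    reflected[perm], stage, specimen.specimen_id
                )
            else:
                configs[stage] = config.copy()
        new_specimens.append(
            SpecimenSeries(specimen.specimen_id, specimen.species, configs)
        )
    return LandmarkDataset(scheme, new_specimens, dict(dataset.provenance))


def validate_scheme(dataset: LandmarkDataset) -> dict:
    """Report structural issues without raising.

    Checks per-specimen stage completeness, point counts, duplicate
    specimen ids and pair ordering (paired landmarks on opposite sides of
    the axial line).  Returns a JSON-serializable report.
    """
    scheme = dataset.scheme
    m1, m2 = scheme.midline_ids
    issues: list[dict] = []
    seen: set[str] = set()
    for specimen in dataset.specimens:
        if specimen.specimen_id in seen:
            issues.append(
                {"kind": "duplicate_id", "specimen": specimen.specimen_id}
            )
        seen.add(specimen.specimen_id)
        missing = [s for s in STAGES if s not in specimen.configurations]
        if missing:
            issues.append(
                {
                    "kind": "missing_stage",
                    "specimen": specimen.specimen_id,
                    "stages": missing,
                }
            )
        for stage, config in specimen.configurations.items():
            n = config.points.shape[0]
            if n != scheme.n_landmarks:
                issues.append(
                    {
                        "kind": "point_count",
                        "specimen": specimen.specimen_id,
                        "stage": stage,
                        "count": n,
                    }
                )
                continue
            pts = config.points
            a, b = pts[m1 - 1], pts[m2 - 1]
            d = b - a
            if np.hypot(*d) == 0:
                continue
            normal = np.array([-d[1], d[0]]) / np.hypot(*d)
            centered = pts - pts.mean(axis=0)
            cs = float(np.sqrt((centered**2).sum()))
            # flag only pairs clearly on one side: landmarks near the axial
            # line (umbilical seam on adult whorls) would otherwise misfire
            # under digitization noise
            margin = 0.02 * cs
            for left, right in scheme.pairs:
                sl = float(np.dot(pts[left - 1] - a, normal))
                sr = float(np.dot(pts[right - 1] - a, normal))
                if sl * sr > 0 and min(abs(sl), abs(sr)) > margin:
                    issues.append(
                        {
                            "kind": "pair_side",
                            "specimen": specimen.specimen_id,
                            "stage": stage,
                            "pair": [left, right],
                        }
                    )
    return {
        "n_specimens": len(dataset.specimens),
        "n_issues": len(issues),
        "issues": issues,
    }


def write_validation_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
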