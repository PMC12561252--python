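"""TFQ-1: an open plain-text exchange dialect for per-eye polar maps.

One file per map.  Header lines (``key: value``) carry the metadata,
followed by one CSV row per ring with one column per meridian; an empty
field is the missing-value sentinel.  Example::

    format: TFQ-1
    subject: S1001
    eye: OD
    wear_days: 17
    session: pre
    modality: tear_quality
    flags:
    rings: 0.1,0.2,0.3
    angles: 0,90,180,270

A small JSON sidecar written next to the map files groups the two (or
four) maps of an :class:`~tearmap.core.EyeRecord`; a JSON manifest lists
record sidecars to form a cohort.  Floats are serialised with ``repr``
(shortest round-trip form), so write -> read is the identity and two
writes of the same record are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Cohort, EyeRecord, PolarGrid, TearFilmMap

__all__ = ["read_map_file", "write_map_file", "load_cohort", "write_cohort",
           "ParseError"]

_HEADER_KEYS = ("format", "subject", "eye", "wear_days", "session",
                "modality", "flags", "rings", "angles")
_MAP_SUFFIXES = {
    "pre": "_pre.tfq", "post": "_post.tfq",
    "pre_curvature": "_pre_curv.tfq", "post_curvature": "_post_curv.tfq",
}


class ParseError(ValueError):
    """Malformed TFQ-1 content; message names the offending file/line."""


def _fmt(x: float) -> str:
    return "" if not np.isfinite(x) else repr(float(x))


def _write_single_map(tfm: TearFilmMap, meta: dict, path: Path) -> None:
    lines = [
        "format: TFQ-1",
        f"subject: {meta['subject']}",
        f"eye: {meta['eye']}",
        f"wear_days: {meta['wear_days']}",
        f"session: {tfm.session}",
        f"modality: {tfm.modality}",
        "flags: " + ",".join(sorted(tfm.artefact_flags)),
        "rings: " + ",".join(repr(float(r)) for r in tfm.grid.ring_radii),
        "angles: " + ",".join(repr(float(a)) for a in tfm.grid.meridian_angles),
    ]
    for row in tfm.values:
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_single_map(path: Path) -> tuple[TearFilmMap, dict]:
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    for i, key in enumerate(_HEADER_KEYS):
        if i >= len(lines):
            raise ParseError(f"{path}: truncated header, missing '{key}'")
        if ":" not in lines[i]:
            raise ParseError(f"{path}: line {i + 1}: expected '{key}: ...'")
        k, _, v = lines[i].partition(":")
        if k.strip() != key:
            raise ParseError(f"{path}: line {i + 1}: expected key '{key}', got '{k.strip()}'")
        header[key] = v.strip()
    if header["format"] != "TFQ-1":
        raise ParseError(f"{path}: unsupported format {header['format']!r}")
    try:
        rings = np.array([float(x) for x in header["rings"].split(",")])
        angles = np.array([float(x) for x in header["angles"].split(",")])
        grid = PolarGrid(ring_radii=rings, meridian_angles=angles)
    except ValueError as exc:
        raise ParseError(f"{path}: bad grid header: {exc}") from exc

    body = lines[len(_HEADER_KEYS):]
    if len(body) != grid.n_rings:
        raise ParseError(
            f"{path}: expected {grid.n_rings} value rows, found {len(body)}"
        )
    values = np.empty(grid.shape)
    for i, line in enumerate(body):
        cells = line.split(",")
        if len(cells) != grid.n_meridians:
            raise ParseError(
                f"{path}: line {len(_HEADER_KEYS) + i + 1}: expected "
                f"{grid.n_meridians} columns, found {len(cells)}"
            )
        for j, cell in enumerate(cells):
            cell = cell.strip()
            try:
                values[i, j] = np.nan if cell == "" else float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {len(_HEADER_KEYS) + i + 1}, column {j + 1}: "
                    f"bad value {cell!r}"
                ) from exc
    flags = frozenset(f for f in header["flags"].split(",") if f)
    tfm = TearFilmMap(grid=grid, values=values, modality=header["modality"],
                      session=header["session"], artefact_flags=flags)
    meta = {"subject": header["subject"], "eye": header["eye"],
            "wear_days": int(header["wear_days"])}
    return tfm, meta


def write_map_file(record: EyeRecord, path: str | Path) -> Path:
    """Serialise an EyeRecord: one TFQ-1 file per map plus a JSON sidecar.

    ``path`` is a base path without extension; returns the sidecar path
    (``<base>.json``), which is what :func:`read_map_file` consumes.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    meta = {"subject": record.subject_id, "eye": record.eye,
            "wear_days": record.wear_days}
    files = {}
    for name, suffix in _MAP_SUFFIXES.items():
        tfm = getattr(record, name if "curv" in name else f"{name}_map")
        if tfm is None:
            continue
        p = base.with_name(base.name + suffix)
        _write_single_map(tfm, meta, p)
        files[name] = p.name
    sidecar = base.with_suffix(".json")
    sidecar.write_text(json.dumps({**meta, "files": files}, indent=1,
                                  sort_keys=True) + "\n")
    return sidecar


def read_map_file(path: str | Path) -> EyeRecord:
    """Read an EyeRecord from its JSON sidecar (or base path without extension)."""
    sidecar = Path(path)
    if sidecar.suffix != ".json":
        sidecar = sidecar.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    meta = json.loads(sidecar.read_text())
    maps: dict[str, TearFilmMap] = {}
    for name, fname in meta["files"].items():
        tfm, map_meta = _read_single_map(sidecar.parent / fname)
        for key in ("subject", "eye", "wear_days"):
            expect = {"subject": meta["subject"], "eye": meta["eye"],
                      "wear_days": meta["wear_days"]}[key]
            if str(map_meta[key]) != str(expect):
                raise ValueError(
                    f"{sidecar.parent / fname}: inconsistent {key} "
                    f"({map_meta[key]!r} != {expect!r})"
                )
        maps[name] = tfm
    if "pre" not in maps or "post" not in maps:
        raise ValueError(f"{sidecar}: record needs both pre and post tear-quality maps")
    return EyeRecord(
        subject_id=meta["subject"], eye=meta["eye"], wear_days=int(meta["wear_days"]),
        pre_map=maps["pre"], post_map=maps["post"],
        pre_curvature=maps.get("pre_curvature"),
        post_curvature=maps.get("post_curvature"),
    )


def write_cohort(cohort: Cohort, directory: str | Path,
                 manifest_name: str = "manifest.json") -> Path:
    """Write every record plus a cohort manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        base = directory / f"{rec.subject_id}_{rec.eye}"
        sidecar = write_map_file(rec, base)
        entries.append({"subject": rec.subject_id, "eye": rec.eye,
                        "wear_days": rec.wear_days, "record": sidecar.name})
    manifest = directory / manifest_name
    manifest.write_text(json.dumps(
        {"format": "TFQ-1-manifest", "provenance": cohort.provenance,
         "records": entries},
        indent=1, sort_keys=True) + "\n")
    return manifest


def load_cohort(manifest: str | Path, logger=None) -> Cohort:
    """Load a cohort from a manifest; invalid records are skipped with a logged reason."""
    manifest = Path(manifest)
    data = json.loads(manifest.read_text())
    entries = data.get("records", [])
    if not entries:
        raise ValueError(f"{manifest}: empty manifest")
    keys = [(e["subject"], e["eye"]) for e in entries]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise ValueError(f"{manifest}: duplicate subject x eye keys: {dupes}")
    records = []
    for entry in entries:
        try:
            records.append(read_map_file(manifest.parent / entry["record"]))
        except (ValueError, OSError) as exc:
            if logger is not None:
                logger.warning("skipping record %s/%s: %s",
                               entry["subject"], entry["eye"], exc)
    return Cohort(records=records,
                  provenance={"source": "file", "manifest": str(manifest),
                              **data.get("provenance", {})})
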