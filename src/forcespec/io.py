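"""Plain-text containers: the FDC-TSV curve format and the manifest CSV.

FDC-TSV is a UTF-8 text format::

    # fdc-tsv v1
    # curve_id = sim-0001
    # mode = indentation
    # spring_constant_pN_per_nm = 120.0
    # velocity_nm_per_s = 5000.0
    # temperature_K = 310.0
    # sampling_rate_Hz = 4096.0
    # cell_id = cell-03            (optional)
    # group_label = Q              (optional)
    # annotation.true_E_kPa = 2.0  (optional, repeated)
    segment	height_nm	force_pN
    approach	7500.0	0.0
    ...

Floats are written with ``repr`` so that read(write(curve)) reproduces every
numeric value exactly. Segments with a sampling rate differing from the
header carry it in an optional ``# segment_sampling_rates_Hz`` key.

The manifest is a CSV with columns ``path,group_label,cell_id,mode`` listing
the curves of a study.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import CURVE_MODES, CurveValidationError, ForceCurve, Segment

REQUIRED_KEYS = (
    "curve_id",
    "mode",
    "spring_constant_pN_per_nm",
    "velocity_nm_per_s",
    "temperature_K",
    "sampling_rate_Hz",
)

COLUMN_HEADER = "segment\theight_nm\tforce_pN"


class FdcParseError(ValueError):
    """Malformed FDC-TSV input; the message names the offending line."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def write_curve(curve: ForceCurve, path) -> None:
    """Serialize a validated curve to FDC-TSV at ``path``."""
    curve.validate()
    lines = ["# fdc-tsv v1"]
    lines.append(f"# curve_id = {curve.curve_id}")
    lines.append(f"# mode = {curve.mode}")
    lines.append(f"# spring_constant_pN_per_nm = {float(curve.spring_constant)!r}")
    lines.append(f"# velocity_nm_per_s = {float(curve.velocity)!r}")
    lines.append(f"# temperature_K = {float(curve.temperature)!r}")
    lines.append(f"# sampling_rate_Hz = {float(curve.segments[0].sampling_rate)!r}")
    if curve.cell_id:
        lines.append(f"# cell_id = {curve.cell_id}")
    if curve.group_label:
        lines.append(f"# group_label = {curve.group_label}")
    rates = [float(seg.sampling_rate) for seg in curve.segments]
    if len(set(rates)) > 1:
        lines.append(
            "# segment_sampling_rates_Hz = " + ",".join(repr(r) for r in rates)
        )
    for key, value in curve.annotations.items():
        lines.append(f"# annotation.{key} = {value}")
    lines.append(COLUMN_HEADER)
    for seg in curve.segments:
        for h, f in zip(seg.height.tolist(), seg.force.tolist()):
            lines.append(f"{seg.kind}\t{h!r}\t{f!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_curve(path) -> ForceCurve:
    """Parse an FDC-TSV file into a validated :class:`ForceCurve`."""
    path = Path(path)
    meta: dict[str, str] = {}
    annotations: dict[str, str] = {}
    rows: list[tuple[str, float, float]] = []
    in_data = False
    with path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if in_data:
                    raise FdcParseError(path, line_no, "comment after data block")
                body = line[1:].strip()
                if "=" not in body:
                    continue  # free-form comment (e.g. the format tag)
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key.startswith("annotation."):
                    annotations[key[len("annotation."):]] = value
                else:
                    meta[key] = value
                continue
            if not in_data:
                if line != COLUMN_HEADER:
                    raise FdcParseError(
                        path, line_no, f"expected column header {COLUMN_HEADER!r}"
                    )
                in_data = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FdcParseError(path, line_no, f"expected 3 columns, got {len(parts)}")
            kind, h_s, f_s = parts
            try:
                h, f = float(h_s), float(f_s)
            except ValueError as exc:
                raise FdcParseError(path, line_no, f"non-numeric value: {exc}") from None
            if not (np.isfinite(h) and np.isfinite(f)):
                raise FdcParseError(path, line_no, "non-finite value")
            rows.append((kind, h, f))
    if not in_data:
        raise FdcParseError(path, 0, "no data block found")
    missing = [k for k in REQUIRED_KEYS if k not in meta]
    if missing:
        raise FdcParseError(path, 0, f"missing required header keys: {missing}")
    try:
        spring = float(meta["spring_constant_pN_per_nm"])
        velocity = float(meta["velocity_nm_per_s"])
        temperature = float(meta["temperature_K"])
        rate = float(meta["sampling_rate_Hz"])
    except ValueError as exc:
        raise FdcParseError(path, 0, f"non-numeric header value: {exc}") from None

    # split rows into contiguous same-kind blocks, preserving order
    segments: list[Segment] = []
    block_kind = None
    heights: list[float] = []
    forces: list[float] = []

    def flush():
        if block_kind is not None:
            segments.append(
                Segment(block_kind, np.array(heights), np.array(forces), rate)
            )

    for kind, h, f in rows:
        if kind != block_kind:
            flush()
            block_kind, heights, forces = kind, [], []
        heights.append(h)
        forces.append(f)
    flush()

    if "segment_sampling_rates_Hz" in meta:
        per_seg = [float(x) for x in meta["segment_sampling_rates_Hz"].split(",")]
        if len(per_seg) == len(segments):
            for seg, r in zip(segments, per_seg):
                seg.sampling_rate = r

    known = set(REQUIRED_KEYS) | {"cell_id", "group_label", "segment_sampling_rates_Hz"}
    for key, value in meta.items():
        if key not in known:
            annotations.setdefault(key, value)  # unknown keys preserved

    curve = ForceCurve(
        segments=segments,
        spring_constant=spring,
        velocity=velocity,
        temperature=temperature,
        mode=meta["mode"],
        curve_id=meta["curve_id"],
        cell_id=meta.get("cell_id", ""),
        group_label=meta.get("group_label", ""),
        annotations=annotations,
    )
    try:
        curve.validate()
    except CurveValidationError as exc:
        raise FdcParseError(path, 0, f"validation failed: {exc}") from exc
    return curve


@dataclass
class ManifestEntry:
    path: str
    group_label: str
    cell_id: str
    mode: str


@dataclass
class Manifest:
    """Listing of the curve files making up a study, with group labels."""

    entries: list[ManifestEntry]
    notes: str = ""
    base_dir: Path = field(default_factory=Path)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.group_label not in seen:
                seen.append(e.group_label)
        return seen


def read_manifest(path) -> Manifest:
    """Read a manifest CSV; raises on empty files, bad modes or duplicate paths."""
    path = Path(path)
    entries: list[ManifestEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "path",
            "group_label",
            "cell_id",
            "mode",
        } <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: manifest needs columns path,group_label,cell_id,mode"
            )
        for row in reader:
            if row["mode"] not in CURVE_MODES:
                raise ValueError(f"{path}: unknown mode {row['mode']!r}")
            entries.append(
                ManifestEntry(
                    row["path"], row["group_label"], row["cell_id"], row["mode"]
                )
            )
    if not entries:
        raise ValueError(f"{path}: no entries")
    paths = [e.path for e in entries]
    if len(set(paths)) != len(paths):
        raise ValueError(f"{path}: duplicate curve paths in manifest")
    return Manifest(entries=entries, base_dir=path.parent)


def write_manifest(manifest: Manifest, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "group_label", "cell_id", "mode"])
        for e in manifest.entries:
            writer.writerow([e.path, e.group_label, e.cell_id, e.mode])


def iter_manifest_curves(manifest: Manifest):
    """Yield ``(entry, curve_or_None, error_or_None)`` per manifest entry.

    Missing or unreadable files are reported per entry rather than aborting
    the whole load; duplicate curve_ids across loaded files raise.
    """
    seen_ids: set[str] = set()
    for entry in manifest.entries:
        p = Path(entry.path)
        if not p.is_absolute():
            p = manifest.base_dir / p
        try:
            curve = read_curve(p)
        except (OSError, ValueError) as exc:
            yield entry, None, exc
            continue
        if curve.curve_id in seen_ids:
            yield entry, None, ValueError(f"duplicate curve_id {curve.curve_id!r}")
            continue
        seen_ids.add(curve.curve_id)
        if entry.group_label:
            curve.group_label = entry.group_label
        if entry.cell_id:
            curve.cell_id = entry.cell_id
        yield entry, curve, None
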