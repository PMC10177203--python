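"""Case-structured histology dataset manifests.

Every pipeline stage consumes a :class:`DatasetManifest`: a flat table of
images, each belonging to exactly one *case* (a histological slide /
patient) carrying exactly one benign/malignant label.  The case is the
grouping unit that must never straddle a train/test split, so the manifest
enforces one-label-per-case at construction.

Two directory conventions are read natively:

* ``cmtd`` — per-case subdirectories named ``<label>_<caseID>/`` with
  ``label ∈ {benign, malignant}``, images directly inside.  This is the
  layout the synthetic generator writes.
* ``breakhis`` — the published BreakHis convention
  ``<label>/SOB/<subtype>/<patient>/<mag>X/<file>.png``.

Arbitrary layouts go through a flat CSV manifest (the escape hatch).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from PIL import Image

LABELS = ("benign", "malignant")

MANIFEST_COLUMNS = [
    "image_id",
    "path",
    "case_id",
    "label",
    "magnification",
    "width_px",
    "height_px",
]

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


class ManifestError(ValueError):
    """A dataset layout or manifest violates the documented contract."""


@dataclass(frozen=True)
class ImageRecord:
    """One image: identity, location, case membership and label."""

    image_id: str
    path: str  # relative to the manifest root, POSIX separators
    case_id: str
    label: str
    magnification: int
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ManifestError(
                f"label must be one of {LABELS}, got {self.label!r} "
                f"(image {self.image_id!r})"
            )
        if self.magnification <= 0 or self.width_px <= 0 or self.height_px <= 0:
            raise ManifestError(
                f"magnification/width/height must be positive (image {self.image_id!r})"
            )


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ImageRecord, ...]
    root: str
    layout: str  # {cmtd, breakhis, synthetic, flat-csv}

    def __post_init__(self) -> None:
        _validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def case_ids(self) -> tuple[str, ...]:
        """Distinct case ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.case_id, None)
        return tuple(seen)

    @property
    def case_labels(self) -> dict[str, str]:
        return {r.case_id: r.label for r in self.records}

    def abspath(self, record: ImageRecord) -> Path:
        return Path(self.root) / record.path

    def filter_magnification(self, magnification: int) -> "DatasetManifest":
        kept = tuple(r for r in self.records if r.magnification == magnification)
        return replace(self, records=kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in MANIFEST_COLUMNS] for r in self.records],
            columns=MANIFEST_COLUMNS,
        )


def _validate_records(records: tuple[ImageRecord, ...]) -> None:
    ids: set[str] = set()
    case_label: dict[str, str] = {}
    for r in records:
        if r.image_id in ids:
            raise ManifestError(f"duplicate image_id {r.image_id!r}")
        ids.add(r.image_id)
        prev = case_label.setdefault(r.case_id, r.label)
        if prev != r.label:
            raise ManifestError(
                f"case {r.case_id!r} carries two labels ({prev!r} and {r.label!r}); "
                "a case is one patient/slide and must have exactly one label"
            )


def _decode_size(path: Path) -> tuple[int, int]:
    try:
        with Image.open(path) as im:
            im.load()
            return im.width, im.height
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ManifestError(f"undecodable image file: {path}") from exc


def scan_cmtd_layout(root: str | Path, *, magnification: int = 400) -> DatasetManifest:
    """Scan a ``<label>_<caseID>/image.jpg`` tree into a manifest.

    Ordering is lexicographic by relative path, so the result is independent
    of filesystem enumeration order.  The single-magnification default of
    400× matches how such bench-microscope datasets are captured.
    """
    root = Path(root)
    if not root.is_dir():
        raise ManifestError(f"dataset root does not exist: {root}")
    records: list[ImageRecord] = []
    case_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not case_dirs:
        raise ManifestError(f"no case directories under {root}")
    for case_dir in case_dirs:
        name = case_dir.name
        label, sep, case_id = name.partition("_")
        if not sep or label not in LABELS or not case_id:
            raise ManifestError(
                f"case directory {case_dir} does not match the "
                "'<label>_<caseID>' convention with label in "
                f"{LABELS}"
            )
        files = sorted(
            p for p in case_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        for f in files:
            w, h = _decode_size(f)
            rel = f.relative_to(root).as_posix()
            records.append(
                ImageRecord(
                    image_id=rel,
                    path=rel,
                    case_id=case_id,
                    label=label,
                    magnification=magnification,
                    width_px=w,
                    height_px=h,
                )
            )
    return DatasetManifest(records=tuple(records), root=str(root), layout="cmtd")


_BREAKHIS_LABELS = {"benign": "benign", "malignant": "malignant"}


def scan_breakhis_layout(
    root: str | Path, *, magnification: int | None = None
) -> DatasetManifest:
    """Scan a BreakHis-convention tree (label/SOB/subtype/patient/magX/).

    ``case_id`` is the patient directory name (e.g. ``SOB_B_F_14-9133``);
    magnification is parsed from the ``<N>X`` path component.  Pass
    ``magnification`` to keep a single magnifying factor.
    """
    root = Path(root)
    if not root.is_dir():
        raise ManifestError(f"dataset root does not exist: {root}")
    records: list[ImageRecord] = []
    for f in sorted(root.rglob("*")):
        if not (f.is_file() and f.suffix.lower() in _IMAGE_SUFFIXES):
            continue
        rel = f.relative_to(root)
        parts = rel.parts
        # label / SOB / subtype / patient / <mag>X / file
        if len(parts) < 6:
            raise ManifestError(
                f"path does not follow the BreakHis convention "
                f"(label/SOB/subtype/patient/magX/file): {f}"
            )
        label_token = parts[0].lower()
        if label_token not in _BREAKHIS_LABELS:
            raise ManifestError(f"unrecognized label component {parts[0]!r} in {f}")
        mag_token = parts[-2]
        if not (mag_token.endswith("X") and mag_token[:-1].isdigit()):
            raise ManifestError(f"unparseable magnification component {mag_token!r} in {f}")
        mag = int(mag_token[:-1])
        if magnification is not None and mag != magnification:
            continue
        w, h = _decode_size(f)
        records.append(
            ImageRecord(
                image_id=rel.as_posix(),
                path=rel.as_posix(),
                case_id=parts[-3],
                label=_BREAKHIS_LABELS[label_token],
                magnification=mag,
                width_px=w,
                height_px=h,
            )
        )
    if not records:
        raise ManifestError(f"no images found under {root}")
    return DatasetManifest(records=tuple(records), root=str(root), layout="breakhis")


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the manifest as canonical UTF-8 CSV (rewrite is byte-identical)."""
    frame = manifest.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_manifest(
    path: str | Path, *, root: str | Path | None = None, layout: str = "flat-csv"
) -> DatasetManifest:
    """Read a CSV manifest; validates columns, id uniqueness, case labels.

    ``root`` defaults to the CSV's directory (paths are stored relative).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ImageRecord(
                image_id=row.image_id,
                path=row.path,
                case_id=row.case_id,
                label=row.label,
                magnification=int(row.magnification),
                width_px=int(row.width_px),
                height_px=int(row.height_px),
            )
        )
    if root is None:
        root = path.parent
    return DatasetManifest(records=tuple(records), root=str(root), layout=layout)
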