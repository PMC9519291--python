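"""Reading per-tooth annotations into records and radiograph-level splitting.

A *ToothRecord* is one annotated tooth: the radiograph it came from, its FDI
position string, the cropped grayscale image, a binary caries label
(1 = caries) and a presence flag. Missing teeth are carried as records with
``present = False`` and no image so positional bookkeeping stays intact.

Two annotation dialects are read, sharing one record model:

* a VIA-style region JSON — per image: ``filename``, rectangle
  ``shape_attributes`` (x/y/width/height) and ``region_attributes`` with
  ``fdi`` and ``caries``; missing positions may be listed in the image's
  ``file_attributes["missing"]`` (space-separated FDI codes);
* a flat CSV with columns ``radiograph_id, fdi, x, y, w, h, label`` where a
  row with empty box fields marks a missing tooth.

Box coordinates are 0-based, half-open pixel rectangles
``[x, x+w) x [y, y+h)``.

Dataset splitting is at radiograph level: all teeth of a radiograph land in
the same partition, so neighbor lookups during training can never touch
another partition's images.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ToothRecord",
    "ToothDataset",
    "DatasetSplit",
    "load_annotations",
    "save_records",
    "load_records",
    "split_by_radiograph",
]

_IMG_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class ToothRecord:
    radiograph_id: str
    position: str
    image: np.ndarray | None = None
    label: int | None = None
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and (self.image is None or self.image.size == 0):
            raise ValueError(
                f"present tooth ({self.radiograph_id}, {self.position}) has no image"
            )


@dataclass
class ToothDataset(Sequence):
    """Sequence of ToothRecords plus a load summary."""

    records: list[ToothRecord] = field(default_factory=list)
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[ToothRecord]:
        return iter(self.records)

    def radiograph_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.radiograph_id, None)
        return list(seen)


def _read_grayscale(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except Exception as exc:  # noqa: BLE001 - re-raise with the filename
        raise OSError(f"cannot read radiograph image {path}") from exc


def _resolve_image(image_dir: Path, name: str) -> Path | None:
    p = image_dir / name
    if p.exists():
        return p
    for ext in _IMG_EXTENSIONS:
        q = image_dir / (name + ext)
        if q.exists():
            return q
    return None


def _parse_label(raw) -> int:
    if isinstance(raw, bool):
        return int(raw)
    s = str(raw).strip().lower()
    if s in ("1", "caries", "true", "yes"):
        return 1
    if s in ("0", "normal", "sound", "false", "no"):
        return 0
    raise ValueError(f"unrecognized caries label {raw!r}")


def _crop(image: np.ndarray, x: int, y: int, w: int, h: int) -> np.ndarray:
    if w <= 0 or h <= 0:
        raise ValueError("box has non-positive size")
    if x < 0 or y < 0 or x + w > image.shape[1] or y + h > image.shape[0]:
        raise ValueError("box exceeds image bounds")
    return image[y : y + h, x : x + w].copy()


class _Collector:
    """Accumulates records, enforcing (radiograph, position) uniqueness."""

    def __init__(self) -> None:
        self.ds = ToothDataset()
        self._seen: set[tuple[str, str]] = set()

    def add(self, rec: ToothRecord) -> None:
        key = (rec.radiograph_id, rec.position)
        if key in self._seen:
            raise ValueError(f"duplicate tooth annotation {key}")
        self._seen.add(key)
        self.ds.records.append(rec)

    def skip(self, why: str) -> None:
        logger.warning("skipping annotation entry: %s", why)
        self.ds.n_skipped += 1
        self.ds.messages.append(why)


def _load_via(path: Path, image_dir: Path, out: _Collector) -> None:
    with open(path) as fh:
        data = json.load(fh)
    if "_via_img_metadata" in data:
        data = data["_via_img_metadata"]
    for entry in data.values():
        if not isinstance(entry, dict) or "filename" not in entry:
            out.skip(f"VIA entry without filename in {path.name}")
            continue
        fname = entry["filename"]
        rid = Path(fname).stem
        img_path = _resolve_image(image_dir, fname)
        if img_path is None:
            raise OSError(f"cannot read radiograph image {image_dir / fname}")
        image = _read_grayscale(img_path)
        for region in entry.get("regions", []):
            try:
                sa = region["shape_attributes"]
                ra = region["region_attributes"]
                crop = _crop(
                    image,
                    int(sa["x"]),
                    int(sa["y"]),
                    int(sa["width"]),
                    int(sa["height"]),
                )
                rec = ToothRecord(
                    radiograph_id=rid,
                    position=str(ra["fdi"]),
                    image=crop,
                    label=_parse_label(ra["caries"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                out.skip(f"{rid}: {exc}")
                continue
            out.add(rec)
        missing = str(entry.get("file_attributes", {}).get("missing", "")).split()
        for pos in missing:
            out.add(ToothRecord(radiograph_id=rid, position=pos, present=False))


def _load_csv(path: Path, image_dir: Path, out: _Collector) -> None:
    cache: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rid = (row.get("radiograph_id") or "").strip()
            pos = (row.get("fdi") or "").strip()
            if not rid or not pos:
                out.skip(f"CSV row without radiograph_id/fdi: {row}")
                continue
            box = [(row.get(c) or "").strip() for c in ("x", "y", "w", "h")]
            if all(v == "" for v in box):  # missing tooth
                out.add(ToothRecord(radiograph_id=rid, position=pos, present=False))
                continue
            if rid not in cache:
                img_path = _resolve_image(image_dir, rid)
                if img_path is None:
                    raise OSError(f"cannot read radiograph image {image_dir / rid}")
                cache[rid] = _read_grayscale(img_path)
            try:
                x, y, w, h = (int(v) for v in box)
                rec = ToothRecord(
                    radiograph_id=rid,
                    position=pos,
                    image=_crop(cache[rid], x, y, w, h),
                    label=_parse_label(row.get("label")),
                )
            except (TypeError, ValueError) as exc:
                out.skip(f"{rid}/{pos}: {exc}")
                continue
            out.add(rec)


def load_annotations(annotation_file: str | Path, image_dir: str | Path) -> ToothDataset:
    """Read a VIA-region JSON or flat CSV annotation file into ToothRecords.

    Malformed entries are skipped with a logged warning and counted in the
    returned dataset's ``n_skipped``; an unreadable radiograph image raises
    ``OSError`` naming the file; a duplicate (radiograph, position) pair
    raises ``ValueError``.
    """
    annotation_file = Path(annotation_file)
    image_dir = Path(image_dir)
    if not annotation_file.exists():
        raise FileNotFoundError(annotation_file)
    out = _Collector()
    if annotation_file.suffix.lower() == ".json":
        _load_via(annotation_file, image_dir, out)
    elif annotation_file.suffix.lower() == ".csv":
        _load_csv(annotation_file, image_dir, out)
    else:
        raise ValueError(f"unsupported annotation format: {annotation_file.suffix}")
    if out.ds.n_skipped:
        logger.warning(
            "loaded %d tooth records, skipped %d malformed entries",
            len(out.ds),
            out.ds.n_skipped,
        )
    return out.ds


def save_records(records: Sequence[ToothRecord], out_dir: str | Path, overwrite: bool = False) -> Path:
    """Serialize records to a directory: ``records.csv`` plus lossless PNG crops."""
    out_dir = Path(out_dir)
    index = out_dir / "records.csv"
    if index.exists() and not overwrite:
        raise FileExistsError(index)
    (out_dir / "crops").mkdir(parents=True, exist_ok=True)
    with open(index, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["radiograph_id", "position", "label", "present", "crop"])
        for rec in records:
            crop_name = ""
            if rec.present:
                crop_name = f"crops/{rec.radiograph_id}_{rec.position}.png"
                Image.fromarray(np.asarray(rec.image, dtype=np.uint8)).save(out_dir / crop_name)
            writer.writerow(
                [
                    rec.radiograph_id,
                    rec.position,
                    "" if rec.label is None else int(rec.label),
                    int(rec.present),
                    crop_name,
                ]
            )
    return index


def load_records(in_dir: str | Path) -> ToothDataset:
    """Inverse of :func:`save_records`."""
    in_dir = Path(in_dir)
    ds = ToothDataset()
    with open(in_dir / "records.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            present = bool(int(row["present"]))
            image = None
            if present:
                with Image.open(in_dir / row["crop"]) as im:
                    image = np.asarray(im.convert("L"), dtype=np.uint8)
            ds.records.append(
                ToothRecord(
                    radiograph_id=row["radiograph_id"],
                    position=row["position"],
                    image=image,
                    label=int(row["label"]) if row["label"] != "" else None,
                    present=present,
                )
            )
    return ds


@dataclass(frozen=True)
class DatasetSplit:
    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]

    def partition_of(self, radiograph_id: str) -> str:
        for name in ("train", "validation", "test"):
            if radiograph_id in getattr(self, name):
                return name
        raise KeyError(radiograph_id)

    def select(self, records: Sequence[ToothRecord], partition: str) -> list[ToothRecord]:
        ids = getattr(self, partition)
        return [r for r in records if r.radiograph_id in ids]

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["radiograph_id", "partition"])
            for name in ("train", "validation", "test"):
                for rid in sorted(getattr(self, name)):
                    writer.writerow([rid, name])

    @classmethod
    def load(cls, path: str | Path) -> "DatasetSplit":
        parts: dict[str, set[str]] = {"train": set(), "validation": set(), "test": set()}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                parts[row["partition"]].add(row["radiograph_id"])
        return cls(*(frozenset(parts[k]) for k in ("train", "validation", "test")))


def split_by_radiograph(
    records: Sequence[ToothRecord] | Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle radiograph ids with ``seed`` and partition by ``fractions``.

    Partition sizes are the largest-remainder rounding of ``fraction * n``,
    so they always sum to the total. All teeth of a radiograph inherit its
    partition.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive reals")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-6):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if records and isinstance(records[0], ToothRecord):
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.radiograph_id, None)
        ids = list(seen)
    else:
        ids = list(dict.fromkeys(records))
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 radiographs to split, got {n}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    raw = [f * n for f in fractions]
    counts = [int(math.floor(v)) for v in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    a, b = counts[0], counts[0] + counts[1]
    return DatasetSplit(
        train=frozenset(order[:a]),
        validation=frozenset(order[a:b]),
        test=frozenset(order[b:]),
    )
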