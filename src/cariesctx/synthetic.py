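"""Synthetic pseudo-radiograph cohorts with mouth-correlated caries labels.

The generator reproduces the statistical structure the context-aware
classifier exploits, not radiographic realism:

* each mouth m draws a caries propensity theta_m ~ Beta(alpha, beta), so
  labels are correlated within a mouth (beta-binomial intra-class
  correlation 1/(alpha+beta+1) when contagion = 0);
* a single *contagion* sweep in fixed arch order re-samples every tooth
  with log-odds  logit(theta_m) + contagion * (# carious K=3 neighbors),
  inducing extra correlation between anatomically adjacent teeth;
* each tooth crop is a bright crown-plus-roots shape on a darker
  background; a carious tooth additionally carries a radiolucent (darker)
  elliptical blob of depth ``lesion_contrast`` at the crown margin;
* teeth are dropped independently with probability ``missing_rate``;
* crop height and width are sampled per tooth from ``crop_side_range``
  (annotation boxes are deliberately variable-sized).

``generate_cohort`` writes composite per-radiograph images, a VIA-style
annotation JSON and a ground-truth CSV, byte-identical for a fixed seed, so
the full disk pipeline is exercised; ``generate_records`` is the in-memory
fast path used by the experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data import ToothRecord
from .topology import ALL_POSITIONS, arch_order, neighbor_set

__all__ = ["SyntheticConfig", "sample_labels", "render_tooth", "generate_records", "generate_cohort"]

_SWEEP_ORDER = tuple(arch_order("upper") + arch_order("lower"))
_K3 = {p: tuple(neighbor_set(p, 3)) for p in ALL_POSITIONS}


@dataclass(frozen=True)
class SyntheticConfig:
    n_radiographs: int = 300
    propensity_alpha: float = 2.0
    propensity_beta: float = 2.0
    contagion: float = 1.0
    missing_rate: float = 0.02
    crop_side_range: tuple[int, int] = (48, 96)
    lesion_contrast: float = 40.0
    noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_radiographs < 1:
            raise ValueError("n_radiographs must be >= 1")
        if self.propensity_alpha <= 0 or self.propensity_beta <= 0:
            raise ValueError("Beta propensity parameters must be positive")
        if self.contagion < 0:
            raise ValueError("contagion must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")
        lo, hi = self.crop_side_range
        if lo < 16 or hi < lo:
            raise ValueError("crop sides must be >= 16 and ordered")


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def sample_labels(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[dict[str, int | None]]:
    """Per-radiograph maps FDI code -> 1 (caries), 0 (sound) or None (absent)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    out: list[dict[str, int | None]] = []
    for _ in range(config.n_radiographs):
        theta = rng.beta(config.propensity_alpha, config.propensity_beta)
        base_logit = np.log(theta) - np.log1p(-theta)
        labels = {p: int(rng.random() < theta) for p in _SWEEP_ORDER}
        for p in _SWEEP_ORDER:
            n_car = sum(labels[q] for q in _K3[p])
            prob = _sigmoid(base_logit + config.contagion * n_car)
            labels[p] = int(rng.random() < prob)
        mouth: dict[str, int | None] = {}
        for p in _SWEEP_ORDER:
            absent = rng.random() < config.missing_rate
            mouth[str(p)] = None if absent else labels[p]
        out.append(mouth)
    return out


def render_tooth(
    position: str, label: int, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one tooth crop (uint8, values in [0,255]).

    Geometry scales with the FDI index: molars (index 4-5) are wider and get
    two root lobes, incisors one. The same random draws are consumed for
    sound and carious teeth, so renders at equal rng state differ only by
    the lesion blob.
    """
    lo, hi = config.crop_side_range
    h = int(rng.integers(lo, hi + 1))
    w = int(rng.integers(lo, hi + 1))
    index = int(str(position)[-1]) if str(position)[-1].isdigit() else 3
    yy, xx = np.ogrid[:h, :w]

    img = np.full((h, w), 60.0)

    # crown: bright ellipse in the upper part of the crop
    cy, cx = 0.33 * h, 0.5 * w
    crown_ry = 0.24 * h
    crown_rx = (0.16 + 0.05 * index) * w / 2 * 2  # wider for molars
    crown = ((yy - cy) / crown_ry) ** 2 + ((xx - cx) / crown_rx) ** 2 <= 1.0
    img[crown] = 175.0

    # roots: narrow lobes below the crown
    n_roots = 2 if index >= 4 else 1
    root_ry = 0.30 * h
    root_rx = 0.07 * w
    root_cy = 0.70 * h
    offsets = (-0.6, 0.6) if n_roots == 2 else (0.0,)
    for off in offsets:
        rcx = cx + off * crown_rx * 0.7
        root = ((yy - root_cy) / root_ry) ** 2 + ((xx - rcx) / root_rx) ** 2 <= 1.0
        img[root] = 150.0

    # lesion geometry is always sampled so rng state stays label-independent
    side = 1.0 if rng.random() < 0.5 else -1.0
    les_cy = cy + rng.uniform(-0.3, 0.3) * crown_ry
    les_cx = cx + side * crown_rx * rng.uniform(0.5, 0.9)
    les_ry = max(2.0, 0.10 * h * rng.uniform(0.8, 1.2))
    les_rx = max(2.0, 0.09 * w * rng.uniform(0.8, 1.2))
    if label == 1:
        lesion = ((yy - les_cy) / les_ry) ** 2 + ((xx - les_cx) / les_rx) ** 2 <= 1.0
        img[lesion] -= config.lesion_contrast

    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def generate_records(
    config: SyntheticConfig,
) -> tuple[list[ToothRecord], list[dict[str, int | None]]]:
    """In-memory cohort: ToothRecords (incl. absent ones) plus the label maps."""
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_render = (np.random.default_rng(s) for s in ss.spawn(2))
    label_maps = sample_labels(config, rng_labels)
    records: list[ToothRecord] = []
    for i, mouth in enumerate(label_maps):
        rid = f"radiograph_{i:04d}"
        for pos, lab in mouth.items():
            if lab is None:
                records.append(ToothRecord(rid, pos, present=False))
            else:
                img = render_tooth(pos, lab, config, rng_render)
                records.append(ToothRecord(rid, pos, image=img, label=lab))
    return records, label_maps


_GAP = 6


def _compose_radiograph(
    mouth_records: list[ToothRecord],
) -> tuple[np.ndarray, list[tuple[str, int, int, int, int]]]:
    """Place the mouth's crops on a two-row canvas; return canvas + boxes."""
    upper = [str(p) for p in arch_order("upper")]
    rows = [
        [r for r in mouth_records if r.present and r.position in upper],
        [r for r in mouth_records if r.present and r.position not in upper],
    ]
    row_h = [max((r.image.shape[0] for r in row), default=16) for row in rows]
    width = max(
        (sum(r.image.shape[1] for r in row) + _GAP * (len(row) + 1) for row in rows),
        default=64,
    )
    canvas = np.full((row_h[0] + row_h[1] + 3 * _GAP, max(width, 64)), 40, dtype=np.uint8)
    boxes: list[tuple[str, int, int, int, int]] = []
    y = _GAP
    for row, rh in zip(rows, row_h):
        x = _GAP
        for rec in row:
            ih, iw = rec.image.shape
            canvas[y : y + ih, x : x + iw] = rec.image
            boxes.append((rec.position, x, y, iw, ih))
            x += iw + _GAP
        y += rh + _GAP
    return canvas, boxes


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path, overwrite: bool = False
) -> Path:
    """Write composite images, VIA annotations and a ground-truth CSV.

    Returns the path of the annotation JSON. Raises ``FileExistsError`` on
    collision unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    ann_path = out_dir / "annotations.json"
    truth_path = out_dir / "truth.csv"
    img_dir = out_dir / "images"
    if ann_path.exists() and not overwrite:
        raise FileExistsError(ann_path)
    img_dir.mkdir(parents=True, exist_ok=True)

    records, label_maps = generate_records(config)
    by_rid: dict[str, list[ToothRecord]] = {}
    for rec in records:
        by_rid.setdefault(rec.radiograph_id, []).append(rec)

    via: dict[str, dict] = {}
    truth_lines = ["radiograph_id,fdi,label,present"]
    for rid, mouth_records in by_rid.items():
        canvas, boxes = _compose_radiograph(mouth_records)
        fname = f"{rid}.png"
        Image.fromarray(canvas).save(img_dir / fname)
        size = (img_dir / fname).stat().st_size
        labels = {r.position: r.label for r in mouth_records}
        regions = [
            {
                "shape_attributes": {
                    "name": "rect",
                    "x": x,
                    "y": y,
                    "width": w,
                    "height": h,
                },
                "region_attributes": {"fdi": pos, "caries": str(labels[pos])},
            }
            for pos, x, y, w, h in boxes
        ]
        missing = " ".join(r.position for r in mouth_records if not r.present)
        via[f"{fname}{size}"] = {
            "filename": fname,
            "size": size,
            "regions": regions,
            "file_attributes": {"missing": missing} if missing else {},
        }
        for rec in mouth_records:
            lab = "" if rec.label is None else rec.label
            truth_lines.append(f"{rid},{rec.position},{lab},{int(rec.present)}")

    with open(ann_path, "w") as fh:
        json.dump(via, fh, indent=1, sort_keys=True)
    truth_path.write_text("\n".join(truth_lines) + "\n")
    return ann_path
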