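"""File interfaces: detection tables, per-stem measurements, plot traits.

Detections travel as CSV with columns
``plot_id, image_id, xmin, ymin, xmax, ymax, score`` (coordinates in
parent-image pixels) or as an equivalent JSON array of objects with the same
keys. Per-stem measurements and plot traits are written as documented CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .diameter import StemMeasurement
from .geometry import Box, Detection
from .traits import PlotTraits

__all__ = [
    "DETECTION_COLUMNS",
    "read_detections",
    "write_detections",
    "write_measurements",
    "write_plot_traits",
]

DETECTION_COLUMNS = ["plot_id", "image_id", "xmin", "ymin", "xmax", "ymax", "score"]


def _detection_from_record(rec: dict, rownum) -> Detection:
    try:
        box = Box(float(rec["xmin"]), float(rec["ymin"]),
                  float(rec["xmax"]), float(rec["ymax"]))
        score = float(rec["score"])
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        return Detection(box=box, score=score)
    except (ValueError, TypeError, KeyError) as exc:
        raise ValueError(f"malformed detection row {rownum}: {exc}") from exc


def read_detections(path, format: str | None = None,
                    image_size: tuple[int, int] | None = None):
    """Read detections grouped by (plot_id, image_id).

    ``format`` is 'csv' or 'json'; inferred from the suffix when omitted.
    When ``image_size`` (width, height) is known, boxes extending outside the
    image are rejected. Malformed rows raise with their row number. Returns
    ``dict[(plot_id, image_id) -> list[Detection]]``.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        unknown = set(df.columns) - set(DETECTION_COLUMNS)
        if unknown:
            raise ValueError(f"unknown detection column(s): {sorted(unknown)}")
        missing = set(DETECTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing detection column(s): {sorted(missing)}")
        records = df.to_dict("records")
    elif fmt == "json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError("JSON detections must be an array of objects")
    else:
        raise ValueError(f"unknown detection format {fmt!r}")

    grouped: dict[tuple[str, str], list[Detection]] = {}
    for i, rec in enumerate(records):
        det = _detection_from_record(rec, i + 1)
        if image_size is not None:
            w, h = image_size
            b = det.box
            if b.xmin < 0 or b.ymin < 0 or b.xmax > w or b.ymax > h:
                raise ValueError(f"row {i + 1}: box outside the {w}x{h} image")
        key = (str(rec.get("plot_id", "")), str(rec.get("image_id", "")))
        grouped.setdefault(key, []).append(det)
    return grouped


def write_detections(path, detections, plot_id: str = "", image_id: str = "",
                     format: str | None = None) -> None:
    """Write a flat list of detections for one image, CSV or JSON."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    rows = [
        {
            "plot_id": plot_id,
            "image_id": image_id,
            "xmin": d.box.xmin,
            "ymin": d.box.ymin,
            "xmax": d.box.xmax,
            "ymax": d.box.ymax,
            "score": d.score,
        }
        for d in detections
    ]
    if fmt == "csv":
        pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise ValueError(f"unknown detection format {fmt!r}")


def write_measurements(path, measurements: list[StemMeasurement],
                       plot_id: str = "", image_id: str = "") -> None:
    """Per-stem CSV: box, score, per-direction and mean diameters, validity."""
    rows = []
    for m in measurements:
        b = m.detection.box
        d = dict(zip(("d0", "d45", "d90", "d135"), m.per_direction_px))
        rows.append(
            {
                "plot_id": plot_id,
                "image_id": image_id,
                "xmin": b.xmin, "ymin": b.ymin, "xmax": b.xmax, "ymax": b.ymax,
                "score": m.detection.score,
                **d,
                "mean_px": m.mean_diameter_px,
                "diameter_mm": m.diameter_mm,
                "valid": m.valid,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_plot_traits(path, traits: list[PlotTraits],
                      genotypes: dict[str, str] | None = None) -> None:
    """Plot-level traits CSV with the distribution fit alongside."""
    rows = []
    for t in traits:
        dist = t.distribution
        rows.append(
            {
                "plot_id": t.plot_id,
                "genotype": (genotypes or {}).get(t.plot_id, ""),
                "n_stems": t.n_stems,
                "sampled_area_m2": t.sampled_area_m2,
                "stem_density": t.stem_density,
                "mean_diameter_mm": t.mean_diameter_mm,
                "dist_family": dist.family if dist else "",
                "shape": dist.shape if dist and dist.family == "gamma" else None,
                "scale": dist.scale if dist and dist.family == "gamma" else None,
                "p_value": dist.p_value if dist else None,
                "height_m": t.height_m,
                "basal_area": t.basal_area,
                "biovolume": t.biovolume,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)
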