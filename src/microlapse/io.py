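"""Reading and writing time-lapse stacks, result tables and manifests.

File layout: one multi-page grayscale TIFF per (position, channel), pages
ordered by time, named ``<position>_<channel>.tif`` with positions named
``r<row>c<col>`` row-major in the grid.  A ``manifest.json`` in the same
directory carries the time base, grid shape, metadata and any frames that
are explicitly missing; when no manifest is present, names are parsed and a
default time base (first frame = 0 h, configurable interval) is assumed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig

__all__ = [
    "TimelapseDataset",
    "ManifestError",
    "DimensionMismatchError",
    "TimeBaseError",
    "load_timelapse",
    "save_timelapse",
    "write_results",
    "read_cfu_table",
]

_NAME_RE = re.compile(r"^(?P<pos>r\d+c\d+)_(?P<ch>[a-zA-Z0-9]+)\.tiff?$")

REQUIRED_CHANNELS = ("brightfield", "pi")


class ManifestError(ValueError):
    """File names or manifest entries cannot be interpreted."""


class DimensionMismatchError(ValueError):
    """Frames at one position disagree in shape."""


class TimeBaseError(ValueError):
    """The time base does not start at zero or is not increasing."""


@dataclass
class TimelapseDataset:
    """A position x time x channel stack of 2-D grayscale frames.

    ``frames`` maps (position id, time index, channel) to an image; keys in
    ``missing`` are acquisitions that are known absent (recorded, never
    silently skipped).
    """

    positions: list[str]
    grid_shape: tuple[int, int]
    frame_times: list[float]
    channels: list[str]
    frames: dict[tuple[str, int, str], np.ndarray]
    missing: set[tuple[str, int, str]] = dc_field(default_factory=set)
    metadata: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        r, c = self.grid_shape
        if r * c != len(self.positions):
            raise ManifestError(
                f"grid {r}x{c} does not match {len(self.positions)} positions")
        if not self.frame_times or self.frame_times[0] != 0.0:
            raise TimeBaseError("frame_times must start at 0 (time zero = agar addition)")
        if np.any(np.diff(self.frame_times) <= 0):
            raise TimeBaseError("frame_times must be strictly increasing")
        for ch in REQUIRED_CHANNELS:
            if ch not in self.channels:
                raise ManifestError(f"channel {ch!r} is required")
        shapes: dict[str, tuple[int, ...]] = {}
        for pos in self.positions:
            for t in range(len(self.frame_times)):
                for ch in self.channels:
                    key = (pos, t, ch)
                    if key in self.frames:
                        shp = self.frames[key].shape
                        if shapes.setdefault(pos, shp) != shp:
                            raise DimensionMismatchError(
                                f"position {pos}: {shp} != {shapes[pos]}")
                    elif key not in self.missing:
                        raise ManifestError(f"frame {key} neither present nor marked missing")

    def get(self, position: str, t_index: int, channel: str) -> np.ndarray:
        return self.frames[(position, t_index, channel)]

    def stack(self, position: str, channel: str) -> list[np.ndarray | None]:
        return [self.frames.get((position, t, channel))
                for t in range(len(self.frame_times))]


def save_timelapse(dataset: TimelapseDataset, out_dir: str | Path) -> Path:
    """Write one multi-page TIFF per (position, channel) plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}
    pages: dict[str, list[int]] = {}
    for pos in dataset.positions:
        files[pos] = {}
        for ch in dataset.channels:
            stack, t_present = [], []
            for t in range(len(dataset.frame_times)):
                img = dataset.frames.get((pos, t, ch))
                if img is not None:
                    stack.append(img)
                    t_present.append(t)
            if not stack:
                continue
            name = f"{pos}_{ch}.tif"
            tifffile.imwrite(out / name, np.stack(stack), photometric="minisblack")
            files[pos][ch] = name
            pages[name] = t_present
    manifest = {
        "grid_shape": list(dataset.grid_shape),
        "positions": dataset.positions,
        "frame_times": dataset.frame_times,
        "channels": dataset.channels,
        "metadata": dataset.metadata,
        "files": files,
        "pages": pages,
        "missing": sorted([list(k) for k in dataset.missing]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def load_timelapse(path: str | Path, config: AnalysisConfig | None = None) -> TimelapseDataset:
    """Load a dataset from a directory (manifest-driven if one is present,
    otherwise by parsing ``<pos>_<channel>.tif`` names).

    Missing acquisitions are recorded in ``dataset.missing``; inconsistent
    frame shapes raise :class:`DimensionMismatchError` and unparseable names
    raise :class:`ManifestError`.
    """
    p = Path(path)
    manifest_path = p if p.name.endswith(".json") else p / "manifest.json"
    root = manifest_path.parent
    if manifest_path.exists():
        man = json.loads(manifest_path.read_text())
        positions = list(man["positions"])
        frame_times = [float(t) for t in man["frame_times"]]
        channels = list(man["channels"])
        grid = tuple(man["grid_shape"])
        metadata = man.get("metadata", {})
        files = man["files"]
        pages = man.get("pages", {})
        missing = {tuple(k) for k in man.get("missing", [])}
        frames: dict[tuple[str, int, str], np.ndarray] = {}
        for pos in positions:
            for ch in channels:
                name = files.get(pos, {}).get(ch)
                if name is None:
                    missing.update((pos, t, ch) for t in range(len(frame_times)))
                    continue
                stack = tifffile.imread(root / name)
                if stack.ndim == 2:
                    stack = stack[None]
                t_present = pages.get(name, list(range(stack.shape[0])))
                for t, img in zip(t_present, stack):
                    frames[(pos, int(t), ch)] = img
                missing.update((pos, t, ch) for t in range(len(frame_times))
                               if t not in set(t_present))
    else:
        if not root.is_dir():
            raise ManifestError(f"{path} is not a dataset directory or manifest")
        tifs = sorted(root.glob("*.tif")) + sorted(root.glob("*.tiff"))
        if not tifs:
            raise ManifestError(f"no TIFF files under {root}")
        parsed = []
        for f in tifs:
            m = _NAME_RE.match(f.name)
            if m is None:
                raise ManifestError(f"cannot parse file name {f.name!r} "
                                    "(expected r<row>c<col>_<channel>.tif)")
            parsed.append((m["pos"], m["ch"], f))
        positions = sorted({pos for pos, _, _ in parsed},
                           key=lambda s: tuple(int(x) for x in re.findall(r"\d+", s)))
        channels = sorted({ch for _, ch, _ in parsed})
        rows = 1 + max(int(re.findall(r"\d+", pos)[0]) for pos in positions)
        cols = 1 + max(int(re.findall(r"\d+", pos)[1]) for pos in positions)
        grid = (rows, cols)
        frames = {}
        n_t = 0
        for pos, ch, f in parsed:
            stack = tifffile.imread(f)
            if stack.ndim == 2:
                stack = stack[None]
            n_t = max(n_t, stack.shape[0])
            for t, img in enumerate(stack):
                frames[(pos, t, ch)] = img
        dt = config.frame_interval if config is not None else 1.0
        frame_times = [dt * t for t in range(n_t)]
        missing = {(pos, t, ch) for pos in positions for t in range(n_t)
                   for ch in channels if (pos, t, ch) not in frames}
        metadata = {"frame_interval_h": dt}

    ds = TimelapseDataset(positions=positions, grid_shape=grid,  # type: ignore[arg-type]
                          frame_times=frame_times, channels=channels,
                          frames=frames, missing=missing, metadata=metadata)
    ds.validate()
    return ds


FOUNDER_COLUMNS = [
    "founder_id", "position", "centroid_row", "centroid_col", "area_t0",
    "label_class", "pi_positive_t0", "max_area_ratio", "censored",
    "fittable", "lag_h", "mu_max", "y0", "ymax", "h0", "rmse", "n_points",
]


def write_results(founder_table: pd.DataFrame, summary: dict | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the per-founder CSV (deterministic column order) and, when
    given, the condition-summary JSON.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = founder_table.copy()
    for col in FOUNDER_COLUMNS:
        if col not in table.columns:
            table[col] = pd.NA
    table = table[FOUNDER_COLUMNS]
    csv_path = out / "founders.csv"
    table.to_csv(csv_path, index=False)
    paths = {"founders": csv_path}
    if summary is not None:
        sp = out / "summary.json"
        sp.write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
        paths["summary"] = sp
    return paths


def read_cfu_table(path: str | Path) -> pd.DataFrame:
    """CFU counts: columns condition, replicate, cfu_control, cfu_treatment."""
    df = pd.read_csv(path)
    required = {"condition", "replicate", "cfu_control", "cfu_treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"CFU table missing columns: {sorted(missing)}")
    return df
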