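"""Readers, writers, run configuration and logging.

Tables are CSV (comma, dot decimal, UTF-8, header required); count
matrices may also be TSV or MatrixMarket.  Images are 16-bit TIFF or 8-bit
PNG with the pixel size supplied by a JSON sidecar (``<image>.json`` with
a ``px_size_um`` key) or explicitly — never silently defaulted.  Run
configurations are YAML with unknown keys rejected; run logs are JSON
lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .growthdev import DevEvents, GrowthTrajectory
from .lipidome import LipidTable
from .morphometry import WormImage

__all__ = [
    "RunConfig",
    "RunLog",
    "read_table",
    "write_table",
    "read_counts",
    "read_image",
    "write_image",
]

SCHEMA_VERSION = 1
KNOWN_STAGES = (
    "simulate",
    "measure-length",
    "growth-fit",
    "timings",
    "ratio-bootstrap",
    "effect-size",
    "rnaseq-de",
    "embed",
    "lipids",
)


# ---------------------------------------------------------------------------
# Configuration and logging
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A validated pipeline-stage configuration.

    Every stochastic stage must carry an explicit seed; unknown keys in a
    YAML file are rejected rather than ignored.
    """

    stage: str
    inputs: dict = field(default_factory=dict)
    outdir: str = "."
    params: dict = field(default_factory=dict)
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION

    _FIELDS = ("stage", "inputs", "outdir", "params", "seed", "schema_version")
    _STOCHASTIC = ("simulate", "ratio-bootstrap", "effect-size")

    def __post_init__(self) -> None:
        if self.stage not in KNOWN_STAGES:
            raise ValueError(f"unknown stage: {self.stage!r}")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version: {self.schema_version}")
        if self.stage in self._STOCHASTIC and self.seed is None:
            raise ValueError(f"stage {self.stage!r} is stochastic: explicit seed required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        unknown = set(data) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}


class RunLog:
    """Append-only JSON-lines run log."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def record(self, event: str, **fields) -> None:
        entry = {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "event": event,
            **fields,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _check_numeric(df: pd.DataFrame, cols, kind: str, allow_nan=False) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{kind}: malformed numeric cell at row {row}, column {c!r}")
        df[c] = vals


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV/CSV by extension, or MTX).

    The first column holds gene ids.  MatrixMarket input expects sidecar
    ``<stem>.genes.txt`` / ``<stem>.samples.txt`` id lists.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        genes = Path(path.with_suffix("")).with_suffix(".genes.txt").read_text().split()
        samples = Path(path.with_suffix("")).with_suffix(".samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        sep = "\t" if path.suffix in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    if (vals < 0).any():
        gene = df.index[np.nonzero((vals < 0).any(axis=1))[0][0]]
        raise ValueError(f"negative count at gene {gene!r}")
    return df


def read_table(path: str | Path, kind: str):
    """Read and validate a typed CSV table.

    kinds: ``counts`` (gene x sample matrix), ``lengths`` (columns
    animal_id, time_h, length_um), ``events`` (animal_id, t_laid_h,
    t_hatch_h, t_first_egg_h; blanks allowed), ``lipids`` (lipid_id,
    class, then sample columns; sample sheet read separately).
    """
    path = Path(path)
    if kind == "counts":
        return read_counts(path)

    df = pd.read_csv(path)
    if kind == "lengths":
        required = {"animal_id", "time_h", "length_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"lengths table missing columns: {sorted(missing)}")
        _check_numeric(df, ["time_h", "length_um"], "lengths")
        out = []
        for animal, sub in df.groupby("animal_id", sort=False):
            sub = sub.sort_values("time_h")
            out.append(
                GrowthTrajectory(
                    animal_id=str(animal),
                    times_h=sub["time_h"].to_numpy(),
                    lengths_um=sub["length_um"].to_numpy(),
                )
            )
        return out
    if kind == "events":
        required = {"animal_id", "t_laid_h", "t_hatch_h", "t_first_egg_h"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        _check_numeric(df, ["t_laid_h", "t_hatch_h", "t_first_egg_h"], "events")
        events = {}
        for _, row in df.iterrows():
            aid = str(row["animal_id"])
            if aid in events:
                raise ValueError(f"duplicate animal id: {aid!r}")
            events[aid] = DevEvents(
                t_laid_h=None if pd.isna(row["t_laid_h"]) else float(row["t_laid_h"]),
                t_hatch_h=None if pd.isna(row["t_hatch_h"]) else float(row["t_hatch_h"]),
                t_first_egg_h=None if pd.isna(row["t_first_egg_h"]) else float(row["t_first_egg_h"]),
            )
        return events
    if kind == "lipids":
        if "lipid_id" not in df.columns or "class" not in df.columns:
            raise ValueError("lipid table must have lipid_id and class columns")
        if df["lipid_id"].duplicated().any():
            dup = df.loc[df["lipid_id"].duplicated(), "lipid_id"].iloc[0]
            raise ValueError(f"duplicate lipid id: {dup!r}")
        sample_cols = [c for c in df.columns if c not in ("lipid_id", "class")]
        _check_numeric(df, sample_cols, "lipids")
        ab = df.set_index("lipid_id")[sample_cols]
        if (ab.to_numpy() < 0).any():
            raise ValueError("negative abundance")
        classes = df.set_index("lipid_id")["class"]
        # Group/timepoint annotations default to unknown; the caller
        # attaches a sample sheet for real runs.
        samples = pd.Index(sample_cols)
        return LipidTable(
            abundances=ab,
            classes=classes,
            groups=pd.Series("unknown", index=samples, name="group"),
            timepoints=pd.Series("unknown", index=samples, name="timepoint"),
        )
    raise ValueError(f"unknown table kind: {kind!r}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a CSV (or TSV by extension) with a header row."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=index)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path: str | Path, px_size_um: float | None = None) -> WormImage:
    """Read a TIFF/PNG into a :class:`WormImage`.

    The pixel size comes from ``px_size_um`` or a ``<image>.json`` sidecar;
    a missing pixel size is an error — physical lengths must never rely on
    a silent default.  RGB input is converted to luminance.
    """
    path = Path(path)
    if px_size_um is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            px_size_um = json.loads(sidecar.read_text()).get("px_size_um")
    if px_size_um is None:
        raise ValueError(f"no pixel size for {path.name}: pass px_size_um or add a JSON sidecar")

    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> ITU-R 601 luminance
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return WormImage(pixels=arr.astype(float), px_size_um=float(px_size_um))


def write_image(
    image: np.ndarray, path: str | Path, px_size_um: float | None = None
) -> None:
    """Write a float [0, 1] image as 16-bit TIFF or 8-bit PNG, with sidecar.

    When ``px_size_um`` is given, a ``<image>.json`` sidecar records it.
    """
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (arr * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, (arr * 255).round().astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if px_size_um is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"px_size_um": px_size_um})
        )
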