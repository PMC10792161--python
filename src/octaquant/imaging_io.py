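"""Read/write en-face slab images and cohort tables.

En-face slabs are single-channel 8- or 16-bit TIFF or PNG images. At read
time intensities are rescaled to [0, 1] by dividing by the bit-depth
maximum, so all downstream math is bit-depth and device independent.
Acquisition metadata (scan width, fovea center, signal strength index,
eye label, subject id) travels with the image in an :class:`EnFaceSlab`.
"""

from __future__ import annotations

import configparser
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

#: Minimum image side length accepted, in pixels.
MIN_SIDE_PX = 32

#: Default signal-strength-index inclusion cut-off (rows must be strictly above).
DEFAULT_SSI_MIN = 8.0


class SlabKind(str, enum.Enum):
    """The en-face slab types the pipeline distinguishes."""

    SCP = "SCP"  # superficial capillary plexus
    DCP = "DCP"  # deep capillary plexus
    CC = "CC"  # choriocapillaris
    EZ = "EZ"  # ellipsoid zone
    VITREOUS_REF = "VITREOUS_REF"  # dark reflectivity reference
    RNFL_REF = "RNFL_REF"  # bright reflectivity reference


@dataclass
class EnFaceSlab:
    """One grayscale en-face image plus physical/acquisition metadata.

    Parameters
    ----------
    image
        2-D float array with intensities in [0, 1].
    slab_kind
        Which slab this image represents.
    scan_width_mm
        Physical width of the (square) scan field. Default 3.0 mm.
    fovea_center_px
        (row, col) of the fovea in 0-based pixel coordinates, or None if
        not localized. The fovea is always an input, never auto-detected.
    ssi
        Device-reported signal strength index on a 0-10 scale.
    eye_label
        "study" or "fellow".
    subject_id
        Opaque subject identifier.
    """

    image: np.ndarray
    slab_kind: SlabKind
    scan_width_mm: float = 3.0
    fovea_center_px: tuple[float, float] | None = None
    ssi: float | None = None
    eye_label: str | None = None
    subject_id: str | None = None
    source_path: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError(f"slab image must be 2-D, got shape {self.image.shape}")
        if min(self.image.shape) < MIN_SIDE_PX:
            raise ValueError(
                f"slab image must be at least {MIN_SIDE_PX} px per side, "
                f"got shape {self.image.shape}"
            )
        lo, hi = float(self.image.min()), float(self.image.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")
        self.slab_kind = SlabKind(self.slab_kind)
        if not self.scan_width_mm > 0:
            raise ValueError("scan_width_mm must be positive")
        if self.ssi is not None and not (0.0 <= self.ssi <= 10.0):
            raise ValueError(f"ssi must be in [0, 10], got {self.ssi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one pixel (scan width / number of columns)."""
        return self.scan_width_mm / self.image.shape[1]

    def with_image(self, image: np.ndarray) -> "EnFaceSlab":
        """Copy of this slab with a replacement image (metadata unchanged)."""
        return replace(self, image=image)


def _load_raw(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return tifffile.imread(path)
    with Image.open(path) as im:
        if im.mode == "I;16":
            return np.asarray(im, dtype=np.uint16)
        return np.asarray(im)


def read_slab(
    path: str | Path,
    slab_kind: SlabKind | str,
    *,
    scan_width_mm: float = 3.0,
    fovea_center_px: tuple[float, float] | None = None,
    ssi: float | None = None,
    eye_label: str | None = None,
    subject_id: str | None = None,
) -> EnFaceSlab:
    """Read an 8- or 16-bit single-channel TIFF/PNG into an EnFaceSlab.

    Intensities are divided by the bit-depth maximum (255 or 65535) so the
    returned slab is normalized to [0, 1]. Metadata is attached unmodified.

    Raises
    ------
    ValueError
        If the file is unreadable, multi-channel, not 8/16-bit integer,
        or zero-sized; the message names the offending path.
    """
    path = Path(path)
    try:
        raw = _load_raw(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if raw.ndim != 2:
        raise ValueError(
            f"expected a single-channel image at {path}, got shape {raw.shape}"
        )
    if raw.dtype == np.uint8:
        maxval = 255.0
    elif raw.dtype == np.uint16:
        maxval = 65535.0
    else:
        raise ValueError(
            f"expected 8- or 16-bit unsigned integer pixels at {path}, got {raw.dtype}"
        )
    return EnFaceSlab(
        image=raw.astype(float) / maxval,
        slab_kind=SlabKind(slab_kind),
        scan_width_mm=scan_width_mm,
        fovea_center_px=fovea_center_px,
        ssi=ssi,
        eye_label=eye_label,
        subject_id=subject_id,
        source_path=str(path),
    )


def write_slab(slab: EnFaceSlab, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a slab image as single-channel TIFF or PNG at the given bit depth.

    The inverse of :func:`read_slab`: values are multiplied by the bit-depth
    maximum and rounded, so a slab read from an integer image round-trips
    losslessly at its original depth.
    """
    path = Path(path)
    if bit_depth == 8:
        arr = np.rint(slab.image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.rint(slab.image * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
    return path


# ---------------------------------------------------------------------------
# Cohort manifest / inclusion filter
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "subject_id",
    "eye_label",
    "slab_kind",
    "path",
    "scan_width_mm",
    "fovea_row_px",
    "fovea_col_px",
    "ssi",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (one row per subject/eye/slab image)."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def apply_inclusion_filter(
    manifest: pd.DataFrame, ssi_min: float = DEFAULT_SSI_MIN
) -> pd.DataFrame:
    """Keep only rows with signal strength index strictly above ``ssi_min``.

    The inclusion rule is a strict inequality (default cut-off 8 on the
    device's 0-10 scale). Rows with a missing SSI are rejected loudly, not
    silently dropped.
    """
    if "ssi" not in manifest.columns:
        raise ValueError("manifest has no 'ssi' column")
    missing = manifest["ssi"].isna()
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} manifest row(s) have no SSI recorded: "
            f"indices {manifest.index[missing].tolist()}"
        )
    keep = manifest["ssi"] > ssi_min
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("inclusion filter excluded %d of %d rows (ssi <= %g)",
                    n_excluded, len(manifest), ssi_min)
    return manifest.loc[keep].copy()


# ---------------------------------------------------------------------------
# Per-eye metric tables
# ---------------------------------------------------------------------------

#: Schema of one per-eye metric row (the quantification output table).
METRIC_COLUMNS = [
    "subject_id",
    "eye_label",
    "scp_pd",
    "scp_vld",
    "scp_vdi",
    "dcp_pd",
    "dcp_vld",
    "dcp_vdi",
    "cc_pd",
    "ez_reflectivity",
]


def write_cohort_table(records: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write per-eye metric rows to CSV with the documented header.

    Missing metric values become empty cells and are restored as NaN by
    :func:`read_cohort_table` (lossless round trip at float precision).
    """
    if isinstance(records, list):
        df = pd.DataFrame(records)
    else:
        df = records.copy()
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=METRIC_COLUMNS)
    unknown = set(df.columns) - set(METRIC_COLUMNS)
    if unknown:
        raise ValueError(f"rows carry unknown columns: {sorted(unknown)}")
    for col in METRIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[METRIC_COLUMNS]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-eye metric table written by :func:`write_cohort_table`."""
    df = pd.read_csv(path)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} missing columns: {sorted(missing)}")
    return df[METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# Plain-text configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict[str, float | str] = {
    "ssi_min": DEFAULT_SSI_MIN,
    "scan_width_mm": 3.0,
    "roi_radius_mm": 1.5,
    "global_threshold": "otsu",
    "phansalkar_window_radius_px": 15,
    "phansalkar_k": 0.25,
    "phansalkar_r": 0.5,
    "phansalkar_p": 2.0,
    "phansalkar_q": 10.0,
}


def read_config(path: str | Path | None = None) -> dict[str, float | str]:
    """Read a ``key = value`` text config; unset keys take package defaults."""
    cfg = dict(_CONFIG_DEFAULTS)
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    text = Path(path).read_text()
    parser.read_string("[octaquant]\n" + text)
    for key, value in parser["octaquant"].items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key!r}")
        default = cfg[key]
        cfg[key] = value if isinstance(default, str) else type(default)(float(value))
    return cfg
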