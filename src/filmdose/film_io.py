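"""External formats: 48-bit TIFF scans, dose planes, coefficient and config files.

Conventions used throughout the package:

* image coordinates are 0-based, row-major, origin at the top-left pixel
  center; rectangles are half-open ``(r0, r1, c0, c1)`` selecting rows
  ``r0 <= r < r1`` and columns ``c0 <= c < c1``;
* scans are 16 bits per channel RGB; 8-bit input is rejected, never
  silently upscaled;
* dose planes are plain-text matrices with a 3-line header (rows, cols,
  spacing_mm), row-major, cGy, two decimal places;
* calibration coefficient files are INI-style key-value text, one section
  per color channel, and round-trip losslessly.

All readers reject malformed input; all writers produce files their
readers accept.
"""

from __future__ import annotations

import configparser
import io
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.stats import trim_mean

from .calibration import CalibrationCurve, Channel, CurveForm
from .errors import FormatError, GeometryError, MetadataError
from .multichannel import DoseMap, FilmScan

__all__ = [
    "read_tiff_scan",
    "write_tiff_scan",
    "extract_roi_response",
    "read_dose_plane",
    "write_dose_plane",
    "read_calibration_file",
    "write_calibration_file",
    "load_config",
]

MIN_ROI_AREA = 100  # pixels; smaller ROIs give unstable trimmed means
TRIM_FRACTION = 0.1  # cut 10% from each tail -> central 80%


def write_tiff_scan(scan: FilmScan, path: str | Path) -> None:
    """Write a FilmScan as an uncompressed 48-bit RGB TIFF with dpi tags."""
    tifffile.imwrite(
        str(path),
        np.moveaxis(scan.pixels, 0, -1),  # H x W x 3
        photometric="rgb",
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


def read_tiff_scan(
    path: str | Path, default_dpi: float | None = None, scanner_id: str = ""
) -> FilmScan:
    """Read a 48-bit RGB TIFF into a FilmScan.

    dpi comes from the TIFF resolution tags; if absent, ``default_dpi``
    (e.g. from the run config) is used, else MetadataError.  8-bit files
    raise FormatError rather than being upscaled.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.dtype != np.uint16:
            raise FormatError(
                f"{path.name}: expected 16 bits/sample, got dtype {arr.dtype}"
            )
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise FormatError(
                f"{path.name}: expected 3 samples/pixel RGB, got shape {arr.shape}"
            )
        dpi = None
        tags = page.tags
        if "XResolution" in tags and "ResolutionUnit" in tags:
            num, den = tags["XResolution"].value
            unit = tags["ResolutionUnit"].value
            if den and num:
                res = num / den
                if res > 1:  # tifffile writes (1, 1) when resolution unset
                    unit_name = getattr(unit, "name", str(unit)).upper()
                    if "CENTIMETER" in unit_name:
                        dpi = res * 2.54
                    else:
                        dpi = res
    if dpi is None:
        if default_dpi is None:
            raise MetadataError(
                f"{path.name}: no resolution tags and no default dpi configured"
            )
        dpi = default_dpi
    return FilmScan(
        pixels=np.moveaxis(arr, -1, 0), dpi=float(dpi), scanner_id=scanner_id
    )


def extract_roi_response(
    scan: FilmScan, rectangle: tuple[int, int, int, int], channel: Channel | str
) -> float:
    """Trimmed-mean normalized response of one channel over a rectangle.

    ``rectangle`` is (r0, r1, c0, c1), half-open.  The central 80% of pixel
    values is averaged (10% trimmed from each tail) to resist edge artifacts
    and dust.  Area must be >= 100 pixels.
    """
    r0, r1, c0, c1 = rectangle
    h, w = scan.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise GeometryError(
            f"rectangle {rectangle} not within image bounds {h}x{w}"
        )
    area = (r1 - r0) * (c1 - c0)
    if area < MIN_ROI_AREA:
        raise GeometryError(
            f"ROI area {area} px below the minimum of {MIN_ROI_AREA}"
        )
    ch = {Channel.R: 0, Channel.G: 1, Channel.B: 2}[Channel(channel)]
    values = scan.normalized()[ch, r0:r1, c0:c1].ravel()
    return float(trim_mean(values, TRIM_FRACTION))


def write_dose_plane(dose_map: DoseMap, path: str | Path) -> None:
    """Write a dose plane in the text-matrix exchange format (cGy, 2 dp)."""
    h, w = dose_map.shape
    with open(path, "w") as f:
        f.write(f"rows {h}\n")
        f.write(f"cols {w}\n")
        f.write(f"spacing_mm {dose_map.spacing_mm!r}\n")
        np.savetxt(f, dose_map.dose, fmt="%.2f")


def read_dose_plane(path: str | Path) -> DoseMap:
    """Read a text-matrix dose plane; header/shape mismatches are errors."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path.name}: missing 3-line header")
    header: dict[str, str] = {}
    for line in lines[:3]:
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path.name}: bad header line {line!r}")
        header[parts[0]] = parts[1]
    try:
        rows = int(header["rows"])
        cols = int(header["cols"])
        spacing = float(header["spacing_mm"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path.name}: invalid header: {exc}") from exc
    try:
        data = np.loadtxt(io.StringIO("\n".join(lines[3:])), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path.name}: unreadable matrix body: {exc}") from exc
    if data.shape != (rows, cols):
        raise FormatError(
            f"{path.name}: header promises {rows}x{cols}, body is {data.shape}"
        )
    return DoseMap(dose=data, spacing_mm=spacing)


def write_calibration_file(
    curves: list[CalibrationCurve], path: str | Path
) -> None:
    """Write per-channel curve coefficients as key-value text (INI)."""
    cp = configparser.ConfigParser()
    lots = {c.lot_id for c in curves}
    if len(lots) != 1:
        raise ValueError(f"curves must share one lot_id, got {lots}")
    cp["lot"] = {"lot_id": curves[0].lot_id}
    for c in curves:
        cp[c.channel.value] = {
            "form": c.form.value,
            "a": repr(c.a),
            "b": repr(c.b),
            "c": repr(c.c),
            "dose_min": repr(c.dose_domain[0]),
            "dose_max": repr(c.dose_domain[1]),
        }
    with open(path, "w") as f:
        cp.write(f)


def read_calibration_file(path: str | Path) -> dict[Channel, CalibrationCurve]:
    """Read a coefficient file back into per-channel curves."""
    path = Path(path)
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read or "lot" not in cp:
        raise FormatError(f"{path.name}: not a calibration coefficient file")
    lot_id = cp["lot"].get("lot_id", "")
    curves: dict[Channel, CalibrationCurve] = {}
    for name in ("R", "G", "B"):
        if name not in cp:
            continue
        s = cp[name]
        try:
            curves[Channel(name)] = CalibrationCurve(
                channel=Channel(name),
                a=float(s["a"]),
                b=float(s["b"]),
                c=float(s["c"]),
                dose_domain=(float(s["dose_min"]), float(s["dose_max"])),
                lot_id=lot_id,
                form=CurveForm(s.get("form", "standard")),
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path.name}: channel {name}: {exc}") from exc
    if not curves:
        raise FormatError(f"{path.name}: no channel sections found")
    return curves


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration.

    Recognized keys (all optional unless a workflow needs them):
    ``calibration_file``, ``reference_dose_cgy``, ``default_dpi``,
    ``rois`` (mapping name -> [r0, r1, c0, c1]), ``gamma`` (mapping of
    GammaParams fields), ``simulator`` (seed, shape, levels...).
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path.name}: invalid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    rois = cfg.get("rois", {})
    if not isinstance(rois, dict):
        raise FormatError(f"{path.name}: rois must be a mapping")
    for name, rect in rois.items():
        if not (isinstance(rect, (list, tuple)) and len(rect) == 4):
            raise FormatError(
                f"{path.name}: ROI {name!r} must be [r0, r1, c0, c1]"
            )
    return cfg
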