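"""Grayscale intensity profiles extracted from fish flank images.

The unit of analysis is a one-dimensional anterior-to-posterior series of
gray values (0 = pure black, 255 = pure white) obtained by averaging the
pixels of each column of a thin rectangular region of the flank.  Profiles
can be extracted from PNG/TIFF images or read from a simple commented CSV
dialect, and carry the metadata (group, sex, standard length, physical
scale) that downstream statistics need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

GROUPS = ("parental_A", "parental_M", "F2")
SEXES = ("F", "M", "unknown")

# Rec. 601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class IntensityProfile:
    """One individual's anterior->posterior gray-value series.

    Parameters
    ----------
    values
        Gray values in [0, 255], one per pixel column, anterior first.
    scale_cm_per_px
        Physical size of one pixel column in centimeters.
    individual_id
        Identifier carried through trait tables and reports.
    group
        One of ``parental_A``, ``parental_M``, ``F2``.
    sex
        One of ``F``, ``M``, ``unknown``.
    standard_length_cm
        Snout-to-caudal-peduncle length in cm, or ``None`` if unknown.
    """

    values: np.ndarray
    scale_cm_per_px: float
    individual_id: str = ""
    group: str = "F2"
    sex: str = "unknown"
    standard_length_cm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile values must be a non-empty 1-D series")
        if np.any(self.values < 0) or np.any(self.values > 255):
            raise ValueError("gray values must lie in [0, 255]")
        if not self.scale_cm_per_px > 0:
            raise ValueError("scale_cm_per_px must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def length_px(self) -> int:
        return int(self.values.size)

    def copy(self, **changes) -> "IntensityProfile":
        out = replace(self, **changes)
        out.values = np.array(out.values, dtype=float, copy=True)
        return out


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an image array to 2-D grayscale on the 0-255 scale."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[:, :, :3] @ _LUMA
    raise ValueError(f"unsupported image shape {img.shape}")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image into a numpy array (grayscale or RGB)."""
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "F", "RGB", "RGBA"):
            im = im.convert("RGB")
        return np.asarray(im)


def extract_profile(
    image: np.ndarray,
    region: tuple[int, int, int, int],
    scale_cm_per_px: float,
    *,
    individual_id: str = "",
    group: str = "F2",
    sex: str = "unknown",
    standard_length_cm: float | None = None,
    flip: bool = False,
) -> IntensityProfile:
    """Average the pixels of each column of ``region`` into a profile.

    ``region`` is ``(x, y, width, height)`` in pixel coordinates with the
    origin at the top-left corner; the canonical region is 10 pixels high.
    Color images are converted to grayscale with Rec. 601 luma weights
    before averaging.  ``flip=True`` reverses the column order for images
    of right-facing fish so the stored profile is anterior->posterior.
    """
    gray = _to_gray(image)
    x, y, w, h = (int(v) for v in region)
    if w <= 0 or h <= 0:
        raise ValueError("region width and height must be positive")
    if x < 0 or y < 0 or x + w > gray.shape[1] or y + h > gray.shape[0]:
        raise ValueError(
            f"region {region} lies outside image of shape {gray.shape[:2]}"
        )
    values = gray[y : y + h, x : x + w].mean(axis=0)
    if flip:
        values = values[::-1]
    return IntensityProfile(
        values=np.clip(values, 0.0, 255.0),
        scale_cm_per_px=scale_cm_per_px,
        individual_id=individual_id,
        group=group,
        sex=sex,
        standard_length_cm=standard_length_cm,
    )


def standard_length_from_landmarks(
    snout_xy: Sequence[float],
    caudal_peduncle_xy: Sequence[float],
    scale_cm_per_px: float,
) -> float:
    """Standard length in cm: Euclidean pixel distance snout->peduncle x scale."""
    (x0, y0), (x1, y1) = snout_xy, caudal_peduncle_xy
    if x0 == x1 and y0 == y1:
        raise ValueError("snout and caudal peduncle landmarks coincide")
    if not scale_cm_per_px > 0:
        raise ValueError("scale_cm_per_px must be positive")
    return math.hypot(x1 - x0, y1 - y0) * scale_cm_per_px


_HEADER_KEYS = ("id", "group", "sex", "standard_length_cm", "scale_cm_per_px")


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    """Write a profile with its metadata in '#'-commented header lines."""
    sl = "" if profile.standard_length_cm is None else repr(float(profile.standard_length_cm))
    lines = [
        f"# id={profile.individual_id}",
        f"# group={profile.group}",
        f"# sex={profile.sex}",
        f"# standard_length_cm={sl}",
        f"# scale_cm_per_px={float(profile.scale_cm_per_px)!r}",
        "position_px,gray_value",
    ]
    lines += [f"{i},{float(v)!r}" for i, v in enumerate(profile.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_csv(path: str | Path) -> IntensityProfile:
    """Read a profile CSV written by :func:`write_profile_csv` (lossless)."""
    meta: dict[str, str] = {}
    values: list[float] = []
    next_pos = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("position_px"):
                continue
            parts = line.split(",")
            if len(parts) != 2 or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'position_px,gray_value'")
            try:
                pos = int(parts[0])
                val = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if pos != next_pos:
                raise ValueError(f"{path}:{lineno}: positions must be 0-based and consecutive")
            if not 0 <= val <= 255:
                raise ValueError(f"{path}:{lineno}: gray value {val} outside [0, 255]")
            values.append(val)
            next_pos += 1
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing header fields {missing}")
    if not values:
        raise ValueError(f"{path}: no profile values")
    sl = meta["standard_length_cm"]
    return IntensityProfile(
        values=np.array(values),
        scale_cm_per_px=float(meta["scale_cm_per_px"]),
        individual_id=meta["id"],
        group=meta["group"],
        sex=meta["sex"],
        standard_length_cm=float(sl) if sl else None,
    )


def profile_to_image(profile: IntensityProfile, height: int = 10) -> np.ndarray:
    """Paint a column-constant grayscale image from a profile (round-trip aid)."""
    return np.tile(profile.values, (height, 1))
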