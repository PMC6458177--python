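"""Exposure metadata from DICOM headers (no pixel data is read).

Standard tags cover thickness, age, anode/filter, HVL and the dose fields;
vendor-specific density outputs (volumetric breast density and glandularity
percent by weight) live in private tags whose addresses vary with the
acquisition software version, so they are resolved through a configurable
tag map rather than hard-coded addresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pydicom
from pydicom.errors import InvalidDicomError

from .dosimetry import ExamRecord

logger = logging.getLogger(__name__)

__all__ = ["DicomTagMap", "DEFAULT_TAG_MAP", "read_dicom_headers", "DicomReadError"]


class DicomReadError(RuntimeError):
    """No usable DICOM files were found."""


@dataclass(frozen=True)
class DicomTagMap:
    """Where each exposure field lives in the header.

    Each entry is a DICOM keyword (str) or a ``(group, element)`` tag tuple.
    ``vendor_agd_scale`` converts the stored organ-dose value to mGy
    (the standard OrganDose tag is in dGy, hence the default 100).
    ``volpara_gpw``/``volpara_vbd`` default to ``None``: private density tags
    must be supplied explicitly for the software version at hand.
    """

    thickness_mm: object = "BodyPartThickness"
    age: object = "PatientAge"
    hvl_mm_al: object = "HalfValueLayer"
    anode: object = "AnodeTargetMaterial"
    filter: object = "FilterMaterial"
    iak_mgy: object = "EntranceDoseInmGy"
    vendor_agd: object = "OrganDose"
    vendor_agd_scale: float = 100.0  # dGy -> mGy
    volpara_gpw: object | None = None
    volpara_vbd: object | None = None
    view: object = "ViewPosition"


DEFAULT_TAG_MAP = DicomTagMap()


def _get(ds, key):
    if key is None:
        return None
    try:
        value = ds[key].value if isinstance(key, tuple) else getattr(ds, key, None)
    except KeyError:
        return None
    return None if value in (None, "") else value


def _parse_age(ds, tag_map: DicomTagMap) -> float | None:
    raw = _get(ds, tag_map.age)
    if raw is not None:
        text = str(raw).strip()
        try:
            if text and text[-1].upper() in "YMD":  # DICOM age string, e.g. 057Y
                unit = text[-1].upper()
                number = float(text[:-1])
                return {"Y": number, "M": number / 12.0, "D": number / 365.25}[unit]
            return float(text)
        except ValueError:
            logger.warning("unparseable age %r", raw)
    birth, study = _get(ds, "PatientBirthDate"), _get(ds, "StudyDate")
    if birth and study:
        try:
            by, bm, bd = int(birth[:4]), int(birth[4:6]), int(birth[6:8])
            sy, sm, sd = int(study[:4]), int(study[4:6]), int(study[6:8])
            return float(sy - by - ((sm, sd) < (bm, bd)))  # whole years
        except (ValueError, IndexError):
            logger.warning("unparseable birth/study dates %r / %r", birth, study)
    return None


def _float_or_none(value) -> float | None:
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def read_dicom_headers(
    paths,
    tag_map: DicomTagMap = DEFAULT_TAG_MAP,
) -> list[ExamRecord]:
    """Read exposure records from DICOM files (headers only).

    Non-DICOM files are skipped with a logged reason; missing optional tags
    leave the corresponding fields empty.  Raises :class:`DicomReadError` if
    no file yields a record.
    """
    paths = [Path(p) for p in paths]
    records: list[ExamRecord] = []
    for path in paths:
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except (InvalidDicomError, IsADirectoryError, FileNotFoundError, OSError) as exc:
            logger.warning("skipping %s: not readable as DICOM (%s)", path, exc)
            continue
        vendor_agd = _float_or_none(_get(ds, tag_map.vendor_agd))
        if vendor_agd is not None:
            vendor_agd *= tag_map.vendor_agd_scale
        try:
            record = ExamRecord(
                exam_id=str(_get(ds, "SOPInstanceUID") or path.stem),
                view=str(_get(ds, tag_map.view) or "CC"),
                age=_parse_age(ds, tag_map),
                thickness_mm=_float_or_none(_get(ds, tag_map.thickness_mm)),
                hvl_mm_al=_float_or_none(_get(ds, tag_map.hvl_mm_al)),
                anode=str(_get(ds, tag_map.anode) or "Mo"),
                filter=str(_get(ds, tag_map.filter) or "Mo"),
                iak_mgy=_float_or_none(_get(ds, tag_map.iak_mgy)),
                vendor_agd_mgy=vendor_agd,
                volpara_gpw=_float_or_none(_get(ds, tag_map.volpara_gpw)),
                volpara_vbd=_float_or_none(_get(ds, tag_map.volpara_vbd)),
            )
        except ValueError as exc:
            logger.warning("skipping %s: invalid header values (%s)", path, exc)
            continue
        for name in ("thickness_mm", "hvl_mm_al", "iak_mgy"):
            if getattr(record, name) is None:
                logger.info("%s: header lacks %s", path, name)
        records.append(record)
    if not records:
        raise DicomReadError(f"no usable DICOM files among {len(paths)} path(s)")
    return records
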