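"""Bounded DICOM codec: uncompressed Explicit-VR-Little-Endian MR objects.

This is not a general DICOM implementation.  It reads and writes exactly the
flavour this pipeline produces (single-frame monochrome MR, explicit VR little
endian, no sequences, no compressed transfer syntaxes) and is round-trip
tested against itself.  Datasets are plain ``dict[tag, (vr, value)]`` so the
pseudonymiser can edit metadata without touching pixel bytes.
"""

from __future__ import annotations

import hashlib
import os
import struct
from pathlib import Path

import numpy as np

from .core import ImagingSession, SliceStack, ValidationError

__all__ = [
    "DicomError",
    "read_dataset",
    "write_dataset",
    "write_session_dicom",
    "read_session_dicom",
    "SERIES_DESCRIPTIONS",
    "Tag",
]

Tag = tuple[int, int]


class DicomError(ValidationError):
    pass


TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_MR = "1.2.840.10008.5.1.4.1.1.4"
IMPLEMENTATION_UID = "2.25.4242424242424242424242"

#: Series Description string per contrast label (and its inverse).
SERIES_DESCRIPTIONS = {
    "fat": "dixon_fat",
    "water": "dixon_water",
    "in_phase": "dixon_ip",
    "out_of_phase": "dixon_op",
    "b50": "dwi_b50",
    "b900": "dwi_b900",
    "adc": "adc",
}
_DESC_TO_CONTRAST = {v: k for k, v in SERIES_DESCRIPTIONS.items()}

# Commonly used tags
TAG = {
    "SOPClassUID": (0x0008, 0x0016),
    "SOPInstanceUID": (0x0008, 0x0018),
    "StudyDate": (0x0008, 0x0020),
    "SeriesDate": (0x0008, 0x0021),
    "StudyTime": (0x0008, 0x0030),
    "Modality": (0x0008, 0x0060),
    "InstitutionName": (0x0008, 0x0080),
    "ReferringPhysicianName": (0x0008, 0x0090),
    "SeriesDescription": (0x0008, 0x103E),
    "PatientName": (0x0010, 0x0010),
    "PatientID": (0x0010, 0x0020),
    "PatientBirthDate": (0x0010, 0x0030),
    "PatientIdentityRemoved": (0x0012, 0x0062),
    "SliceThickness": (0x0018, 0x0050),
    "SpacingBetweenSlices": (0x0018, 0x0088),
    "StudyInstanceUID": (0x0020, 0x000D),
    "SeriesInstanceUID": (0x0020, 0x000E),
    "StudyID": (0x0020, 0x0010),
    "SeriesNumber": (0x0020, 0x0011),
    "InstanceNumber": (0x0020, 0x0013),
    "ImagePositionPatient": (0x0020, 0x0032),
    "ImageOrientationPatient": (0x0020, 0x0037),
    "SamplesPerPixel": (0x0028, 0x0002),
    "PhotometricInterpretation": (0x0028, 0x0004),
    "Rows": (0x0028, 0x0010),
    "Columns": (0x0028, 0x0011),
    "PixelSpacing": (0x0028, 0x0030),
    "BitsAllocated": (0x0028, 0x0100),
    "BitsStored": (0x0028, 0x0101),
    "HighBit": (0x0028, 0x0102),
    "PixelRepresentation": (0x0028, 0x0103),
    "RescaleIntercept": (0x0028, 0x1052),
    "RescaleSlope": (0x0028, 0x1053),
    "PixelData": (0x7FE0, 0x0010),
}
TAG_NAME = {v: k for k, v in TAG.items()}

_LONG_HEADER_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"UI", "SH", "LO", "PN", "CS", "DA", "TM", "AS", "DS", "IS", "ST", "LT"}


def deterministic_uid(*parts: str) -> str:
    digest = hashlib.sha256("|".join(parts).encode()).hexdigest()
    return "2.25." + str(int(digest[:30], 16))


def _encode_value(vr: str, value) -> bytes:
    if vr in _STRING_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        raw = str(value).encode("ascii")
        if len(raw) % 2:
            raw += b"\x00" if vr == "UI" else b" "
        return raw
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    if vr in ("OB", "OW"):
        raw = bytes(value)
        if len(raw) % 2:
            raw += b"\x00"
        return raw
    raise DicomError(f"unsupported VR {vr!r} for writing")


def _decode_value(vr: str, raw: bytes):
    if vr in _STRING_VRS:
        text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
        return text.split("\\") if "\\" in text else text
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw) // 2}H", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        vals = list(struct.unpack(f"<{len(raw) // 4}I", raw))
        return vals[0] if len(vals) == 1 else vals
    return raw  # OB/OW and anything else: raw bytes


def _element_bytes(tag: Tag, vr: str, value) -> bytes:
    raw = _encode_value(vr, value)
    head = struct.pack("<HH", *tag) + vr.encode("ascii")
    if vr in _LONG_HEADER_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(raw)) + raw
    if len(raw) > 0xFFFF:
        raise DicomError(f"value too long for short-form VR {vr}")
    return head + struct.pack("<H", len(raw)) + raw


def write_dataset(path, elements: dict[Tag, tuple[str, object]]) -> None:
    """Write one Part-10 file.  ``elements`` excludes the group-0002 meta."""
    sop_class = elements.get(TAG["SOPClassUID"], ("UI", SOP_CLASS_MR))[1]
    sop_inst = elements.get(TAG["SOPInstanceUID"], ("UI", deterministic_uid(str(path))))[1]
    meta_elems = [
        ((0x0002, 0x0001), "OB", b"\x00\x01"),
        ((0x0002, 0x0002), "UI", sop_class),
        ((0x0002, 0x0003), "UI", sop_inst),
        ((0x0002, 0x0010), "UI", TRANSFER_SYNTAX_EXPLICIT_LE),
        ((0x0002, 0x0012), "UI", IMPLEMENTATION_UID),
    ]
    meta_body = b"".join(_element_bytes(t, vr, v) for t, vr, v in meta_elems)
    meta = _element_bytes((0x0002, 0x0000), "UL", len(meta_body)) + meta_body
    body = b"".join(
        _element_bytes(tag, vr, value)
        for tag, (vr, value) in sorted(elements.items())
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def read_dataset(path) -> dict[Tag, tuple[str, object]]:
    """Parse one Part-10 Explicit-VR-LE file into ``{tag: (vr, value)}``."""
    data = Path(path).read_bytes()
    if data[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM Part-10 file")
    pos = 132
    elements: dict[Tag, tuple[str, object]] = {}
    n = len(data)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4 : pos + 6].decode("ascii", errors="replace")
        if vr in _LONG_HEADER_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            pos += 8
        if length == 0xFFFFFFFF:
            raise DicomError(f"{path}: undefined-length element (unsupported)")
        raw = data[pos : pos + length]
        pos += length
        tag = (group, elem)
        if group == 0x0002:
            if tag == (0x0002, 0x0010):
                ts = _decode_value("UI", raw)
                if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
                    raise DicomError(f"{path}: unsupported transfer syntax {ts}")
            continue
        elements[tag] = (vr, _decode_value(vr, raw))
    return elements


# ---------------------------------------------------------------------------
# Session-level read/write
# ---------------------------------------------------------------------------


def _ds(values, fmt="%.6f") -> list[str]:
    vals = values if isinstance(values, (list, tuple, np.ndarray)) else [values]
    out = []
    for v in vals:
        s = fmt % float(v)
        if len(s) > 16:  # DS values are limited to 16 bytes
            s = "%.6g" % float(v)
        out.append(s)
    return out


def _ds_floats(value) -> list[float]:
    vals = value if isinstance(value, list) else [value]
    return [float(v) for v in vals]


def write_session_dicom(session: ImagingSession, directory) -> list[str]:
    """Write one file per slice per series; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = deterministic_uid(session.subject_id, session.session_id)
    manifest: list[str] = []
    for series_no, (label, stack) in enumerate(sorted(session.series.items()), start=1):
        desc = SERIES_DESCRIPTIONS[label]
        series_uid = deterministic_uid(study_uid, desc)
        series_dir = directory / desc
        series_dir.mkdir(exist_ok=True)
        vmax = float(stack.voxels.max()) if stack.voxels.size else 0.0
        slope = vmax / 60000.0 if vmax > 0 else 1.0
        raw16 = np.round(stack.voxels / slope).astype(np.uint16)
        normal = stack.slice_normal
        iop = list(stack.orientation[0]) + list(stack.orientation[1])
        p0 = stack.slice_positions[0]
        for k in range(stack.n_slices):
            ipp = stack.origin + (stack.slice_positions[k] - p0) * normal
            elems: dict[Tag, tuple[str, object]] = {
                TAG["SOPClassUID"]: ("UI", SOP_CLASS_MR),
                TAG["SOPInstanceUID"]: ("UI", deterministic_uid(series_uid, str(k))),
                TAG["StudyDate"]: ("DA", "20200101"),
                TAG["StudyTime"]: ("TM", "120000"),
                TAG["Modality"]: ("CS", "MR"),
                TAG["SeriesDescription"]: ("LO", desc),
                TAG["PatientName"]: ("PN", session.subject_id),
                TAG["PatientID"]: ("LO", session.subject_id),
                TAG["StudyInstanceUID"]: ("UI", study_uid),
                TAG["SeriesInstanceUID"]: ("UI", series_uid),
                TAG["StudyID"]: ("SH", session.session_id[:16]),
                TAG["SeriesNumber"]: ("IS", str(series_no)),
                TAG["InstanceNumber"]: ("IS", str(k + 1)),
                TAG["ImagePositionPatient"]: ("DS", _ds(ipp)),
                TAG["ImageOrientationPatient"]: ("DS", _ds(iop)),
                TAG["SliceThickness"]: ("DS", _ds(stack.nominal_slice_spacing)),
                TAG["SpacingBetweenSlices"]: ("DS", _ds(stack.nominal_slice_spacing)),
                TAG["SamplesPerPixel"]: ("US", 1),
                TAG["PhotometricInterpretation"]: ("CS", "MONOCHROME2"),
                TAG["Rows"]: ("US", stack.voxels.shape[1]),
                TAG["Columns"]: ("US", stack.voxels.shape[2]),
                TAG["PixelSpacing"]: ("DS", _ds(stack.pixel_spacing)),
                TAG["BitsAllocated"]: ("US", 16),
                TAG["BitsStored"]: ("US", 16),
                TAG["HighBit"]: ("US", 15),
                TAG["PixelRepresentation"]: ("US", 0),
                TAG["RescaleIntercept"]: ("DS", _ds(0.0)),
                TAG["RescaleSlope"]: ("DS", _ds(slope, "%.10g")),
                TAG["PixelData"]: ("OW", raw16[k].tobytes()),
            }
            fname = series_dir / f"{k:04d}.dcm"
            write_dataset(fname, elems)
            manifest.append(str(fname.relative_to(directory)))
    return manifest


_REQUIRED_TAGS = (
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "Rows",
    "Columns",
    "PixelData",
)


def read_session_dicom(directory) -> ImagingSession:
    """Group a directory of DICOM files into an :class:`ImagingSession`.

    Files are grouped by Series Instance UID and sorted by the projection of
    Image Position (Patient) onto the slice normal (ties broken by Instance
    Number).  Series whose description is not one of the seven known contrasts
    are collected in ``session.extra_series``.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.rglob("*.dcm") if p.is_file())
    if not files:
        raise DicomError(f"no DICOM files under {directory}")
    by_series: dict[str, list[dict]] = {}
    for f in files:
        ds = read_dataset(f)
        for name in _REQUIRED_TAGS:
            if TAG[name] not in ds:
                raise DicomError(f"{f}: missing required tag {name}")
        uid = ds.get(TAG["SeriesInstanceUID"], ("UI", str(f.parent)))[1]
        by_series.setdefault(str(uid), []).append(ds)

    series: dict[str, SliceStack] = {}
    extras: list[str] = []
    subject_id = session_id = None
    for uid, datasets in sorted(by_series.items()):
        first = datasets[0]
        desc = str(first.get(TAG["SeriesDescription"], ("LO", ""))[1])
        iop0 = _ds_floats(first[TAG["ImageOrientationPatient"]][1])
        for ds in datasets[1:]:
            if _ds_floats(ds[TAG["ImageOrientationPatient"]][1]) != iop0:
                raise DicomError(f"series {desc or uid}: mixed orientations")
        orientation = np.array(iop0, float).reshape(2, 3)
        normal = np.cross(orientation[0], orientation[1])

        def sort_key(ds):
            ipp = np.array(_ds_floats(ds[TAG["ImagePositionPatient"]][1]))
            inst = int(str(ds.get(TAG["InstanceNumber"], ("IS", "0"))[1]))
            return (float(np.dot(ipp, normal)), inst)

        datasets.sort(key=sort_key)
        label = _DESC_TO_CONTRAST.get(desc)
        if label is None:
            extras.append(desc or uid)
            continue

        slices, positions = [], []
        for ds in datasets:
            rows = int(ds[TAG["Rows"]][1])
            cols = int(ds[TAG["Columns"]][1])
            raw = np.frombuffer(ds[TAG["PixelData"]][1], dtype="<u2")[: rows * cols]
            slope = float(_ds_floats(ds.get(TAG["RescaleSlope"], ("DS", "1"))[1])[0])
            icept = float(_ds_floats(ds.get(TAG["RescaleIntercept"], ("DS", "0"))[1])[0])
            slices.append(raw.reshape(rows, cols).astype(np.float64) * slope + icept)
            ipp = np.array(_ds_floats(ds[TAG["ImagePositionPatient"]][1]))
            positions.append(float(np.dot(ipp, normal)))
        ipp0 = np.array(_ds_floats(datasets[0][TAG["ImagePositionPatient"]][1]))
        ps = _ds_floats(first[TAG["PixelSpacing"]][1])
        if TAG["SpacingBetweenSlices"] in first:
            nominal = float(_ds_floats(first[TAG["SpacingBetweenSlices"]][1])[0])
        else:
            gaps = np.diff(positions)
            nominal = float(np.median(np.abs(gaps))) if len(gaps) else 1.0
        series[label] = SliceStack(
            voxels=np.stack(slices),
            slice_positions=np.array(positions),
            orientation=orientation,
            origin=ipp0,
            pixel_spacing=(ps[0], ps[1]),
            nominal_slice_spacing=nominal,
            contrast_label=label,
        )
        if subject_id is None:
            subject_id = str(first.get(TAG["PatientID"], ("LO", "UNKNOWN"))[1])
            session_id = str(first.get(TAG["StudyID"], ("SH", subject_id + "_S1"))[1])

    session = ImagingSession(
        subject_id=subject_id or "UNKNOWN",
        session_id=session_id or "UNKNOWN_S1",
        series=series,
    )
    session.extra_series = extras
    return session
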