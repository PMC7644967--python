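"""Readers and writers for all pipeline artifacts.

Peak-list CSV is the canonical spectrum format (two columns ``mz,intensity``,
one file per well, sample id taken from the file stem); mzML is supported as
an adapter through a self-contained MS1-centroid reader/writer (binary
arrays as base64 floats, zlib compression accepted on read). A combined
long-format CSV with a ``sample_id`` column is also accepted for whole-plate
tables.

Abundance matrices serialize as CSV with a ``# normalized=...`` first line;
missing cells are written as empty fields and ``NA`` is accepted on read.
Missing is a distinct state from zero throughout.
"""

from __future__ import annotations

import base64
import struct
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .core import (
    SAMPLE_COLUMNS,
    AbundanceMatrix,
    LipidTarget,
    Spectrum,
    validate_samples,
)

__all__ = [
    "read_spectra",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_spectra_table",
    "write_spectra_table",
    "read_mzml",
    "write_mzml",
    "read_targets",
    "write_targets",
    "read_samples",
    "write_samples",
    "read_matrix",
    "write_matrix",
]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def read_peaklist_csv(path, sample_id: str | None = None) -> Spectrum:
    """Read one two-column (m/z, intensity) peak list.

    A header row is optional: if the first row parses as two numbers it is
    treated as data. ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    cells = [c.strip() for c in first.split(",")]
    has_header = True
    if len(cells) >= 2:
        try:
            float(cells[0]), float(cells[1])
            has_header = False
        except ValueError:
            pass
    try:
        df = pd.read_csv(path, header=0 if has_header else None, usecols=[0, 1], float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed peak list {path}: {exc}") from exc
    df.columns = ["mz", "intensity"]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"malformed peak list {path}: non-numeric {col} at data row {row}")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise ValueError(f"malformed peak list {path}: empty field at data row {row}")
    return Spectrum(sample_id or path.stem, df["mz"].to_numpy(float), df["intensity"].to_numpy(float))


def write_peaklist_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(path, index=False)


def read_spectra_table(path) -> list[Spectrum]:
    """Read a combined long-format CSV with columns sample_id, mz, intensity."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: combined spectra CSV needs columns {sorted(required)}")
    spectra = []
    for sid, grp in df.groupby("sample_id", sort=False):
        spectra.append(Spectrum(str(sid), grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float)))
    return spectra


def write_spectra_table(spectra, path) -> None:
    frames = [
        pd.DataFrame({"sample_id": s.sample_id, "mz": s.mz, "intensity": s.intensity})
        for s in spectra
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "mz", "intensity"]
    )
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _decode_binary_array(bda: "ET.Element") -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    import zlib

    accessions = {
        el.get("accession") for el in bda.iter() if el.tag.endswith("cvParam")
    }
    kind = None
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # 32- vs 64-bit float
    binary = next((el for el in bda.iter() if el.tag.endswith("binary")), None)
    raw = base64.b64decode(binary.text or "") if binary is not None else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[Spectrum]:
    """Read MS1 centroid spectra from mzML; sample_id is the spectrum id attribute.

    Handles uncompressed and zlib-compressed 32/64-bit float binary arrays.
    """
    spectra = []
    for event, elem in ET.iterparse(str(path), events=("end",)):
        if not elem.tag.endswith("}spectrum") and elem.tag != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if bda.tag.endswith("binaryDataArray"):
                kind, values = _decode_binary_array(bda)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"{path}: spectrum {elem.get('id')!r} lacks m/z or intensity array"
            )
        if arrays["mz"].size != arrays["intensity"].size:
            raise ValueError(f"{path}: spectrum {elem.get('id')!r} has mismatched arrays")
        spectra.append(Spectrum(str(elem.get("id")), arrays["mz"], arrays["intensity"]))
        elem.clear()
    return spectra


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra, path) -> None:
    """Write MS1 centroid spectra as minimal mzML (64-bit float, no compression)."""
    NS = "http://psi.hupo.org/ms/mzml"
    ET.register_namespace("", NS)
    root = ET.Element(f"{{{NS}}}mzML", version="1.1.0")
    cvlist = ET.SubElement(root, f"{{{NS}}}cvList", count="1")
    ET.SubElement(
        cvlist, f"{{{NS}}}cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, f"{{{NS}}}run", id="run")
    slist = ET.SubElement(run, f"{{{NS}}}spectrumList", count=str(len(spectra)))

    def cv(parent, accession, name, value=""):
        ET.SubElement(
            parent, f"{{{NS}}}cvParam", cvRef="MS", accession=accession, name=name, value=value
        )

    for i, spec in enumerate(spectra):
        sp = ET.SubElement(
            slist, f"{{{NS}}}spectrum",
            index=str(i), id=spec.sample_id, defaultArrayLength=str(len(spec)),
        )
        cv(sp, "MS:1000511", "ms level", "1")
        cv(sp, "MS:1000127", "centroid spectrum")
        bal = ET.SubElement(sp, f"{{{NS}}}binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", spec.mz),
            ("MS:1000515", "intensity array", spec.intensity),
        ):
            encoded = _b64_doubles(arr)
            bda = ET.SubElement(bal, f"{{{NS}}}binaryDataArray", encodedLength=str(len(encoded)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, accession, name)
            ET.SubElement(bda, f"{{{NS}}}binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_spectra(path, format: str = "auto") -> list[Spectrum]:
    """Read spectra from a directory of per-well files or a single file.

    ``format`` is one of ``auto``, ``mzML``, ``peaklist_csv``. For a
    directory, files are read in sorted-name order; the sample id of a
    per-well CSV is the file stem, of an mzML spectrum its id attribute.
    A single CSV containing a ``sample_id`` column is treated as a combined
    long-format table.
    """
    path = Path(path)
    if path.is_dir():
        spectra: list[Spectrum] = []
        for child in sorted(path.iterdir()):
            if child.suffix.lower() == ".mzml" and format in ("auto", "mzML"):
                spectra.extend(read_mzml(child))
            elif child.suffix.lower() == ".csv" and format in ("auto", "peaklist_csv"):
                spectra.append(read_peaklist_csv(child))
        if not spectra:
            raise ValueError(f"no spectra found under {path}")
        return spectra
    if path.suffix.lower() == ".mzml" or format == "mzML":
        return read_mzml(path)
    with open(path) as fh:
        header = fh.readline()
    if "sample_id" in header:
        return read_spectra_table(path)
    return [read_peaklist_csv(path)]


# ---------------------------------------------------------------------------
# targets and samples
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = ("name", "lipid_class", "carbons", "double_bonds", "adduct", "target_mz")


def read_targets(path) -> list[LipidTarget]:
    """Read a target lipid list CSV; validates unique names and known classes."""
    df = pd.read_csv(path)
    missing = [c for c in _TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: target list missing columns {missing}")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValueError(f"{path}: duplicate lipid name {dup!r}")
    targets = []
    for _, row in df.iterrows():
        try:
            targets.append(
                LipidTarget(
                    name=str(row["name"]),
                    lipid_class=str(row["lipid_class"]),
                    carbons=int(row["carbons"]),
                    double_bonds=int(row["double_bonds"]),
                    adduct=str(row["adduct"]),
                    target_mz=float(row["target_mz"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid target row {row['name']!r}: {exc}") from exc
    return targets


def write_targets(targets, path) -> None:
    pd.DataFrame(
        [
            {
                "name": t.name,
                "lipid_class": t.lipid_class,
                "carbons": t.carbons,
                "double_bonds": t.double_bonds,
                "adduct": t.adduct,
                "target_mz": t.target_mz,
            }
            for t in targets
        ]
    ).to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "well": str}, keep_default_na=True)
    for col in ("genotype", "replicate", "experiment_id"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    validate_samples(samples)[list(SAMPLE_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: AbundanceMatrix, path) -> None:
    """Serialize as CSV with a ``# normalized=...`` first line; missing -> empty field."""
    with open(path, "w") as fh:
        fh.write(f"# normalized={'true' if matrix.normalized else 'false'}\n")
        matrix.values.to_csv(fh, index_label="sample_id", na_rep="", float_format=lambda v: repr(float(v)))


def read_matrix(path) -> AbundanceMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# normalized="):
            raise ValueError(f"{path}: missing '# normalized=' header line")
        flag = first.split("=", 1)[1].strip().lower()
        if flag not in ("true", "false"):
            raise ValueError(f"{path}: normalized flag must be true/false, got {flag!r}")
        df = pd.read_csv(fh, index_col="sample_id", na_values=["NA"], float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return AbundanceMatrix(df, normalized=flag == "true")
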