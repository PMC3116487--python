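"""Readers and writers for the formats the pipeline exchanges.

Per-spectrum traces travel as two-column CSV (mz, intensity) or profile
mzML; the sample sheet is a CSV mapping each spectrum to its biological
sample and factor levels.  Outputs are a peaks x profiles intensity
matrix CSV (peaks as rows, m/z first), an ANOVA TSV, Newick plus JSON
for the annotated dendrogram, and JSON reports.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from maldianova.preprocessing import IntensityMatrix
from maldianova.spectrum import Spectrum, Stage

SAMPLE_SHEET_COLUMNS = ["spectrum_file", "sample_id", "genotype", "diet",
                        "week", "preparation", "replicate"]


# ------------------------------------------------------------- spectra

def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spectrum.axis,
                  "intensity": spectrum.intensities}).to_csv(path, index=False)


def read_spectrum(path: str | Path, format: str | None = None,
                  spectrum_id: str | None = None) -> Spectrum:
    """Read a raw spectrum from CSV (mz,intensity) or profile mzML."""
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    sid = spectrum_id or path.stem
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"mz", "intensity"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns mz,intensity")
        return Spectrum(sid, df["mz"].to_numpy(), df["intensity"].to_numpy(),
                        Stage.RAW)
    if fmt == "mzml":
        spectra = read_mzml_all(path)
        if not spectra:
            raise ValueError(f"{path}: no spectra in mzML file")
        first = spectra[0]
        return Spectrum(spectrum_id or first.spectrum_id, first.axis,
                        first.intensities, Stage.RAW)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: list[Spectrum], path: str | Path) -> None:
    """Write profile spectra as minimal mzML 1.1 (64-bit, uncompressed).

    Only the elements needed by standard readers are emitted: one
    ``spectrum`` per trace with m/z and intensity binary arrays.
    """
    lines = ['<?xml version="1.0" encoding="utf-8"?>',
             '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
             '  <run id="maldianova">',
             f'    <spectrumList count="{len(spectra)}">']
    for i, s in enumerate(spectra):
        enc_mz, enc_it = _b64(s.axis), _b64(s.intensities)
        lines += [
            f'      <spectrum index="{i}" id="spectrum={escape(s.spectrum_id)}" '
            f'defaultArrayLength="{len(s)}">',
            '        <cvParam cvRef="MS" accession="MS:1000128" '
            'name="profile spectrum" value=""/>',
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(enc_mz)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" '
            'name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" '
            'name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" '
            'name="m/z array" value="" unitCvRef="MS" '
            'unitAccession="MS:1000040" unitName="m/z"/>',
            f'            <binary>{enc_mz}</binary>',
            '          </binaryDataArray>',
            f'          <binaryDataArray encodedLength="{len(enc_it)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" '
            'name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" '
            'name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" '
            'name="intensity array" value="" unitCvRef="MS" '
            'unitAccession="MS:1000131" unitName="number of detector counts"/>',
            f'            <binary>{enc_it}</binary>',
            '          </binaryDataArray>',
            '        </binaryDataArrayList>',
            '      </spectrum>',
        ]
    lines += ['    </spectrumList>', '  </run>', '</mzML>', '']
    Path(path).write_text("\n".join(lines))


_ARRAY_KINDS = {"MS:1000514": "mz", "MS:1000515": "intensity"}


def _decode_binary_array(bda: ET.Element, ns: str) -> tuple[str | None,
                                                            np.ndarray]:
    kind, dtype, compressed = None, "<d", False
    for cv in bda.findall(f"{ns}cvParam"):
        acc = cv.get("accession", "")
        if acc in _ARRAY_KINDS:
            kind = _ARRAY_KINDS[acc]
        elif acc == "MS:1000521":          # 32-bit float
            dtype = "<f"
        elif acc == "MS:1000574":          # zlib compression
            compressed = True
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    values = np.array(struct.unpack(f"{dtype[0]}{len(raw) // width}{dtype[1]}",
                                    raw))
    return kind, values


def read_mzml_all(path: str | Path) -> list[Spectrum]:
    """Read every profile spectrum from an mzML file.

    Minimal reader for 32/64-bit float arrays, plain or zlib-compressed,
    covering the subset of mzML 1.1 this package writes and the common
    output of converters.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    out: list[Spectrum] = []
    for spec in root.iter(f"{ns}spectrum"):
        sid = spec.get("id", f"spectrum{len(out)}")
        sid = sid.split("spectrum=", 1)[-1]
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ns)
            if kind:
                arrays[kind] = values
        if {"mz", "intensity"} <= arrays.keys():
            out.append(Spectrum(sid, arrays["mz"], arrays["intensity"],
                                Stage.RAW))
    return out


# -------------------------------------------------------- sample sheet

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Validated sample sheet: one row per spectrum.

    Requires the canonical columns and rejects duplicated
    (sample_id, preparation, replicate) keys.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty sample sheet")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    key = df[["sample_id", "preparation", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"{path}: duplicated replicate key {dup}")
    if "spectrum_id" not in df.columns:
        df = df.assign(spectrum_id=[Path(f).stem for f in df["spectrum_file"]])
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


# ------------------------------------------------------------- tables

def write_matrix_csv(matrix: IntensityMatrix, path: str | Path) -> None:
    """Peaks as rows, m/z as the first column, one column per profile."""
    df = matrix.data.copy()
    df.insert(0, "peak_index", matrix.peak_indices)
    df.to_csv(path, index_label="mz")


def read_matrix_csv(path: str | Path,
                    level: str = "replicate") -> IntensityMatrix:
    df = pd.read_csv(path, index_col="mz", float_precision="round_trip")
    peak_indices = df.pop("peak_index").to_numpy(dtype=int)
    return IntensityMatrix(df, peak_indices, level)


def write_anova_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["f_diet", "p_diet", "f_genotype", "p_genotype", "f_week",
            "p_week", "f_interaction", "p_interaction", "flags"]
    table[[c for c in cols if c in table.columns]].to_csv(
        path, sep="\t", index_label="peak_mz")


def read_anova_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peak_mz",
                       float_precision="round_trip")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
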