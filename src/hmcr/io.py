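"""Reading and writing the pipeline's on-disk artifacts.

Raw data moves as ANDI-style netCDF (one file per sample, centroided
``mass_values`` / ``intensity_values`` point lists) or mzML (read-only);
everything derived — sample manifests, peak tables, reference tables,
selection results and reports — is plain CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import netcdf_file

from .datatypes import GCMSDataset, IonMap, PeakTable, ReferenceTable, SpectralProfile

__all__ = [
    "write_andi",
    "read_andi",
    "write_dataset",
    "read_dataset",
    "read_mzml",
    "write_peaktable",
    "read_peaktable",
    "write_reference_table",
    "read_reference_table",
    "write_json",
    "read_json",
]


def write_andi(ionmap: IonMap, path: str | Path) -> None:
    """Write one sample as an ANDI/netCDF-style file (nonzero points only)."""
    path = Path(path)
    n_scans = len(ionmap.rt_axis)
    masses, intens, scan_index, point_count = [], [], [], []
    offset = 0
    for i in range(n_scans):
        nz = np.nonzero(ionmap.intensities[i])[0]
        scan_index.append(offset)
        point_count.append(len(nz))
        masses.append(ionmap.mz_axis[nz])
        intens.append(ionmap.intensities[i, nz])
        offset += len(nz)
    masses = np.concatenate(masses) if masses else np.empty(0)
    intens = np.concatenate(intens) if intens else np.empty(0)

    with netcdf_file(str(path), "w") as f:
        f.createDimension("scan_number", n_scans)
        f.createDimension("point_number", max(int(offset), 1))
        v = f.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = ionmap.rt_axis
        v = f.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.asarray(scan_index, dtype=np.int32)
        v = f.createVariable("point_count", "i", ("scan_number",))
        v[:] = np.asarray(point_count, dtype=np.int32)
        v = f.createVariable("mass_values", "d", ("point_number",))
        v[: len(masses)] = masses
        v = f.createVariable("intensity_values", "d", ("point_number",))
        v[: len(intens)] = intens


def read_andi(
    path: str | Path, sample_id: str | None = None, mz_axis: np.ndarray | None = None
) -> IonMap:
    """Read an ANDI/netCDF file into a dense ion map on nominal m/z channels.

    If ``mz_axis`` is given the intensities are binned onto it (masses
    rounded to the nearest channel); otherwise the axis spans the file's
    own integer mass range.
    """
    path = Path(path)
    with netcdf_file(str(path), "r", mmap=False) as f:
        rt = np.array(f.variables["scan_acquisition_time"][:], dtype=float)
        scan_index = np.array(f.variables["scan_index"][:], dtype=int)
        point_count = np.array(f.variables["point_count"][:], dtype=int)
        masses = np.array(f.variables["mass_values"][:], dtype=float)
        intens = np.array(f.variables["intensity_values"][:], dtype=float)

    if mz_axis is None:
        if point_count.sum() == 0:
            raise ValueError(f"{path}: file contains no data points")
        lo = int(np.floor(masses[: point_count.sum()].min()))
        hi = int(np.ceil(masses[: point_count.sum()].max()))
        mz_axis = np.arange(lo, hi + 1, dtype=float)
    mz_axis = np.asarray(mz_axis, dtype=float)

    x = np.zeros((len(rt), len(mz_axis)))
    mz0 = mz_axis[0]
    for i in range(len(rt)):
        s, c = scan_index[i], point_count[i]
        if c == 0:
            continue
        cols = np.rint(masses[s : s + c] - mz0).astype(int)
        keep = (cols >= 0) & (cols < len(mz_axis))
        np.add.at(x[i], cols[keep], intens[s : s + c][keep])
    return IonMap(
        sample_id=sample_id or path.stem, intensities=x, rt_axis=rt, mz_axis=mz_axis
    )


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one mzML binaryDataArray element (base64, optional zlib)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.iter() if cv.tag.endswith("cvParam")
    }
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = elem.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_scans(path: Path) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """MS1 scans of an mzML file as (rt seconds, m/z, intensity) triples."""
    from lxml import etree

    scans = []
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spectrum.iter("{*}cvParam")
        }
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", ""):
            spectrum.clear()
            continue
        rt_cv = params.get("MS:1000016")
        rt = float(rt_cv.get("value")) if rt_cv is not None else float(len(scans))
        if rt_cv is not None and rt_cv.get("unitName", "").startswith("min"):
            rt *= 60.0
        mz = inten = None
        for arr in spectrum.iter("{*}binaryDataArray"):
            acc = {cv.get("accession") for cv in arr.iter("{*}cvParam")}
            if "MS:1000514" in acc:
                mz = _decode_binary_array(arr)
            elif "MS:1000515" in acc:
                inten = _decode_binary_array(arr)
        if mz is not None and inten is not None:
            scans.append((rt, mz, inten))
        spectrum.clear()
    return scans


def read_mzml(
    path: str | Path, sample_id: str | None = None, mz_axis: np.ndarray | None = None
) -> IonMap:
    """Read an mzML file into a dense ion map on nominal m/z channels.

    A compact lxml-based reader covering MS1 spectra with uncompressed or
    zlib-compressed 32/64-bit float arrays — the profile of centroided
    GC/MS unit-mass data this pipeline consumes.
    """
    path = Path(path)
    scans = _parse_mzml_scans(path)
    if not scans:
        raise ValueError(f"{path}: no MS1 spectra found")
    scans.sort(key=lambda s: s[0])
    if mz_axis is None:
        lo = int(np.floor(min(s[1].min() for s in scans if len(s[1]))))
        hi = int(np.ceil(max(s[1].max() for s in scans if len(s[1]))))
        mz_axis = np.arange(lo, hi + 1, dtype=float)
    mz_axis = np.asarray(mz_axis, dtype=float)
    rt = np.array([s[0] for s in scans])
    x = np.zeros((len(scans), len(mz_axis)))
    mz0 = mz_axis[0]
    for i, (_, mz, inten) in enumerate(scans):
        cols = np.rint(np.asarray(mz) - mz0).astype(int)
        keep = (cols >= 0) & (cols < len(mz_axis))
        np.add.at(x[i], cols[keep], np.asarray(inten)[keep])
    return IonMap(
        sample_id=sample_id or path.stem, intensities=x, rt_axis=rt, mz_axis=mz_axis
    )


def write_dataset(dataset: GCMSDataset, outdir: str | Path) -> Path:
    """Write one ANDI file per sample plus a ``samples.csv`` manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    filenames = []
    for s in dataset.samples:
        fn = f"{s.sample_id}.cdf"
        write_andi(s, outdir / fn)
        filenames.append(fn)
    manifest = dataset.metadata.copy()
    manifest["filename"] = filenames
    manifest_path = outdir / "samples.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(directory: str | Path) -> GCMSDataset:
    """Load a dataset from a directory with a ``samples.csv`` manifest."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "samples.csv")
    # shared axis: union of the per-file integer mass ranges
    raw = []
    for _, row in manifest.iterrows():
        p = directory / row["filename"]
        reader = read_mzml if p.suffix.lower() == ".mzml" else read_andi
        raw.append(reader(p, sample_id=str(row["sample_id"])))
    lo = min(m.mz_axis[0] for m in raw)
    hi = max(m.mz_axis[-1] for m in raw)
    mz_axis = np.arange(lo, hi + 1, dtype=float)
    samples = []
    for m, (_, row) in zip(raw, manifest.iterrows()):
        p = directory / row["filename"]
        reader = read_mzml if p.suffix.lower() == ".mzml" else read_andi
        samples.append(reader(p, sample_id=str(row["sample_id"]), mz_axis=mz_axis))
    return GCMSDataset(samples=samples, metadata=manifest.drop(columns=["filename"]))


def write_peaktable(
    pt: PeakTable, path: str | Path, apex_rts: list[float] | None = None
) -> None:
    """Peak table as CSV: rows = samples, columns = profile IDs.

    Apex retention times, when given, go in a leading comment line so the
    table body stays a plain samples x profiles matrix.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if apex_rts is not None:
            fh.write("# apex_rt," + ",".join(f"{t:.6g}" for t in apex_rts) + "\n")
        if pt.normalized:
            fh.write("# normalized,true\n")
        pt.to_frame().rename_axis("sample_id").to_csv(fh)


def read_peaktable(path: str | Path) -> PeakTable:
    normalized = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# normalized,true"):
                normalized = True
    df = pd.read_csv(path, comment="#", index_col="sample_id")
    return PeakTable.from_frame(df, normalized=normalized)


def write_reference_table(table: ReferenceTable, path: str | Path) -> None:
    payload = {
        "mz_axis": table.mz_axis.tolist(),
        "provenance": table.provenance,
        "profiles": [
            {
                "profile_id": p.profile_id,
                "apex_rt": p.apex_rt,
                "window_id": p.window_id,
                "stable": bool(p.stable),
                "spectrum": p.spectrum.tolist(),
            }
            for p in table.profiles
        ],
    }
    write_json(payload, path)


def read_reference_table(path: str | Path) -> ReferenceTable:
    payload = read_json(path)
    profiles = [
        SpectralProfile(
            profile_id=d["profile_id"],
            spectrum=np.asarray(d["spectrum"]),
            apex_rt=float(d["apex_rt"]),
            window_id=int(d["window_id"]),
            stable=bool(d["stable"]),
        )
        for d in payload["profiles"]
    ]
    return ReferenceTable(
        profiles=profiles,
        mz_axis=np.asarray(payload["mz_axis"]),
        provenance=payload.get("provenance", {}),
    )


def write_json(payload: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
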