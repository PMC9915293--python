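"""Record readers/writers (CSV, WFDB) and evaluation report tables.

Samples are always read and written as raw digital integers (ADU).  The
codec path never converts to physical units — millivolt conversion via the
gain is display-only — because any unit conversion would break losslessness.

The WFDB support here is a small self-contained reader/writer for the
header (``.hea``) plus signal formats 16 (little-endian int16) and 212
(packed 12-bit pairs), the formats used by the classic arrhythmia and ST-T
databases.  It reads digital samples only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import CompressionReport
from .records import ECGRecord, Lead

__all__ = [
    "read_record",
    "read_csv_record",
    "write_csv_record",
    "read_wfdb_record",
    "write_wfdb_record",
    "write_report",
    "scan_dataset",
]

logger = logging.getLogger("alpc")


class MetadataError(ValueError):
    """A required acquisition-metadata field is missing or malformed."""


# -- CSV ----------------------------------------------------------------------


def read_csv_record(
    path,
    fs: float | None = None,
    resolution_bits: int | None = None,
    gain: float | None = None,
    name: str | None = None,
) -> ECGRecord:
    """Read a single-lead CSV record.

    Two dialects are accepted:

    * a header line ``name,fs,bits,gain`` followed by one integer per line;
    * one integer per line, with metadata from a ``<path>.meta`` sidecar
      (``key = value`` lines: fs, bits, gain, name) or from the keyword
      arguments.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty CSV record")
    lead_name = "I"
    start = 0
    if "," in lines[0]:
        fields = [f.strip() for f in lines[0].split(",")]
        if len(fields) != 4:
            raise ValueError(f"{path}: header must be 'name,fs,bits,gain'")
        lead_name, fs, resolution_bits, gain = (
            fields[0],
            float(fields[1]),
            int(fields[2]),
            float(fields[3]),
        )
        start = 1
    else:
        sidecar = path.with_suffix(path.suffix + ".meta")
        if sidecar.exists():
            meta = _parse_sidecar(sidecar)
            fs = float(meta.get("fs", fs or 0)) or fs
            resolution_bits = int(meta.get("bits", resolution_bits or 0)) or resolution_bits
            gain = float(meta.get("gain", gain or 0)) or gain
            lead_name = meta.get("name", lead_name)
    if fs is None or resolution_bits is None:
        raise MetadataError(
            f"{path}: sampling frequency and bit resolution must come from a "
            "header line, a .meta sidecar, or keyword arguments"
        )
    samples = []
    for i, ln in enumerate(lines[start:], start=start + 1):
        try:
            samples.append(int(ln))
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: non-integer sample {ln!r}") from exc
    arr = np.asarray(samples, dtype=np.int64)
    signed = bool(arr.size and arr.min() < 0)
    return ECGRecord(
        name=name or path.stem,
        fs=fs,
        resolution_bits=resolution_bits,
        leads=[Lead(name=lead_name, samples=arr, adu_per_mv=gain or 200.0)],
        signed=signed,
    )


def _parse_sidecar(path: Path) -> dict:
    meta = {}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or "=" not in ln:
            continue
        key, _, value = ln.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def write_csv_record(record: ECGRecord, path, lead: str | None = None) -> None:
    """Write one lead as header-dialect CSV (name,fs,bits,gain then samples)."""
    the_lead = record.get_lead(lead) if lead else record.leads[0]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"{the_lead.name},{record.fs:g},{record.resolution_bits},"
            f"{the_lead.adu_per_mv:g}\n"
        )
        fh.write("\n".join(str(int(v)) for v in the_lead.samples))
        fh.write("\n")


# -- WFDB ---------------------------------------------------------------------


def read_wfdb_record(header_path) -> ECGRecord:
    """Read a WFDB record (``.hea`` + signal files, formats 16 and 212)."""
    header_path = Path(header_path)
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise MetadataError(f"{header_path}: record line needs name, n_sig, fs, n_samples")
    rec_name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    specs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise MetadataError(f"{header_path}: malformed signal line {ln!r}")
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain = 200.0
        adc_res = 12
        if len(tok) > 2:
            gain_str = tok[2].split("(")[0].split("/")[0]
            gain = float(gain_str) if float(gain_str) != 0 else 200.0
        if len(tok) > 3:
            adc_res = int(tok[3])
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(specs)}"
        specs.append(dict(fname=fname, fmt=fmt, gain=gain, adc_res=adc_res, desc=desc))
    by_file: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_file.setdefault(s["fname"], []).append(i)
    signals: dict[int, np.ndarray] = {}
    for fname, idxs in by_file.items():
        data = (header_path.parent / fname).read_bytes()
        fmt = specs[idxs[0]]["fmt"]
        if any(specs[i]["fmt"] != fmt for i in idxs):
            raise MetadataError(f"{fname}: mixed signal formats in one file")
        mat = _read_signal_file(data, fmt, len(idxs), n_samples, fname)
        for col, i in enumerate(idxs):
            signals[i] = mat[:, col]
    res_bits = max(s["adc_res"] for s in specs)
    leads = [
        Lead(name=specs[i]["desc"], samples=signals[i], adu_per_mv=specs[i]["gain"])
        for i in range(n_sig)
    ]
    signed = any(lead.samples.size and lead.samples.min() < 0 for lead in leads)
    return ECGRecord(
        name=rec_name,
        fs=fs,
        resolution_bits=max(8, res_bits),
        leads=leads,
        signed=signed,
    )


def _read_signal_file(
    data: bytes, fmt: int, n_sig: int, n_samples: int, fname: str
) -> np.ndarray:
    if fmt == 16:
        flat = np.frombuffer(data, dtype="<i2")
        flat = flat[: n_samples * n_sig]
        return flat.reshape(-1, n_sig).astype(np.int64)
    if fmt == 212:
        total = n_samples * n_sig
        raw = np.frombuffer(data, dtype=np.uint8)
        n_pairs = (total + 1) // 2
        raw = raw[: 3 * n_pairs]
        b0 = raw[0::3].astype(np.int64)
        b1 = raw[1::3].astype(np.int64)
        b2 = raw[2::3].astype(np.int64)
        first = ((b1 & 0x0F) << 8) | b0
        second = ((b1 & 0xF0) << 4) | b2
        # 12-bit two's complement
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * len(b0), dtype=np.int64)
        flat[0::2] = first
        flat[1::2] = second
        return flat[:total].reshape(-1, n_sig)
    raise MetadataError(f"{fname}: unsupported WFDB signal format {fmt}")


def write_wfdb_record(record: ECGRecord, directory) -> Path:
    """Write a record as a format-16 WFDB pair (``.hea`` + ``.dat``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hea = directory / f"{record.name}.hea"
    dat_name = f"{record.name}.dat"
    lines = [f"{record.name} {len(record.leads)} {record.fs:g} {record.n_samples}"]
    for lead in record.leads:
        first = int(lead.samples[0]) if len(lead.samples) else 0
        lines.append(
            f"{dat_name} 16 {lead.adu_per_mv:g} {record.resolution_bits} 0 "
            f"{first} 0 0 {lead.name}"
        )
    hea.write_text("\n".join(lines) + "\n")
    mat = np.stack([lead.samples for lead in record.leads], axis=1)
    if mat.min() < -(1 << 15) or mat.max() >= (1 << 15):
        raise ValueError("format 16 holds only int16 samples")
    (directory / dat_name).write_bytes(mat.astype("<i2").tobytes())
    return hea


def read_record(path, fmt: str | None = None, lead: str | None = None) -> ECGRecord:
    """Read a record, inferring the format from the extension if not given."""
    path = Path(path)
    if fmt is None:
        if path.suffix in (".csv", ".txt"):
            fmt = "csv"
        elif path.suffix in (".hea", ".dat") or path.with_suffix(".hea").exists():
            fmt = "wfdb"
        else:
            raise ValueError(f"cannot infer format of {path} (use fmt='csv'|'wfdb')")
    if fmt == "csv":
        record = read_csv_record(path)
    elif fmt == "wfdb":
        record = read_wfdb_record(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if lead is not None:
        record = ECGRecord(
            name=record.name,
            fs=record.fs,
            resolution_bits=record.resolution_bits,
            leads=[record.get_lead(lead)],
            signed=record.signed,
        )
    return record


def scan_dataset(root, pattern: str = "*.hea") -> list[Path]:
    """Resolvable record headers under a dataset root, sorted by name."""
    root = Path(root)
    paths = sorted(root.glob(pattern)) or sorted(root.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no records found under {root}")
    return paths


# -- reports ------------------------------------------------------------------


def reports_to_frame(reports: list[CompressionReport]) -> pd.DataFrame:
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = []
    for r in reports:
        usage = r.order_usage
        rows.append(
            {
                "record": r.record,
                "lead": r.lead,
                "n_samples": r.n_samples,
                "B0_bits": r.b0_bits,
                "BC_bits": r.bc_bits,
                "CR": r.cr,
                "order1_pct": 100 * usage[0],
                "order2_pct": 100 * usage[1],
                "order3_pct": 100 * usage[2],
                "order4_pct": 100 * usage[3],
                "PRD": r.prd,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {c: "" for c in df.columns}
    mean_row.update({"record": "MEAN", "CR": df["CR"].mean()})
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def write_report(reports: list[CompressionReport], path) -> None:
    """Write per-lead compression reports plus a mean-CR row (CSV or JSON)."""
    df = reports_to_frame(reports)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        df.to_csv(path, index=False)
    logger.info("wrote %d report rows to %s", len(df), path)
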