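"""Reading and writing 1D spectra and correction reports.

Three spectrum dialects are supported:

* ``delimited`` — TSV with a header line and columns ``ppm, real[, imag]``,
  ppm axis descending (the NMR plotting convention);
* ``binary_container`` — a versioned NumPy ``.npz`` container, exact
  round trip;
* ``bruker_processed`` — a minimal reader for Bruker processed-data
  directories (``procs`` parameter file plus ``1r``/``1i`` integer
  arrays), covering the parameters needed to rebuild the ppm axis.

Internally all math is index-based (0-based, ascending channels); the
ppm axis is metadata applied only at I/O time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .baseline import BaselineSplit
from .fif import Decomposition

__all__ = [
    "SpectrumRecord",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "write_correction_report",
    "read_correction_report",
]

logger = logging.getLogger(__name__)

Dialect = Literal["delimited", "binary_container", "bruker_processed"]

_CONTAINER_VERSION = 1


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed under the named dialect."""


@dataclass
class SpectrumRecord:
    """A 1D spectrum with its frequency axis and acquisition metadata."""

    axis: np.ndarray
    real_part: np.ndarray
    imag_part: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.real_part = np.asarray(self.real_part, dtype=float)
        if self.imag_part is not None:
            self.imag_part = np.asarray(self.imag_part, dtype=float)
        if self.axis.size != self.real_part.size:
            raise ValueError("axis and real_part must have equal length")
        if self.imag_part is not None and self.imag_part.size != self.axis.size:
            raise ValueError("axis and imag_part must have equal length")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")


def _normalize_descending(record: SpectrumRecord) -> SpectrumRecord:
    if record.axis.size > 1 and record.axis[1] > record.axis[0]:
        logger.warning("ppm axis is ascending; reversing to NMR convention")
        record.axis = record.axis[::-1].copy()
        record.real_part = record.real_part[::-1].copy()
        if record.imag_part is not None:
            record.imag_part = record.imag_part[::-1].copy()
    return record


def _read_delimited(path: Path) -> SpectrumRecord:
    try:
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    except (OSError, ValueError) as exc:
        raise SpectrumParseError(f"{path}: cannot parse delimited spectrum: {exc}") from exc
    if data.size == 0 or data.shape[1] < 2:
        raise SpectrumParseError(f"{path}: need at least columns ppm and real")
    if len(header) != data.shape[1]:
        raise SpectrumParseError(
            f"{path}: header has {len(header)} fields but data rows have {data.shape[1]}"
        )
    imag = data[:, 2] if data.shape[1] >= 3 else None
    return SpectrumRecord(
        axis=data[:, 0],
        real_part=data[:, 1],
        imag_part=imag,
        meta={"source": str(path), "npoints": data.shape[0]},
    )


def _read_container(path: Path) -> SpectrumRecord:
    try:
        with np.load(path, allow_pickle=False) as npz:
            version = int(npz["format_version"])
            if version != _CONTAINER_VERSION:
                raise SpectrumParseError(
                    f"{path}: unsupported container version {version}"
                )
            meta = json.loads(str(npz["meta_json"]))
            imag = npz["imag_part"] if "imag_part" in npz.files else None
            return SpectrumRecord(
                axis=npz["axis"], real_part=npz["real_part"], imag_part=imag, meta=meta
            )
    except (OSError, KeyError, ValueError) as exc:
        if isinstance(exc, SpectrumParseError):
            raise
        raise SpectrumParseError(f"{path}: cannot parse container: {exc}") from exc


_JCAMP_RE = re.compile(r"^##\$?(?P<key>[A-Za-z_0-9]+)=\s*(?P<value>.*)$")


def _read_bruker_params(procs: Path) -> dict:
    params: dict = {}
    try:
        text = procs.read_text(errors="replace")
    except OSError as exc:
        raise SpectrumParseError(f"{procs}: cannot read: {exc}") from exc
    for line in text.splitlines():
        m = _JCAMP_RE.match(line.strip())
        if m:
            value = m.group("value").strip()
            try:
                params[m.group("key")] = float(value) if "." in value or "e" in value.lower() else int(value)
            except ValueError:
                params[m.group("key")] = value
    return params


def _read_bruker(path: Path) -> SpectrumRecord:
    """Minimal Bruker processed-data reader (procs + 1r [+ 1i])."""
    directory = path if path.is_dir() else path.parent
    procs = directory / "procs"
    if not procs.exists():
        raise SpectrumParseError(f"{directory}: no procs file found")
    params = _read_bruker_params(procs)
    for key in ("SI", "SW_p", "SF", "OFFSET"):
        if key not in params:
            raise SpectrumParseError(f"{procs}: missing parameter {key}")
    si = int(params["SI"])
    dtype = "<i4" if int(params.get("BYTORDP", 0)) == 0 else ">i4"
    scale = 2.0 ** int(params.get("NC_proc", 0))

    def _load(name: str) -> np.ndarray | None:
        f = directory / name
        if not f.exists():
            return None
        raw = np.fromfile(f, dtype=dtype)
        if raw.size != si:
            raise SpectrumParseError(f"{f}: expected {si} points, found {raw.size}")
        return raw.astype(float) * scale

    real = _load("1r")
    if real is None:
        raise SpectrumParseError(f"{directory}: no 1r file found")
    imag = _load("1i")
    sw_ppm = float(params["SW_p"]) / float(params["SF"])
    axis = float(params["OFFSET"]) - np.arange(si) * sw_ppm / si
    meta = {
        "source": str(directory),
        "npoints": si,
        "sw_ppm": sw_ppm,
        "spectrometer_MHz": float(params["SF"]),
        "carrier_ppm": float(params["OFFSET"]) - sw_ppm / 2.0,
    }
    return SpectrumRecord(axis=axis, real_part=real, imag_part=imag, meta=meta)


def read_spectrum(path: str | Path, dialect: Dialect = "delimited") -> SpectrumRecord:
    """Read a spectrum file; see the module docstring for dialects."""
    path = Path(path)
    if dialect == "delimited":
        record = _read_delimited(path)
    elif dialect == "binary_container":
        record = _read_container(path)
    elif dialect == "bruker_processed":
        record = _read_bruker(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _normalize_descending(record)


def write_spectrum(
    record: SpectrumRecord, path: str | Path, dialect: Dialect = "delimited"
) -> None:
    """Write a spectrum in the delimited or container dialect."""
    path = Path(path)
    if dialect == "delimited":
        cols = [record.axis, record.real_part]
        header = "ppm\treal"
        if record.imag_part is not None:
            cols.append(record.imag_part)
            header += "\timag"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, np.column_stack(cols), delimiter="\t", fmt="%.12e")
    elif dialect == "binary_container":
        payload = {
            "format_version": _CONTAINER_VERSION,
            "axis": record.axis,
            "real_part": record.real_part,
            "meta_json": json.dumps(record.meta),
        }
        if record.imag_part is not None:
            payload["imag_part"] = record.imag_part
        np.savez(path, **payload)
    else:
        raise ValueError(f"cannot write dialect {dialect!r}")


def write_correction_report(
    split: BaselineSplit, decomposition: Decomposition, path: str | Path
) -> None:
    """Write a correction run to a directory: ``report.json`` (chosen
    split, CPR profile, per-IMF iteration counts and mask lengths),
    ``corrected.tsv`` (input, signal and baseline estimates) and
    ``imfs.tsv`` (the IMF stack plus remainder).  Deterministic output
    for identical inputs."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "k_signal": int(split.k_signal),
        "auto_selected": bool(split.auto_selected),
        "cpr_profile": [None if np.isnan(v) else float(v) for v in split.cpr_profile],
        "n_imfs": decomposition.n_imfs,
        "iterations": [int(v) for v in decomposition.iterations],
        "mask_lengths": [int(v) for v in decomposition.mask_lengths],
        "input_length": decomposition.input_length,
        "windowed": split.window is not None,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    reconstructed = split.signal_estimate + split.baseline_estimate
    table = np.column_stack(
        [
            np.arange(decomposition.input_length),
            reconstructed,
            split.signal_estimate,
            split.baseline_estimate,
        ]
    )
    with open(out / "corrected.tsv", "w") as fh:
        fh.write("channel\tinput\tsignal_estimate\tbaseline_estimate\n")
        np.savetxt(fh, table, delimiter="\t", fmt=["%d", "%.12e", "%.12e", "%.12e"])

    stack = np.column_stack(
        [np.arange(decomposition.input_length)]
        + list(decomposition.imfs)
        + [decomposition.remainder]
    )
    header = (
        "channel\t"
        + "\t".join(f"imf_{i}" for i in range(decomposition.n_imfs))
        + "\tremainder"
    )
    with open(out / "imfs.tsv", "w") as fh:
        fh.write(header + "\n")
        np.savetxt(
            fh, stack, delimiter="\t", fmt=["%d"] + ["%.12e"] * (decomposition.n_imfs + 1)
        )


def read_correction_report(path: str | Path) -> dict:
    """Parse back a ``report.json`` written by :func:`write_correction_report`."""
    report = json.loads((Path(path) / "report.json").read_text())
    report["cpr_profile"] = np.array(
        [np.nan if v is None else v for v in report["cpr_profile"]]
    )
    return report
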