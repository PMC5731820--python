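"""TSV/FASTA/config I/O with provenance headers.

All interchange is tab-separated text with '#'-prefixed metadata headers:
columnar, diff-able, and adequate at desk scale.  Readers validate the
required columns and report the missing column by name; writers prepend a
provenance block (tool version, config hash, seed, input digests) so any
result table can be traced to its inputs.  Configurations are flat
``key = value`` text files hashed over all keys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import TitrationDataset
from .condense import ForceExtensionCurve
from .spectra import MeltCurve, PeakList
from .tethersim import Trajectory

__all__ = [
    "FormatError",
    "RunConfig",
    "provenance_header",
    "read_trajectory",
    "write_trajectory",
    "read_curve",
    "write_curve",
    "read_titrations",
    "write_titration",
    "read_spectrum",
    "read_peaklist",
    "read_melt",
    "read_mz_list",
    "read_fasta",
    "read_table",
    "write_table",
]

TRAJ_COLUMNS = ["t_s", "x_nm", "y_nm", "z_nm", "force_pN", "turns"]
CURVE_COLUMNS = ["force_pN", "ext_nm", "sem_nm", "n"]
TITRATION_COLUMNS = ["label", "conc_nM", "response", "replicate"]


class FormatError(ValueError):
    """Raised on malformed interchange files."""


@dataclass
class RunConfig:
    """Flat key = value configuration with a stable content hash."""

    values: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values: dict[str, str] = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        return cls(values)

    def to_file(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self.values.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @property
    def hash(self) -> str:
        payload = "\n".join(f"{k} = {v}" for k, v in sorted(self.values.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.values.get(key, default)

    def require(self, key: str) -> str:
        if key not in self.values:
            raise KeyError(f"config key {key!r} is required")
        return self.values[key]


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def provenance_header(
    *, tool_version: str | None = None, config_hash: str | None = None,
    seed: int | None = None, inputs: list | None = None,
) -> list[str]:
    """'#'-prefixed provenance lines for result tables."""
    from . import __version__

    lines = [f"# tetherkit {tool_version or __version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash {config_hash}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    for p in inputs or []:
        lines.append(f"# input {Path(p).name} sha256:{_file_digest(p)}")
    return lines


def write_table(frame: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a DataFrame as TSV under an optional '#' header block."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a '#'-commented TSV, checking required columns by name."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc
    for col in required or []:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return frame


def read_trajectory(path) -> Trajectory:
    frame = read_table(path, required=TRAJ_COLUMNS)
    t = frame["t_s"].to_numpy(float)
    if t.size < 2:
        raise FormatError(f"{path}: trajectory needs >= 2 samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    lc = frame["lc_eff_nm"].to_numpy(float) if "lc_eff_nm" in frame.columns else None
    return Trajectory(
        t,
        frame["x_nm"].to_numpy(float),
        frame["y_nm"].to_numpy(float),
        frame["z_nm"].to_numpy(float),
        frame["force_pN"].to_numpy(float),
        frame["turns"].to_numpy(float),
        lc,
        rate,
    )


def write_trajectory(traj: Trajectory, path, header_lines: list[str] | None = None) -> None:
    cols = {
        "t_s": traj.time, "x_nm": traj.x, "y_nm": traj.y, "z_nm": traj.z,
        "force_pN": traj.applied_force, "turns": traj.turns,
    }
    if traj.effective_contour is not None:
        cols["lc_eff_nm"] = traj.effective_contour
    write_table(pd.DataFrame(cols), path, header_lines)


def read_curve(path, label: str = "") -> ForceExtensionCurve:
    frame = read_table(path, required=CURVE_COLUMNS)
    return ForceExtensionCurve(
        frame["force_pN"].to_numpy(float),
        frame["ext_nm"].to_numpy(float),
        frame["sem_nm"].to_numpy(float),
        frame["n"].to_numpy(int),
        label or str(Path(path).stem),
    )


def write_curve(curve: ForceExtensionCurve, path,
                header_lines: list[str] | None = None) -> None:
    frame = pd.DataFrame({
        "force_pN": curve.force, "ext_nm": curve.mean_extension,
        "sem_nm": curve.sem, "n": curve.n_molecules,
    })
    write_table(frame, path, header_lines)


def read_titrations(path) -> list[TitrationDataset]:
    """Read a titration TSV; one dataset per distinct label."""
    frame = read_table(path, required=TITRATION_COLUMNS)
    out = []
    for label, grp in frame.groupby("label", sort=False):
        out.append(TitrationDataset(
            str(label),
            grp["conc_nM"].to_numpy(float),
            grp["response"].to_numpy(float),
            grp["replicate"].to_numpy(),
        ))
    return out


def write_titration(data: TitrationDataset, path,
                    header_lines: list[str] | None = None) -> None:
    frame = pd.DataFrame({
        "label": data.label,
        "conc_nM": data.concentrations,
        "response": data.responses,
        "replicate": (data.replicate_ids if data.replicate_ids is not None
                      else np.zeros(len(data.concentrations), dtype=int)),
    })
    write_table(frame, path, header_lines)


def read_spectrum(path) -> np.ndarray:
    frame = read_table(path, required=["wavelength_nm", "intensity"])
    return frame[["wavelength_nm", "intensity"]].to_numpy(float)


def read_peaklist(path, label: str = "") -> PeakList:
    frame = read_table(path, required=["residue", "dH_ppm", "dN_ppm"])
    shifts = {
        str(row.residue): (float(row.dH_ppm), float(row.dN_ppm))
        for row in frame.itertuples()
    }
    if len(shifts) != len(frame):
        raise FormatError(f"{path}: duplicate residue identifiers")
    return PeakList(shifts, label or str(Path(path).stem))


def read_melt(path, units: str = "mre") -> MeltCurve:
    frame = read_table(path, required=["temp_C", "signal"])
    return MeltCurve(frame["temp_C"].to_numpy(float),
                     frame["signal"].to_numpy(float), units=units)


def read_mz_list(path) -> np.ndarray:
    frame = read_table(path, required=["mz"])
    return frame["mz"].to_numpy(float)


def read_fasta(path) -> dict[str, str]:
    """FASTA records as {id: sequence} (uppercased)."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records
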