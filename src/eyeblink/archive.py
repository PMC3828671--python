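"""Trial-archive I/O: manifest table plus per-session trace matrices.

An archive holds one mouse's recordings: a ``header.yaml`` with acquisition
metadata, a ``manifest.tsv`` listing every trial, and one ``traces_<session>.tsv``
numeric matrix per session (one trial per row, raw samples in arbitrary
amplitude units).  The layout is plain text, diffable, and language-neutral;
traces are written at full float64 precision so an archive round-trips through
disk unchanged.

Times are stored in ms as floats; sample indices derive as
``floor(ms * rate / 1000)`` with 0-based indexing and half-open windows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MANIFEST_COLUMNS",
    "ArchiveError",
    "TrialRecord",
    "EmgArchive",
    "read_archive",
    "write_archive",
    "iter_trials",
    "write_table",
]

MANIFEST_COLUMNS = [
    "session_label",
    "trial_index",
    "trial_type",
    "cs_onset_ms",
    "us_onset_ms",
    "expected_us_onset_ms",
    "iti_s",
]

DEFAULT_HEADER = {
    "sampling_rate_hz": 10000.0,
    "amplitude_units": "a.u.",
    "bandpass_hz": [150.0, 1000.0],
}

#: full float64 precision so read(write(a)) == a exactly
_FLOAT_FMT = "%.17g"


class ArchiveError(ValueError):
    """Archive validation failure; the message names the offending trial."""


@dataclass
class TrialRecord:
    """One trial's raw EMG trace plus its stimulus timing and provenance."""

    mouse_id: str
    genotype: str
    session_label: str
    trial_index: int
    trial_type: str
    cs_onset_ms: float | None
    us_onset_ms: float | None
    expected_us_onset_ms: float | None
    iti_s: float
    sampling_rate_hz: float
    trace: np.ndarray

    @property
    def scoring_us_ms(self) -> float | None:
        if self.trial_type == "paired":
            return self.us_onset_ms
        return self.expected_us_onset_ms


@dataclass
class EmgArchive:
    """One mouse's trial archive.

    ``traces[label]`` is a ``(n_trials, n_samples)`` float array aligned
    row-for-row with the manifest entries of that session.
    """

    header: dict = field(default_factory=lambda: dict(DEFAULT_HEADER))
    manifest: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS)
    )
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def sampling_rate_hz(self) -> float:
        return float(self.header["sampling_rate_hz"])

    @property
    def mouse_id(self) -> str:
        return str(self.header.get("mouse_id", ""))

    @property
    def genotype(self) -> str:
        return str(self.header.get("genotype", ""))

    @property
    def session_labels(self) -> list[str]:
        # preserve manifest order of first appearance
        return list(dict.fromkeys(self.manifest["session_label"]))

    def session_manifest(self, label: str) -> pd.DataFrame:
        return self.manifest[self.manifest["session_label"] == label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmgArchive):
            return NotImplemented
        if self.header != other.header:
            return False
        if not self.manifest.reset_index(drop=True).equals(
            other.manifest.reset_index(drop=True)
        ):
            return False
        if set(self.traces) != set(other.traces):
            return False
        return all(
            np.array_equal(self.traces[k], other.traces[k]) for k in self.traces
        )


def validate_archive(archive: EmgArchive) -> None:
    """Check archive invariants, raising :class:`ArchiveError` with the
    session/trial coordinates of the first violation."""
    if archive.sampling_rate_hz <= 0:
        raise ArchiveError("sampling_rate_hz must be positive")
    man = archive.manifest
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ArchiveError(f"manifest missing columns {missing}")
    rate = archive.sampling_rate_hz
    for label in archive.session_labels:
        sub = man[man["session_label"] == label]
        if label not in archive.traces:
            raise ArchiveError(f"session {label!r}: no trace matrix")
        mat = archive.traces[label]
        if mat.ndim != 2 or mat.shape[0] != len(sub):
            n = 0 if mat.ndim != 2 else mat.shape[0]
            raise ArchiveError(
                f"session {label!r}: {len(sub)} manifest entries but "
                f"{n} trace rows"
            )
        if not np.isfinite(mat).all():
            bad = np.argwhere(~np.isfinite(mat))[0]
            idx = int(sub.iloc[int(bad[0])]["trial_index"])
            raise ArchiveError(
                f"session {label!r} trial {idx}: non-finite sample"
            )
        n_samples = mat.shape[1]
        for _, row in sub.iterrows():
            cs = row["cs_onset_ms"]
            eus = row["expected_us_onset_ms"]
            if pd.notna(cs) and pd.notna(eus):
                need = int(np.floor((float(eus) + 100.0) * rate / 1000.0))
                if n_samples < need:
                    raise ArchiveError(
                        f"session {label!r} trial {int(row['trial_index'])}: "
                        f"trace has {n_samples} samples, needs >= {need}"
                    )
    extra = set(archive.traces) - set(archive.session_labels)
    if extra:
        raise ArchiveError(f"trace matrices without manifest entries: {sorted(extra)}")


def write_archive(archive: EmgArchive, path: str | Path) -> Path:
    """Write an archive directory (header.yaml, manifest.tsv, traces_*.tsv).

    The byte layout is deterministic: fixed column order, fixed float
    formatting, sessions in manifest order.
    """
    validate_archive(archive)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "header.yaml").write_text(
        yaml.safe_dump(archive.header, sort_keys=True, default_flow_style=False)
    )
    man = archive.manifest[MANIFEST_COLUMNS]
    man.to_csv(
        path / "manifest.tsv", sep="\t", index=False, float_format=_FLOAT_FMT,
        na_rep="",
    )
    for label in archive.session_labels:
        np.savetxt(
            path / f"traces_{label}.tsv", archive.traces[label],
            fmt=_FLOAT_FMT, delimiter="\t",
        )
    return path


def read_archive(path: str | Path) -> EmgArchive:
    """Read and validate an archive directory written by :func:`write_archive`."""
    path = Path(path)
    header_path = path / "header.yaml"
    manifest_path = path / "manifest.tsv"
    if not header_path.exists():
        raise ArchiveError(f"{header_path} does not exist")
    if not manifest_path.exists():
        raise ArchiveError(f"{manifest_path} does not exist")
    header = yaml.safe_load(header_path.read_text()) or {}
    manifest = pd.read_csv(
        manifest_path, sep="\t",
        dtype={"session_label": str, "trial_type": str},
        float_precision="round_trip",
    )
    if len(manifest) == 0:
        manifest = pd.DataFrame(columns=MANIFEST_COLUMNS)
    for col in ("cs_onset_ms", "us_onset_ms", "expected_us_onset_ms", "iti_s"):
        if col in manifest.columns:
            manifest[col] = manifest[col].astype(float)
    traces: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(manifest.get("session_label", [])):
        tpath = path / f"traces_{label}.tsv"
        if not tpath.exists():
            raise ArchiveError(f"session {label!r}: missing trace file {tpath.name}")
        traces[label] = np.loadtxt(tpath, delimiter="\t", ndmin=2)
    archive = EmgArchive(header=header, manifest=manifest, traces=traces)
    validate_archive(archive)
    return archive


def iter_trials(archive: EmgArchive) -> Iterator[TrialRecord]:
    """Yield one :class:`TrialRecord` per manifest row, in manifest order."""
    mouse = archive.mouse_id
    geno = archive.genotype
    rate = archive.sampling_rate_hz
    for label in archive.session_labels:
        sub = archive.session_manifest(label)
        mat = archive.traces[label]
        for pos, (_, row) in enumerate(sub.iterrows()):
            yield TrialRecord(
                mouse_id=mouse,
                genotype=geno,
                session_label=label,
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                cs_onset_ms=_opt(row["cs_onset_ms"]),
                us_onset_ms=_opt(row["us_onset_ms"]),
                expected_us_onset_ms=_opt(row["expected_us_onset_ms"]),
                iti_s=float(row["iti_s"]),
                sampling_rate_hz=rate,
                trace=mat[pos],
            )


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy result table as TSV with stable formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")
    return path
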