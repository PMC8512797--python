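"""On-disk formats: channel-matrix CSV + JSON sidecar.

Recordings are plain CSV matrices (rows = samples, one column per valid
electrode, header ``r<row>c<col>`` in row-major grid order) with a JSON
sidecar alongside (same stem, ``.json``) that carries everything needed to
reconstruct the object unambiguously: sampling rate, grid dimensions,
missing-electrode list, channel-order convention, trial metadata and a
processing-provenance list each stage appends to. Force traces are
two-column CSVs ``time_s,force_n`` (or a single ``force_n`` column with the
rate in the sidecar). Floats are written with 17 significant digits, so
round trips are lossless to full float64 precision; simulated and imported
studies are indistinguishable on disk.

Grid convention (asserted in tests): 0-based indices, row 0 = top of the
grid as placed, columns run along the muscle-fiber direction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .grid import GridLayout
from .pipeline import TrialRecord, records_to_frame
from .recording import EMGRecording, ForceTrace
from .simulate import SyntheticStudy

__all__ = [
    "sidecar_path",
    "write_recording",
    "read_recording",
    "write_force",
    "read_force",
    "write_features",
    "read_features",
    "write_study",
    "iter_study_dir",
]

_FLOAT_FMT = "%.17g"
CHANNEL_ORDER_CONVENTION = "row-major r<row>c<col>, 0-based, row 0 = top"


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def _layout_to_json(layout: GridLayout) -> dict[str, Any]:
    return {
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "missing": sorted([list(p) for p in layout.missing]),
        "inter_electrode_distance_mm": layout.inter_electrode_distance_mm,
        "channel_order": CHANNEL_ORDER_CONVENTION,
    }


def _layout_from_json(obj: dict[str, Any], path: Path) -> GridLayout:
    try:
        return GridLayout(
            n_rows=int(obj["n_rows"]),
            n_cols=int(obj["n_cols"]),
            missing=frozenset(tuple(p) for p in obj["missing"]),
            inter_electrode_distance_mm=float(
                obj.get("inter_electrode_distance_mm", 8.0)
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid grid description in sidecar ({exc})") from exc


def _write_sidecar(path: Path, payload: dict[str, Any]) -> None:
    sidecar_path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n"
    )


def _read_sidecar(path: Path) -> dict[str, Any]:
    sc = sidecar_path(path)
    if not sc.exists():
        raise ParseError(f"{path}: sidecar {sc.name} not found")
    try:
        return json.loads(sc.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{sc}: invalid JSON ({exc})") from exc


def write_recording(recording: EMGRecording, path: Path | str) -> None:
    """Write a recording as channel-matrix CSV + sidecar JSON."""
    path = Path(path)
    header = ",".join(recording.layout.channel_names)
    np.savetxt(
        path, recording.samples, fmt=_FLOAT_FMT, delimiter=",",
        header=header, comments="",
    )
    _write_sidecar(
        path,
        {
            "format": "hdemg-recording",
            "sampling_rate": recording.sampling_rate,
            "grid": _layout_to_json(recording.layout),
            "meta": recording.meta,
        },
    )


def read_recording(path: Path | str) -> EMGRecording:
    """Read a channel-matrix CSV + sidecar back into an :class:`EMGRecording`.

    The CSV header is validated channel-for-channel against the sidecar's
    grid mask; mismatches, ragged rows and non-numeric cells raise
    :class:`ParseError` naming the offending location.
    """
    path = Path(path)
    sidecar = _read_sidecar(path)
    layout = _layout_from_json(sidecar.get("grid", {}), path)
    with open(path) as fh:
        header = fh.readline().strip()
    names = tuple(header.split(",")) if header else ()
    if names != layout.channel_names:
        expected = set(layout.channel_names)
        got = set(names)
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ParseError(
            f"{path}: header does not match the sidecar grid mask"
            + (f"; missing channels {missing}" if missing else "")
            + (f"; unexpected channels {extra}" if extra else "")
        )
    try:
        samples = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if samples.shape[1] != layout.n_valid:
        raise ParseError(
            f"{path}: {samples.shape[1]} data columns for {layout.n_valid} channels"
        )
    return EMGRecording(
        samples,
        float(sidecar["sampling_rate"]),
        layout,
        dict(sidecar.get("meta", {})),
    )


def write_force(force: ForceTrace, path: Path | str, meta: dict | None = None) -> None:
    """Write a force trace as a two-column ``time_s,force_n`` CSV + sidecar."""
    path = Path(path)
    data = np.column_stack([force.time, force.force])
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=",", header="time_s,force_n", comments="")
    _write_sidecar(
        path,
        {
            "format": "hdemg-force",
            "sampling_rate": force.sampling_rate,
            "meta": meta or {},
        },
    )


def read_force(path: Path | str) -> ForceTrace:
    """Read a force trace.

    Accepts the two-column ``time_s,force_n`` form (the time column must
    advance at a strictly positive constant rate) or a single ``force_n``
    column with the sampling rate taken from the sidecar.
    """
    path = Path(path)
    sidecar = _read_sidecar(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if header == ["time_s", "force_n"]:
        time, force = data[:, 0], data[:, 1]
        steps = np.diff(time)
        if time.size >= 2 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            bad = int(np.argmin(steps))
            raise ParseError(
                f"{path}: time column is not monotone at constant rate "
                f"(step {bad + 1} -> {bad + 2})"
            )
        rate = 1.0 / steps[0] if time.size >= 2 else float(sidecar["sampling_rate"])
        return ForceTrace(force, rate)
    if header == ["force_n"]:
        try:
            rate = float(sidecar["sampling_rate"])
        except KeyError:
            raise ParseError(
                f"{path}: single-column force file needs sampling_rate in sidecar"
            ) from None
        return ForceTrace(data[:, 0], rate)
    raise ParseError(f"{path}: unrecognized force header {header}")


def write_features(records: Iterable[TrialRecord], path: Path | str) -> None:
    """Write the tidy feature table (one row per trial record) as CSV."""
    records_to_frame(records).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc
    frame["error"] = frame.get("error", "").fillna("") if "error" in frame else ""
    if "qc_flags" in frame:
        frame["qc_flags"] = frame["qc_flags"].fillna("")
    return frame


def write_study(study: SyntheticStudy, out_dir: Path | str) -> None:
    """Write a generated study to a directory tree.

    One subdirectory per participant; per bundle an EMG CSV per side
    (``<design>_<muscle>_<side>.csv``), a shared force CSV
    (``<design>_<muscle>_force.csv``, referenced from each EMG sidecar), and
    per muscle/side the MVC trials (``mvc_<muscle>_<side>_t<k>.csv``).
    Everything is reproducible byte-for-byte from (design, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for bundle in study.bundles:
        pdir = out_dir / bundle.participant
        pdir.mkdir(exist_ok=True)
        force_name = f"{bundle.design}_{bundle.muscle}_force.csv"
        write_force(
            bundle.force,
            pdir / force_name,
            meta={
                "participant": bundle.participant,
                "design": bundle.design,
                "muscle": bundle.muscle,
            },
        )
        for side, recording in bundle.recordings.items():
            emg_path = pdir / f"{bundle.design}_{bundle.muscle}_{side}.csv"
            recording = recording.with_samples(
                recording.samples, force_file=force_name
            )
            write_recording(recording, emg_path)
    for (pid, muscle, side), trials in study.mvc_trials.items():
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for k, trial in enumerate(trials):
            write_recording(trial, pdir / f"mvc_{muscle}_{side}_t{k}.csv")


def iter_study_dir(
    in_dir: Path | str,
) -> list[tuple[EMGRecording, ForceTrace, list[EMGRecording]]]:
    """Collect processable trials from a study directory.

    Returns ``(push recording, force trace, MVC trials)`` triples, matching
    each push recording to its force file (named in its sidecar) and to the
    MVC trials of the same participant, muscle and side.
    """
    in_dir = Path(in_dir)
    pushes: list[EMGRecording] = []
    mvc: dict[tuple[str, str, str], list[EMGRecording]] = {}
    for csv in sorted(in_dir.rglob("*.csv")):
        if not sidecar_path(csv).exists():
            continue
        sidecar = _read_sidecar(csv)
        if sidecar.get("format") != "hdemg-recording":
            continue
        rec = read_recording(csv)
        rec.meta["_path"] = str(csv)
        if rec.meta.get("kind") == "mvc":
            key = (
                str(rec.meta.get("participant")),
                str(rec.meta.get("muscle")),
                str(rec.meta.get("side")),
            )
            mvc.setdefault(key, []).append(rec)
        else:
            pushes.append(rec)
    triples = []
    for rec in pushes:
        csv = Path(rec.meta.pop("_path"))
        force_file = rec.meta.get("force_file")
        if not force_file:
            raise ParseError(f"{csv}: push recording sidecar names no force_file")
        force = read_force(csv.parent / force_file)
        key = (
            str(rec.meta.get("participant")),
            str(rec.meta.get("muscle")),
            str(rec.meta.get("side")),
        )
        if key not in mvc:
            raise ParseError(
                f"{csv}: no MVC trials found for participant/muscle/side {key}"
            )
        triples.append((rec, force, mvc[key]))
    for rec in pushes:
        rec.meta.pop("_path", None)
    for trials in mvc.values():
        for rec in trials:
            rec.meta.pop("_path", None)
    return triples
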