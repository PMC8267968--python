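"""Readers and writers for the package's tabular and config dialects.

Traces travel as long-format CSV (trace_id, t_s, uV) with a separate
metadata table; OCT profiles and behavior tracks are plain CSV; box
geometry and filter/window settings are YAML.  Sequences use FASTA via
Biopython.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .behavior import BoxGeometry
from .edits import NucSequence
from .erg import ErgTrace, FilterSpec, PeakSearchWindows

__all__ = [
    "read_erg_traces",
    "read_oct_profiles",
    "read_track",
    "load_box_geometry",
    "load_erg_config",
    "read_fasta",
    "write_fasta",
]

_META_COLS = ("trace_id", "animal", "genotype", "age_weeks", "eye",
              "intensity_cds_m2", "mode")


def read_erg_traces(traces_csv: str | Path, meta_csv: str | Path) -> list[ErgTrace]:
    """Assemble ErgTrace objects from a long trace table plus metadata."""
    traces = pd.read_csv(traces_csv)
    meta = pd.read_csv(meta_csv).set_index("trace_id")
    missing = [c for c in _META_COLS if c != "trace_id" and c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table lacks columns: {missing}")
    out = []
    for tid, g in traces.groupby("trace_id"):
        if tid not in meta.index:
            raise ValueError(f"trace {tid!r} has no metadata row")
        m = meta.loc[tid]
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(dtype=float)
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"trace {tid!r} is not uniformly sampled")
        out.append(ErgTrace(
            samples=g["uV"].to_numpy(dtype=float),
            dt=float(dts[0]),
            stimulus_onset=float(m.get("stimulus_onset_s", 0.020)),
            intensity=float(m["intensity_cds_m2"]),
            mode=str(m["mode"]),
            flicker_hz=float(m["flicker_hz"]) if "flicker_hz" in m and pd.notna(m["flicker_hz"]) else None,
            animal_id=str(m["animal"]),
            genotype=str(m["genotype"]),
            age_weeks=float(m["age_weeks"]) if pd.notna(m["age_weeks"]) else None,
            eye=str(m["eye"]),
        ))
    return out


def write_erg_traces(traces: list[ErgTrace], traces_csv: str | Path, meta_csv: str | Path) -> None:
    """Inverse of :func:`read_erg_traces`; trace ids are assigned serially."""
    rows, meta = [], []
    for i, tr in enumerate(traces):
        tid = f"trace{i:04d}"
        for t, v in zip(tr.time(), tr.samples):
            rows.append((tid, t, v))
        meta.append({"trace_id": tid, "animal": tr.animal_id, "genotype": tr.genotype,
                     "age_weeks": tr.age_weeks, "eye": tr.eye,
                     "intensity_cds_m2": tr.intensity, "mode": tr.mode,
                     "flicker_hz": tr.flicker_hz, "stimulus_onset_s": tr.stimulus_onset})
    pd.DataFrame(rows, columns=["trace_id", "t_s", "uV"]).to_csv(traces_csv, index=False)
    pd.DataFrame(meta).to_csv(meta_csv, index=False)


_OCT_COLS = ("animal", "genotype", "age_weeks", "eye", "scan_offset",
             "position_mm", "layer", "thickness_um")


def read_oct_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _OCT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"OCT profile table lacks columns: {missing}")
    return df


def read_track(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for c in ("t_s", "x_cm", "y_cm"):
        if c not in df.columns:
            raise ValueError(f"track table lacks column {c!r}")
    df = df.sort_values("t_s")
    return (df["t_s"].to_numpy(float), df["x_cm"].to_numpy(float),
            df["y_cm"].to_numpy(float))


def load_box_geometry(path: str | Path) -> BoxGeometry:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "doorway_width" not in cfg:
        raise ValueError("geometry YAML must state doorway_width (cm); there is no default")
    return BoxGeometry(**cfg)


def load_erg_config(path: str | Path) -> dict:
    """ERG analysis settings: filter specs, windows, intensity grid."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {}
    out["a_filter"] = FilterSpec(**cfg.get("a_filter", {"order": 4, "cutoff": 235.0}))
    out["b_filter"] = FilterSpec(**cfg.get("b_filter", {"order": 4, "cutoff": 30.0}))
    win = cfg.get("windows", {})
    out["windows"] = PeakSearchWindows(
        a_window=tuple(win.get("a_window", (5.0, 60.0))),
        b_window=tuple(win.get("b_window", (20.0, 150.0))),
        min_prominence=float(win.get("min_prominence", 10.0)))
    out["intensities"] = tuple(cfg.get("intensities", (0.3, 30.0)))
    out["baseline_end_s"] = float(cfg.get("baseline_end_s", 0.020))
    return out


def read_fasta(path: str | Path, coordinate_frame: str = "raw") -> list[NucSequence]:
    return [NucSequence(rec.id, str(rec.seq), coordinate_frame)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: list[NucSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i:i + 70] + "\n")
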