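"""Text I/O for umbrella-window time series and pairwise-force tables.

Window series use the two-column whitespace ``pullx`` dialect (time in ns,
reaction coordinate in nm) with ``#``/``@`` comment headers, accompanied by
a tab-separated manifest (filename, center, spring_k).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .wham_pmf import UmbrellaWindowData

MANIFEST_NAME = "windows.tsv"


def write_pullx(path, times, xi, comment: str = "") -> None:
    """Write a two-column time/position series in the pullx dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# pull coordinate time series\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write('@    title "Pull COM"\n')
        fh.write('@    xaxis  label "Time (ns)"\n')
        fh.write('@    yaxis  label "Position (nm)"\n')
        for t, x in zip(times, xi):
            fh.write(f"{t:.6f}\t{x:.8f}\n")


def read_pullx(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a pullx-dialect file, skipping ``#`` and ``@`` header lines."""
    times, xi = [], []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s[0] in "#@":
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            times.append(float(parts[0]))
            xi.append(float(parts[1]))
    return np.array(times), np.array(xi)


def write_window_files(windows, outdir, timestep: float = 1.0) -> Path:
    """Write one pullx file per umbrella window plus the manifest TSV.

    Returns the manifest path.  ``timestep`` spaces the synthetic time
    column (ns) when the windows carry no native times.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.xvg"
        times = timestep * np.arange(1, w.n_samples + 1)
        write_pullx(outdir / name, times, w.samples,
                    comment=f"center={w.center:g} nm k={w.spring_k:g} kJ/mol/nm^2")
        rows.append({"filename": name, "center": w.center, "spring_k": w.spring_k})
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_window_files(manifest) -> list[UmbrellaWindowData]:
    """Load umbrella windows listed in a manifest TSV."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    required = {"filename", "center", "spring_k"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    windows = []
    for row in table.itertuples():
        _, xi = read_pullx(manifest.parent / row.filename)
        windows.append(UmbrellaWindowData(center=float(row.center),
                                          spring_k=float(row.spring_k),
                                          samples=xi))
    return windows


def write_pairforce_tsv(records: pd.DataFrame, path) -> None:
    """Write a pairwise-force table (frame, atom_i, atom_j, fx, fy, fz)."""
    cols = ["frame", "atom_i", "atom_j", "fx", "fy", "fz"]
    records[cols].to_csv(path, sep="\t", index=False)


def read_pairforce_tsv(path) -> pd.DataFrame:
    """Read a pairwise-force table; also accepts a scalar signed-force
    superset with a single ``force`` column (mapped onto fx, fy=fz=0)."""
    table = pd.read_csv(path, sep="\t")
    if "force" in table.columns and "fx" not in table.columns:
        table = table.rename(columns={"force": "fx"})
        table["fy"] = 0.0
        table["fz"] = 0.0
    missing = {"frame", "atom_i", "atom_j", "fx", "fy", "fz"} - set(table.columns)
    if missing:
        raise ValueError(f"pairwise-force table missing columns {sorted(missing)}")
    return table
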