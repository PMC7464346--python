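"""Plain-text readers and writers for the pipeline's formats.

Formats
-------
Spectrum TSV      two columns ``mz<TAB>intensity``, one file per replicate,
                  named ``<sample_id>_r<1|2|3>.tsv``.
Peak-table CSV    ``sample_id,replicate,mz_bin,area``; an empty replicate
                  field marks areas that are already triplicate-averaged.
Metadata CSV      ``sample_id,group,sex,age``.
Matrix CSV        rows = samples (index ``sample_id``), columns = bin labels.
Ground-truth CSV  ``mz_bin,direction``.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml

from .preprocess import PeakMatrix, RawSpectrum, average_triplicates
from .simulate import GroundTruth, SimulationConfig

__all__ = [
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_cohort",
    "read_spectra_dir",
    "read_meta_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "read_peak_table_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "load_sim_config",
]

_SPECTRUM_RE = re.compile(r"^(?P<sid>.+)_r(?P<rep>\d+)\.tsv$")


def write_spectrum_tsv(spectrum: RawSpectrum, directory: Path) -> Path:
    path = Path(directory) / f"{spectrum.sample_id}_r{spectrum.replicate_index}.tsv"
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_spectrum_tsv(path: Path) -> RawSpectrum:
    m = _SPECTRUM_RE.match(Path(path).name)
    if not m:
        raise ValueError(f"spectrum filename must match <sample_id>_r<k>.tsv: {path}")
    df = pd.read_csv(path, sep="\t")
    return RawSpectrum(
        m.group("sid"), int(m.group("rep")), df["mz"].to_numpy(), df["intensity"].to_numpy()
    )


def read_spectra_dir(directory: Path) -> dict[str, list[RawSpectrum]]:
    """All ``*_r<k>.tsv`` spectra in a directory, grouped by sample id and
    ordered by replicate index."""
    out: dict[str, list[RawSpectrum]] = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        sp = read_spectrum_tsv(path)
        out.setdefault(sp.sample_id, []).append(sp)
    for reps in out.values():
        reps.sort(key=lambda s: s.replicate_index)
    return out


def write_cohort(spectra: dict[str, list[RawSpectrum]], meta: pd.DataFrame, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for reps in spectra.values():
        for sp in reps:
            write_spectrum_tsv(sp, directory)
    meta.to_csv(directory / "meta.csv")


def read_meta_csv(path: Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata CSV must carry a sample_id column")
    return meta.set_index("sample_id")


def write_matrix_csv(matrix: PeakMatrix, path: Path) -> None:
    matrix.areas.to_csv(path)


def read_matrix_csv(path: Path, meta: pd.DataFrame | None = None) -> PeakMatrix | pd.DataFrame:
    """Read a samples x bins CSV; with ``meta`` supplied a full PeakMatrix
    is returned, otherwise just the areas table."""
    areas = pd.read_csv(path, index_col=0)
    areas.columns = areas.columns.astype(float)
    if meta is None:
        return areas
    missing = [s for s in areas.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return PeakMatrix(areas, meta.loc[areas.index])


def read_peak_table_csv(path: Path, meta: pd.DataFrame) -> PeakMatrix:
    """Build a PeakMatrix from a pre-centroided long-format peak table,
    averaging replicates per sample (blank replicate = already averaged)."""
    tab = pd.read_csv(path)
    required = {"sample_id", "mz_bin", "area"}
    if not required <= set(tab.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    rows = {}
    for sid, sub in tab.groupby("sample_id"):
        if "replicate" in sub.columns and sub["replicate"].notna().any():
            maps = [
                dict(zip(r["mz_bin"], r["area"]))
                for _, r in sub.groupby("replicate")
            ]
            rows[sid] = average_triplicates(maps)
        else:
            rows[sid] = dict(zip(sub["mz_bin"], sub["area"]))
    areas = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    areas = areas.reindex(sorted(areas.columns), axis=1)
    areas.index.name = "sample_id"
    return PeakMatrix(areas, meta.loc[areas.index])


def write_ground_truth_csv(truth: GroundTruth, path: Path) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_ground_truth_csv(path: Path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(df["mz_bin"].to_numpy(), list(df["direction"]))


def load_sim_config(path: Path, **overrides) -> SimulationConfig:
    """Simulation config from a YAML mapping of SimulationConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationConfig(**data)
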