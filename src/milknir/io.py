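"""Reading, writing and aligning spectral blocks and composition tables.

The canonical on-disk format for spectra is a wide CSV: first column
``sample_id``, remaining column headers the wavelengths in nm.  A minimal
JCAMP-DX (XYPOINTS) import/export is provided for per-spectrum exchange.
Composition tables are plain CSVs with one row per sample.

Every downstream stage consumes only row-aligned data; :func:`align_blocks`
is the single gate through which multi-block analyses pass.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ParseError

logger = logging.getLogger("milknir")

COMPOSITION_COLUMNS = [
    "sample_id",
    "fat_true", "protein_true", "carbohydrate_true",
    "fat", "protein", "carbohydrate",
    "lactose", "eu_fat_class",
]


@dataclass
class SpectralBlock:
    """One instrument's replicate-averaged reflectance matrix.

    Attributes
    ----------
    instrument : str
        Identifier of the instrument that produced the block.
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelength grid in nm.
    reflectance : ndarray, shape (n, p)
        Reflectance, one row per sample, aligned with ``sample_ids``.
    sample_ids : list of str
        Unique sample identifiers, in row order.
    """

    instrument: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise ConfigurationError("wavelengths must be a 1-D vector")
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ConfigurationError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ConfigurationError("reflectance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectralBlock":
        """Copy of the block with a new reflectance matrix on the same grid."""
        return SpectralBlock(self.instrument, self.wavelengths.copy(),
                             np.asarray(reflectance, dtype=float),
                             list(self.sample_ids))

    def subset(self, sample_ids: Sequence[str]) -> "SpectralBlock":
        """Row subset in the given id order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SpectralBlock(self.instrument, self.wavelengths.copy(),
                             self.reflectance[rows], list(sample_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance,
                          columns=[f"{w:.12g}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def write_spectra(block: SpectralBlock, path: str | Path, format: str = "csv") -> None:
    """Write a block as wide CSV, or as one JCAMP-DX file per sample.

    For ``format="jcamp"`` the path is a directory that receives
    ``<sample_id>.jdx`` files.
    """
    path = Path(path)
    if format == "csv":
        block.to_frame().to_csv(path, index=False)
    elif format == "jcamp":
        path.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(block.sample_ids):
            _write_jcamp_spectrum(path / f"{sid}.jdx", sid, block.instrument,
                                  block.wavelengths, block.reflectance[i])
    else:
        raise ConfigurationError(f"unknown spectra format {format!r}")
    logger.info("wrote block %s (%d x %d) to %s [%s]", block.instrument,
                block.n_samples, block.n_wavelengths, path, format)


def read_spectra(path: str | Path, format: str = "csv",
                 instrument: str | None = None) -> SpectralBlock:
    """Read a spectral block from wide CSV or a directory of JCAMP-DX files.

    Wavelength columns are sorted to ascending order; duplicate sample ids or
    wavelengths, ragged rows, missing or non-numeric cells raise
    :class:`ParseError` naming the offending row/column.
    """
    path = Path(path)
    if format == "csv":
        return _read_spectra_csv(path, instrument)
    if format == "jcamp":
        return _read_spectra_jcamp(path, instrument)
    raise ConfigurationError(f"unknown spectra format {format!r}")


def _read_spectra_csv(path: Path, instrument: str | None) -> SpectralBlock:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].astype(str).tolist()
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate sample_id {dupes[0]!r}")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if np.unique(wavelengths).size != wavelengths.size:
        raise ParseError(f"{path}: duplicate wavelengths in header")
    values = np.empty((len(sample_ids), wavelengths.size))
    for j, col in enumerate(df.columns[1:]):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: missing or non-numeric cell at row {bad[0]} "
                f"(sample {sample_ids[bad[0]]!r}), column {col!r}")
        values[:, j] = converted.to_numpy()
    order = np.argsort(wavelengths)
    return SpectralBlock(instrument or path.stem, wavelengths[order],
                         values[:, order], sample_ids)


def _write_jcamp_spectrum(path: Path, title: str, origin: str,
                          wavelengths: np.ndarray, y: np.ndarray) -> None:
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NEAR INFRARED SPECTRUM",
        f"##ORIGIN={origin}",
        "##XUNITS=NANOMETERS",
        "##YUNITS=REFLECTANCE",
        f"##NPOINTS={wavelengths.size}",
        f"##FIRSTX={wavelengths[0]:.6g}",
        f"##LASTX={wavelengths[-1]:.6g}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{x:.6f}, {v:.10f}" for x, v in zip(wavelengths, y)]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp_spectrum(path: Path) -> tuple[str, np.ndarray, np.ndarray]:
    title = path.stem
    xs: list[float] = []
    ys: list[float] = []
    in_points = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "TITLE":
                title = value.strip()
            in_points = key == "XYPOINTS"
            if key == "END":
                break
            continue
        if in_points:
            try:
                x_str, y_str = line.split(",")
                xs.append(float(x_str))
                ys.append(float(y_str))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad XY pair {line!r}") from exc
    if not xs:
        raise ParseError(f"{path}: no XYPOINTS data found")
    return title, np.array(xs), np.array(ys)


def _read_spectra_jcamp(path: Path, instrument: str | None) -> SpectralBlock:
    files = sorted(path.glob("*.jdx")) if path.is_dir() else [path]
    if not files:
        raise ParseError(f"{path}: no .jdx files found")
    ids, rows = [], []
    grid: np.ndarray | None = None
    for f in files:
        title, x, y = _read_jcamp_spectrum(f)
        order = np.argsort(x)
        x, y = x[order], y[order]
        if grid is None:
            grid = x
        elif x.size != grid.size or not np.allclose(x, grid):
            raise ParseError(f"{f}: wavelength grid differs from {files[0]}")
        ids.append(title)
        rows.append(y)
    return SpectralBlock(instrument or path.name, grid, np.vstack(rows), ids)


def write_composition(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_composition(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "fat", "protein", "carbohydrate")
               if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def align_blocks(block_a: SpectralBlock, block_b: SpectralBlock,
                 composition: pd.DataFrame,
                 ) -> tuple[SpectralBlock, SpectralBlock, pd.DataFrame]:
    """Inner-join two blocks and the composition table on sample_id.

    Row order follows ``block_a`` restricted to the common ids.  Samples
    present in only some inputs are dropped with a logged warning.  An empty
    intersection is an error.
    """
    ids_a, ids_b = set(block_a.sample_ids), set(block_b.sample_ids)
    ids_c = set(composition["sample_id"].astype(str))
    common = ids_a & ids_b & ids_c
    if not common:
        raise ConfigurationError("no common sample_ids across blocks and composition")
    dropped = (ids_a | ids_b | ids_c) - common
    if dropped:
        logger.warning("align_blocks dropped %d unmatched sample(s): %s",
                       len(dropped), sorted(dropped))
    order = [s for s in block_a.sample_ids if s in common]
    comp = (composition.assign(sample_id=composition["sample_id"].astype(str))
            .set_index("sample_id").loc[order].reset_index())
    return block_a.subset(order), block_b.subset(order), comp


@dataclass
class AnalysisConfig:
    """Plumbing configuration for a full pipeline run (YAML-backed)."""

    recipes: dict = field(default_factory=dict)       # block name -> recipe spec
    cross_validation: dict = field(default_factory=lambda: {
        "scheme": "venetian", "n_splits": 22, "thickness": 5})
    variable_selection: dict = field(default_factory=lambda: {"method": "ipls"})
    lv_rule: dict = field(default_factory=lambda: {"epsilon": 0.02, "max_lv": 8})
    fusion_mode: str = "low"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fusion_mode not in ("low", "mid"):
            raise ConfigurationError(f"unknown fusion mode {self.fusion_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object, for run logging."""
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(text.encode()).hexdigest()[:10]


def log_stage(stage: str, config, n_rows: int, n_cols: int) -> None:
    """Log a pipeline stage with its configuration hash and data shape."""
    logger.info("stage=%s config=%s rows=%d cols=%d",
                stage, config_hash(config), n_rows, n_cols)
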