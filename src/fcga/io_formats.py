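"""Readers and writers for dense time series, parcellations and gradient maps.

The canonical on-disk formats are plain text (TSV with ``#`` header comments)
plus a raw ``.npy`` matrix with a JSON sidecar, so the whole package is usable
and testable without any neuroimaging data.  CIFTI-2 / GIFTI adapters sit
behind the same reader functions and are dispatched on the file suffix.

Internally vertices are always 0-based and matrices are oriented
vertices-by-timepoints; any external convention is converted here, at the
boundary, and nowhere else.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "TimeSeriesMatrix",
    "ParcellationMap",
    "GradientSet",
    "read_timeseries",
    "write_timeseries",
    "read_parcellation",
    "write_parcellation",
    "read_gradients",
    "write_gradients",
]


class FormatError(ValueError):
    """A file's content does not match the expected format."""


# orientation hints accepted by read_timeseries / write_timeseries
_HINT_VXT = "vertices-by-timepoints"
_HINT_TXV = "timepoints-by-vertices"


@dataclass
class TimeSeriesMatrix:
    """Dense functional signal, one row per vertex, one column per timepoint.

    Parameters
    ----------
    values
        ``(n_vertices, n_timepoints)`` array of signal values.
    vertex_ids
        Unique integer id per vertex; defaults to ``0..n-1``.
    space_tag
        Free-text label of the spatial reference (e.g. ``"fsLR32k"``,
        ``"toy-grid"``).
    allow_constant_rows
        Constant (zero-variance) rows are rejected unless this flag is set,
        because they make Pearson correlation undefined downstream.
    """

    values: np.ndarray
    vertex_ids: np.ndarray | None = None
    space_tag: str = "unknown"
    allow_constant_rows: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("time series must be a 2-D matrix")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 vertices, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(n)
        else:
            self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)
            if self.vertex_ids.shape != (n,):
                raise ValueError("vertex_ids length must match vertex count")
            if len(np.unique(self.vertex_ids)) != n:
                raise ValueError("vertex_ids must be unique")
        if not self.allow_constant_rows:
            if np.any(self.values.std(axis=1) == 0.0):
                raise ValueError(
                    "constant (zero-variance) rows present; pass "
                    "allow_constant_rows=True to accept them"
                )

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ParcellationMap:
    """Integer label per vertex; 0 means unassigned, 1..P are parcel ids."""

    labels: np.ndarray
    parcel_names: list[str] | None = None
    space_tag: str = "unknown"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            as_float = np.asarray(labels, dtype=float)
            if not np.all(as_float == np.round(as_float)):
                raise FormatError("parcellation labels must be integers")
            labels = as_float.astype(int)
        if labels.ndim != 1:
            raise FormatError("parcellation labels must be a 1-D vector")
        if labels.min(initial=0) < 0:
            raise ValueError("negative parcel labels are not allowed")
        p = int(labels.max(initial=0))
        present = np.unique(labels[labels > 0])
        if p > 0 and len(present) != p:
            missing = sorted(set(range(1, p + 1)) - set(present.tolist()))
            raise ValueError(f"parcel ids missing from map: {missing}")
        if self.parcel_names is not None and len(self.parcel_names) != p:
            raise ValueError("parcel_names length must equal number of parcels")
        self.labels = labels

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    def parcel_members(self) -> list[np.ndarray]:
        """Vertex indices of each parcel, in ascending parcel-id order."""
        return [np.flatnonzero(self.labels == p) for p in range(1, self.n_parcels + 1)]


@dataclass
class GradientSet:
    """Vertex-level gradient coefficients with per-component variance shares.

    ``coefficients`` is ``(n_vertices, g)``; column ``c`` is the spatial map of
    gradient ``c+1`` (unitless embedding coordinates).  ``provenance`` records
    how the set was produced (landmark method, k, threshold fraction, seed).
    """

    coefficients: np.ndarray
    explained_variance_ratio: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )
        if self.coefficients.ndim != 2:
            raise FormatError("gradient coefficients must be 2-D")
        g = self.coefficients.shape[1]
        if g < 1:
            raise ValueError("need at least one gradient")
        if self.explained_variance_ratio.shape != (g,):
            raise ValueError("explained_variance_ratio length must equal g")

    @property
    def n_vertices(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.coefficients.shape[1]

    def validate_pca_contract(self, atol: float = 1e-8) -> None:
        """Check the invariants PCA output must satisfy.

        Variance ratios non-increasing and in [0, 1]; coefficient columns
        mutually orthogonal.  Aligned (rotated) gradient sets need not satisfy
        the ordering, hence this is a method rather than a construction check.
        """
        evr = self.explained_variance_ratio
        if np.any(evr < -atol) or np.any(evr > 1 + atol):
            raise ValueError("explained variance ratios outside [0, 1]")
        if np.any(np.diff(evr) > atol):
            raise ValueError("explained variance ratios must be non-increasing")
        gram = self.coefficients.T @ self.coefficients
        off = gram - np.diag(np.diag(gram))
        scale = max(np.abs(np.diag(gram)).max(), 1.0)
        if np.abs(off).max() > atol * scale:
            raise ValueError("gradient coefficient columns are not orthogonal")


# ---------------------------------------------------------------------------
# time series


def _load_plain_matrix(path: Path) -> np.ndarray:
    """Load a delimited text matrix, tolerating '#' comments and , ; or tab."""
    text_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            text_rows.append(line)
    if not text_rows:
        raise FormatError(f"{path}: no data rows")
    first = text_rows[0]
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    tokens = first.split(delim)
    if tokens and tokens[0].startswith("gradient_"):
        raise FormatError(
            f"{path}: this is a gradient file; use read_gradients instead"
        )
    try:
        rows = [[float(tok) for tok in line.split(delim)] for line in text_rows]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.asarray(rows, dtype=float)


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_timeseries(
    path: str | Path,
    format_hint: str | None = None,
    *,
    allow_constant_rows: bool = False,
) -> TimeSeriesMatrix:
    """Read a dense time-series matrix as vertices-by-timepoints.

    ``format_hint`` may be ``"vertices-by-timepoints"`` (the default
    orientation for plain matrices) or ``"timepoints-by-vertices"`` (the
    matrix on disk is transposed on load).  A square plain matrix is
    ambiguous and requires an explicit hint; the reader never silently
    transposes.  CIFTI-2 ``.dtseries.nii`` and GIFTI ``.func.gii`` files carry
    their own orientation and ignore the hint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()

    if name.endswith(".dtseries.nii"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())  # timepoints x grayordinates
        return TimeSeriesMatrix(
            data.T, space_tag="cifti", allow_constant_rows=allow_constant_rows
        )
    if name.endswith(".func.gii") or name.endswith(".gii"):
        import nibabel as nib

        img = nib.load(str(path))
        # each data array is one map over vertices -> columns are timepoints
        data = np.column_stack([d.data for d in img.darrays])
        return TimeSeriesMatrix(
            data, space_tag="gifti", allow_constant_rows=allow_constant_rows
        )

    if name.endswith(".npy"):
        values = np.load(path)
        meta = _read_sidecar(path)
    else:
        values = _load_plain_matrix(path)
        meta = {}
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D matrix")

    hint = format_hint or meta.get("orientation")
    if values.shape[0] == values.shape[1] and hint is None:
        raise FormatError(
            f"{path}: square matrix is orientation-ambiguous; pass "
            f"format_hint='{_HINT_VXT}' or '{_HINT_TXV}'"
        )
    if hint == _HINT_TXV:
        values = values.T
    elif hint not in (None, _HINT_VXT):
        raise ValueError(f"unknown format hint {hint!r}")

    if values.shape[1] < 3:
        raise ValueError(
            f"{path}: {values.shape[1]} timepoints after orientation; need >= 3"
        )
    vertex_ids = meta.get("vertex_ids")
    return TimeSeriesMatrix(
        values,
        vertex_ids=None if vertex_ids is None else np.asarray(vertex_ids),
        space_tag=meta.get("space_tag", "unknown"),
        allow_constant_rows=allow_constant_rows,
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    """Write a time series as TSV (default) or .npy with a JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, ts.values)
        meta = {
            "orientation": _HINT_VXT,
            "space_tag": ts.space_tag,
            "vertex_ids": np.asarray(ts.vertex_ids).tolist(),
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh)
        return
    with open(path, "w") as fh:
        fh.write(f"# space_tag: {ts.space_tag}\n")
        fh.write(f"# orientation: {_HINT_VXT}\n")
        np.savetxt(fh, ts.values, delimiter="\t", fmt="%.17g")


# ---------------------------------------------------------------------------
# parcellations


def read_parcellation(path: str | Path) -> ParcellationMap:
    """Read an integer label vector (TSV canonical; GIFTI/CIFTI adapters)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith(".dlabel.nii"):
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.get_fdata()).ravel()
        return ParcellationMap(labels, space_tag="cifti")
    if name.endswith(".label.gii") or name.endswith(".gii"):
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data).ravel()
        return ParcellationMap(labels, space_tag="gifti")

    values = _load_plain_matrix(path)
    labels = values.ravel() if 1 in values.shape or values.ndim == 1 else None
    if labels is None:
        raise FormatError(f"{path}: parcellation must be a single label column")
    return ParcellationMap(labels)


def write_parcellation(p: ParcellationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# space_tag: {p.space_tag}\n")
        np.savetxt(fh, p.labels.reshape(-1, 1), fmt="%d")


# ---------------------------------------------------------------------------
# gradients


def write_gradients(g: GradientSet, path: str | Path, format_hint: str | None = None) -> None:
    """Write gradients as TSV with a ``gradient_1..gradient_g`` header.

    Floats are written with 17 significant digits, so a plain-format
    round-trip reproduces the coefficients bit-exactly.
    """
    path = Path(path)
    header = "\t".join(f"gradient_{i + 1}" for i in range(g.n_gradients))
    evr = json.dumps(np.asarray(g.explained_variance_ratio).tolist())
    prov = json.dumps(g.provenance, default=str)
    try:
        with open(path, "w") as fh:
            fh.write(f"# explained_variance_ratio: {evr}\n")
            fh.write(f"# provenance: {prov}\n")
            fh.write(header + "\n")
            np.savetxt(fh, g.coefficients, delimiter="\t", fmt="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write gradients to {path}: {exc}") from exc


def read_gradients(path: str | Path) -> GradientSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    evr = None
    provenance: dict = {}
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# explained_variance_ratio:"):
                evr = json.loads(line.split(":", 1)[1])
            elif line.startswith("# provenance:"):
                provenance = json.loads(line.split(":", 1)[1])
            elif line.startswith("#") or not line.strip():
                continue
            elif header is None:
                header = line.split("\t")
                if not header[0].startswith("gradient_"):
                    raise FormatError(f"{path}: missing gradient_* header row")
            else:
                rows.append([float(tok) for tok in line.split("\t")])
    if header is None or not rows:
        raise FormatError(f"{path}: not a gradient file")
    coefficients = np.asarray(rows, dtype=float)
    if evr is None:
        warnings.warn(f"{path}: no explained_variance_ratio record; filling NaN")
        evr = [float("nan")] * coefficients.shape[1]
    return GradientSet(coefficients, np.asarray(evr), provenance)
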