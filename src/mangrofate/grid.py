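"""Structured Cartesian model domain.

The domain is an ``ny x nx`` grid of square or rectangular cells.  Scalar
fields (bed depth, land type, Manning roughness, surface elevation, tracer
concentration) live at cell centers; indices are 0-based with ``x``
increasing eastward (second axis) and ``y`` northward (first axis).

Bed depth ``d`` is measured positive *down* from the reference datum, so the
total water depth is ``h = d + zeta`` and land above the datum carries a
negative ``d``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr


class LandType(enum.Enum):
    """Closed enumeration of land-cover classes controlling roughness and uptake."""

    RIVERBED = "riverbed"
    MANGROVE_FLOODPLAIN = "mangrove_floodplain"
    CONSTRUCTED_WETLAND = "constructed_wetland"
    BARE = "bare"


#: Integer codes used when a land-type field is stored as an array.
LANDTYPE_CODES = {lt: i for i, lt in enumerate(LandType)}
LANDTYPE_FROM_CODE = {i: lt for lt, i in LANDTYPE_CODES.items()}

#: Default Manning roughness (s m^-1/3) per land class.  Riverbed and
#: mangrove floodplain follow the calibrated estuary values; constructed
#: wetlands are treated as densely vegetated (mangrove-like) and bare flats
#: as smooth ground.
DEFAULT_MANNING = {
    LandType.RIVERBED: 0.005,
    LandType.MANGROVE_FLOODPLAIN: 0.15,
    LandType.CONSTRUCTED_WETLAND: 0.15,
    LandType.BARE: 0.025,
}


def manning_for_landtype(landtype, table=None) -> float:
    """Return the Manning roughness for a land class.

    Parameters
    ----------
    landtype : LandType or str
        One of the four known land classes (instance or its string label).
    table : dict, optional
        Overrides the default per-class roughness values.

    Raises
    ------
    ValueError
        If the label is not one of the known classes.
    """
    if isinstance(landtype, str):
        try:
            landtype = LandType(landtype)
        except ValueError:
            raise ValueError(f"unknown land type label: {landtype!r}") from None
    if not isinstance(landtype, LandType):
        raise ValueError(f"unknown land type label: {landtype!r}")
    table = DEFAULT_MANNING if table is None else {**DEFAULT_MANNING, **table}
    return float(table[landtype])


@dataclass(frozen=True)
class BoundarySegment:
    """Open-boundary cells of one kind.

    ``kind`` is ``"tide"`` (Dirichlet water level) or ``"inflow"``
    (prescribed bulk discharge).  ``cells`` is a sequence of ``(j, i)``
    index pairs that must lie on the domain edge.
    """

    kind: str
    cells: tuple

    def __post_init__(self):
        if self.kind not in ("tide", "inflow"):
            raise ValueError(f"unknown boundary kind: {self.kind!r}")
        object.__setattr__(self, "cells", tuple((int(j), int(i)) for j, i in self.cells))


@dataclass
class Grid:
    """Static model domain: geometry, bathymetry, land cover and roughness."""

    dx: float
    dy: float
    bed_depth: np.ndarray          # (ny, nx), m, positive down
    landtype: np.ndarray           # (ny, nx), integer codes into LANDTYPE_CODES
    manning: np.ndarray            # (ny, nx), s m^-1/3
    active: np.ndarray             # (ny, nx), bool
    open_boundary: list = field(default_factory=list)

    def __post_init__(self):
        self.bed_depth = np.asarray(self.bed_depth, dtype=float)
        self.landtype = np.asarray(self.landtype, dtype=np.int8)
        self.manning = np.asarray(self.manning, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def ny(self) -> int:
        return self.bed_depth.shape[0]

    @property
    def nx(self) -> int:
        return self.bed_depth.shape[1]

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def validate(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")
        shape = self.bed_depth.shape
        if len(shape) != 2 or shape[0] < 1 or shape[1] < 1:
            raise ValueError("bed_depth must be a 2-D field with nx, ny >= 1")
        for name in ("landtype", "manning", "active"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"field {name!r} has shape {getattr(self, name).shape}, "
                                 f"expected {shape}")
        codes = np.unique(self.landtype)
        if not np.all(np.isin(codes, list(LANDTYPE_FROM_CODE))):
            bad = [c for c in codes if c not in LANDTYPE_FROM_CODE]
            raise ValueError(f"unknown land type codes: {bad}")
        if np.any(self.manning[self.active] <= 0):
            raise ValueError("Manning roughness must be positive on active cells")
        ny, nx = shape
        for seg in self.open_boundary:
            for j, i in seg.cells:
                if not (0 <= j < ny and 0 <= i < nx):
                    raise ValueError(f"open-boundary cell {(j, i)} outside grid")
                if not self.active[j, i]:
                    raise ValueError(f"open-boundary cell {(j, i)} is inactive")
                if not (j in (0, ny - 1) or i in (0, nx - 1)):
                    raise ValueError(f"open-boundary cell {(j, i)} not on the domain edge")

    def boundary_cells(self, kind: str | None = None):
        """Flat list of (j, i) open-boundary cells, optionally of one kind."""
        out = []
        for seg in self.open_boundary:
            if kind is None or seg.kind == kind:
                out.extend(seg.cells)
        return out

    def boundary_mask(self, kind: str | None = None) -> np.ndarray:
        mask = np.zeros(self.bed_depth.shape, dtype=bool)
        for j, i in self.boundary_cells(kind):
            mask[j, i] = True
        return mask

    def landtype_mask(self, lt: LandType) -> np.ndarray:
        return self.landtype == LANDTYPE_CODES[lt]

    # -- serialization ---------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "bed_depth": (("y", "x"), self.bed_depth),
                "landtype": (("y", "x"), self.landtype.astype(np.int32)),
                "manning": (("y", "x"), self.manning),
                "active": (("y", "x"), self.active.astype(np.int8)),
            },
            coords={
                "x": (np.arange(self.nx) + 0.5) * self.dx,
                "y": (np.arange(self.ny) + 0.5) * self.dy,
            },
        )
        ds.attrs["dx"] = self.dx
        ds.attrs["dy"] = self.dy
        ds.attrs["landtype_codes"] = json.dumps(
            {lt.value: code for lt, code in LANDTYPE_CODES.items()})
        ds.attrs["open_boundary"] = json.dumps(
            [{"kind": seg.kind, "cells": list(map(list, seg.cells))}
             for seg in self.open_boundary])
        return ds

    def save(self, path) -> None:
        """Write the grid to a self-describing NetCDF file."""
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "Grid":
        segs = [BoundarySegment(d["kind"], [tuple(c) for c in d["cells"]])
                for d in json.loads(ds.attrs.get("open_boundary", "[]"))]
        return cls(
            dx=float(ds.attrs["dx"]),
            dy=float(ds.attrs["dy"]),
            bed_depth=ds["bed_depth"].values,
            landtype=ds["landtype"].values,
            manning=ds["manning"].values,
            active=ds["active"].values.astype(bool),
            open_boundary=segs,
        )

    @classmethod
    def load(cls, path) -> "Grid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    def save_csv(self, directory) -> None:
        """ASCII fallback: one CSV matrix per field plus a JSON header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "bed_depth.csv", self.bed_depth, delimiter=",")
        np.savetxt(directory / "landtype.csv", self.landtype, fmt="%d", delimiter=",")
        np.savetxt(directory / "manning.csv", self.manning, delimiter=",")
        np.savetxt(directory / "active.csv", self.active.astype(int), fmt="%d",
                   delimiter=",")
        meta = {
            "dx": self.dx, "dy": self.dy,
            "landtype_codes": {lt.value: c for lt, c in LANDTYPE_CODES.items()},
            "open_boundary": [{"kind": s.kind, "cells": list(map(list, s.cells))}
                              for s in self.open_boundary],
        }
        (directory / "grid.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_csv(cls, directory) -> "Grid":
        directory = Path(directory)
        meta = json.loads((directory / "grid.json").read_text())
        segs = [BoundarySegment(d["kind"], [tuple(c) for c in d["cells"]])
                for d in meta["open_boundary"]]
        return cls(
            dx=meta["dx"], dy=meta["dy"],
            bed_depth=np.loadtxt(directory / "bed_depth.csv", delimiter=",", ndmin=2),
            landtype=np.loadtxt(directory / "landtype.csv", delimiter=",", ndmin=2),
            manning=np.loadtxt(directory / "manning.csv", delimiter=",", ndmin=2),
            active=np.loadtxt(directory / "active.csv", delimiter=",", ndmin=2).astype(bool),
            open_boundary=segs,
        )


def _landtype_codes(landtype_field) -> np.ndarray:
    arr = np.asarray(landtype_field)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int8)
    codes = np.empty(arr.shape, dtype=np.int8)
    flat_in, flat_out = arr.ravel(), codes.ravel()
    for idx, val in enumerate(flat_in):
        lt = val if isinstance(val, LandType) else None
        if lt is None:
            try:
                lt = LandType(str(val))
            except ValueError:
                raise ValueError(f"unknown land type label: {val!r}") from None
        flat_out[idx] = LANDTYPE_CODES[lt]
    return codes


def make_grid(bed_depth, landtype, dx, dy, *, active=None, manning=None,
              open_boundary=(), manning_table=None) -> Grid:
    """Assemble a :class:`Grid` from raw fields.

    ``landtype`` may be an array of :class:`LandType`, labels, or integer
    codes.  Unless ``manning`` is given explicitly, roughness is populated
    per cell via :func:`manning_for_landtype`.
    """
    bed_depth = np.atleast_2d(np.asarray(bed_depth, dtype=float))
    codes = _landtype_codes(landtype)
    if codes.shape != bed_depth.shape:
        raise ValueError(f"landtype field shape {codes.shape} does not match "
                         f"bathymetry shape {bed_depth.shape}")
    if active is None:
        active = np.ones(bed_depth.shape, dtype=bool)
    if manning is None:
        lut = np.array([manning_for_landtype(lt, manning_table) for lt in LandType])
        manning = lut[codes]
    return Grid(dx=float(dx), dy=float(dy), bed_depth=bed_depth, landtype=codes,
                manning=np.asarray(manning, dtype=float), active=np.asarray(active, bool),
                open_boundary=list(open_boundary))


def wet_mask(grid: Grid, zeta, h_dry: float = 0.01) -> np.ndarray:
    """Cells that carry water: active and total depth ``d + zeta > h_dry``."""
    if h_dry <= 0:
        raise ValueError("drying threshold h_dry must be positive")
    zeta = np.asarray(zeta, dtype=float)
    return grid.active & (grid.bed_depth + zeta > h_dry)
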