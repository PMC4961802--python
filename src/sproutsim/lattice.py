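"""Sprout geometry on the unrolled cylindrical vessel wall.

The sprout surface is a 2-D lattice, periodic circumferentially (axis y) and
bounded axially (axis x, increasing toward the sprout front).  Each site is a
unit square owned by exactly one endothelial cell or by the medium (EMPTY).
memAgents are the territory sites with at least one non-owner 4-neighbour,
plus all filopodium sites; filopodia live in a layer above the body lattice
(see :mod:`sproutsim.cytoskeleton`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kernel import EMPTY, memagent_com, scan_mesh

__all__ = [
    "EMPTY", "LatticeConfig", "ECell", "SproutMesh",
    "build_sprout", "assign_genotypes", "center_of_mass",
    "junction_interfaces",
]

WT = 0
KD = 1


class ConfigurationError(ValueError):
    """A lattice or scenario configuration violates one of its invariants."""


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry of the initial sprout.

    With the defaults, ten cells tile five axial bands of two half-cylinder
    cells each (50 sites per cell) and the 10-site circumference doubles as
    the tip-scoring window at the sprout front.
    """

    circumference: int = 10
    axial_length: int = 120
    cells_per_cross_section: int = 2
    n_cells: int = 10
    band_length: int = 10

    def __post_init__(self):
        if self.circumference % self.cells_per_cross_section != 0:
            raise ConfigurationError(
                "circumference must be divisible by cells_per_cross_section "
                f"({self.circumference} % {self.cells_per_cross_section})")
        if self.n_cells % self.cells_per_cross_section != 0:
            raise ConfigurationError(
                "n_cells must be divisible by cells_per_cross_section "
                f"({self.n_cells} % {self.cells_per_cross_section})")
        if self.axial_length <= self.n_bands * self.band_length:
            raise ConfigurationError(
                "axial_length must leave room ahead of the sprout front "
                f"(need > {self.n_bands * self.band_length}, "
                f"got {self.axial_length})")

    @property
    def n_bands(self) -> int:
        return self.n_cells // self.cells_per_cross_section

    @property
    def target_area(self) -> int:
        """Sites per cell in the initial tiling (the soft area target)."""
        return self.band_length * self.circumference \
            // self.cells_per_cross_section


@dataclass
class ECell:
    """Bookkeeping view of one endothelial cell on a mesh."""

    id: int
    genotype: int = WT  # WT or KD

    def territory(self, mesh: "SproutMesh") -> set[tuple[int, int]]:
        xs, ys = np.nonzero(mesh.owner == self.id)
        return set(zip(xs.tolist(), ys.tolist()))


@dataclass
class SproutMesh:
    """Ownership lattice plus the filopodia layer.

    ``owner[x, y]`` is the body-occupying cell id or EMPTY.  ``filo_len`` and
    ``filo_base`` describe, per cell and circumferential column, the 1-wide
    axial filopodium chain anchored at the cell's frontmost body site in that
    column (chain sites x = base+1 .. base+len).
    """

    config: LatticeConfig
    owner: np.ndarray
    genotype: np.ndarray
    filo_len: np.ndarray = field(default=None)
    filo_base: np.ndarray = field(default=None)

    def __post_init__(self):
        n, circ = self.config.n_cells, self.config.circumference
        if self.filo_len is None:
            self.filo_len = np.zeros((n, circ), dtype=np.int32)
        if self.filo_base is None:
            self.filo_base = np.full((n, circ), -1, dtype=np.int32)

    @property
    def n_cells(self) -> int:
        return self.config.n_cells

    def cells(self) -> list[ECell]:
        return [ECell(c, int(self.genotype[c])) for c in range(self.n_cells)]

    def areas(self) -> np.ndarray:
        area, *_ = scan_mesh(self.owner, self.n_cells)
        return area

    def memagent_counts(self) -> np.ndarray:
        """M_tot per cell: boundary body sites plus filopodium sites."""
        _, n_boundary, *_ = scan_mesh(self.owner, self.n_cells)
        return n_boundary + self.filo_len.sum(axis=1)

    def front_row(self) -> int:
        """Maximal occupied axial row (body sites only)."""
        occupied = np.nonzero((self.owner >= 0).any(axis=1))[0]
        return int(occupied[-1]) if occupied.size else -1

    def copy(self) -> "SproutMesh":
        return SproutMesh(self.config, self.owner.copy(),
                          self.genotype.copy(), self.filo_len.copy(),
                          self.filo_base.copy())

    # --- serialization -------------------------------------------------
    def to_csv(self, path, timestep: int = 0) -> None:
        """Site table (x, y, owner) with a JSON header line (# prefixed)."""
        header = {
            "timestep": timestep,
            "circumference": self.config.circumference,
            "axial_length": self.config.axial_length,
            "n_cells": self.config.n_cells,
            "cells_per_cross_section": self.config.cells_per_cross_section,
            "band_length": self.config.band_length,
            "genotype": self.genotype.tolist(),
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("x,y,owner\n")
            for x in range(self.config.axial_length):
                for y in range(self.config.circumference):
                    if self.owner[x, y] != EMPTY:
                        fh.write(f"{x},{y},{self.owner[x, y]}\n")

    @classmethod
    def from_csv(cls, path) -> "SproutMesh":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            fh.readline()  # column names
            config = LatticeConfig(
                circumference=header["circumference"],
                axial_length=header["axial_length"],
                cells_per_cross_section=header["cells_per_cross_section"],
                n_cells=header["n_cells"],
                band_length=header["band_length"])
            owner = np.full((config.axial_length, config.circumference),
                            EMPTY, dtype=np.int32)
            for line in fh:
                x, y, c = (int(v) for v in line.split(","))
                owner[x, y] = c
        genotype = np.asarray(header["genotype"], dtype=np.int8)
        return cls(config, owner, genotype)


def build_sprout(config: LatticeConfig) -> SproutMesh:
    """Tile the initial sprout: rectangular cell territories in axial bands.

    Band ``b`` spans x in [b*L, (b+1)*L); within a band each cell occupies a
    contiguous arc of circumference/cells_per_cross_section columns.
    Alternate bands are offset circumferentially by half a territory width
    (brick-like), so every cell contacts both cells of the neighbouring
    cross-sections — the arrangement on a real cylindrical sprout, and the
    geometry under which the ideal salt-and-pepper pattern of the 10-cell
    sprout has exactly three active cells.
    """
    cfg = config
    owner = np.full((cfg.axial_length, cfg.circumference), EMPTY,
                    dtype=np.int32)
    width = cfg.circumference // cfg.cells_per_cross_section
    stagger = width // 2
    cid = 0
    for b in range(cfg.n_bands):
        offset = stagger if b % 2 else 0
        for j in range(cfg.cells_per_cross_section):
            y0 = (j * width + offset) % cfg.circumference
            for x in range(b * cfg.band_length, (b + 1) * cfg.band_length):
                for dy in range(width):
                    owner[x, (y0 + dy) % cfg.circumference] = cid
            cid += 1
    genotype = np.zeros(cfg.n_cells, dtype=np.int8)
    return SproutMesh(cfg, owner, genotype)


def assign_genotypes(mesh: SproutMesh, ratio: tuple[int, int],
                     seed: int) -> SproutMesh:
    """Label cells KD/WT in the given (kd, wt) ratio by a seed-determined
    random placement; exact counts (e.g. 5/5 for 1:1 of 10, 9/1 for 9:1)."""
    kd, wt = ratio
    n = mesh.n_cells
    if kd < 0 or wt < 0 or kd + wt == 0 or n % (kd + wt) != 0:
        raise ConfigurationError(
            f"ratio {kd}:{wt} is not realizable with {n} cells")
    scale = n // (kd + wt)
    labels = np.array([KD] * (kd * scale) + [WT] * (wt * scale),
                      dtype=np.int8)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    out = mesh.copy()
    out.genotype = labels
    return out


def center_of_mass(mesh: SproutMesh, cell_id: int) -> tuple[float, float]:
    """Mean memAgent position of one cell: plain mean along x, circular mean
    along the periodic y (only COM_x feeds the migration metrics)."""
    com_x, com_y = memagent_com(mesh.owner, mesh.filo_len, mesh.filo_base,
                                mesh.n_cells)
    if np.isnan(com_x[cell_id]):
        raise ValueError(f"cell {cell_id} has no memAgents")
    return float(com_x[cell_id]), float(com_y[cell_id])


def junction_interfaces(mesh: SproutMesh) -> list[tuple[int, int, int]]:
    """Heterotypic cell-cell interfaces as (i, j, shared boundary length),
    i < j; length counts 4-adjacent site pairs with distinct owners."""
    *_, lmat, _f, _r, _p = _scan(mesh)
    out = []
    n = mesh.n_cells
    for i in range(n):
        for j in range(i + 1, n):
            if lmat[i, j] > 0:
                out.append((i, j, int(lmat[i, j])))
    return out


def _scan(mesh: SproutMesh):
    area, n_boundary, lmat, frontmost, front_row, perim = scan_mesh(
        mesh.owner, mesh.n_cells)
    return area, n_boundary, lmat, frontmost, front_row, perim
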