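"""Cortical virtual electrodes: mirrored 20-vertex patches.

Nine seed locations on the left sensorimotor cortex define nine
electrode pairs: each seed is grown to its 20 geodesically nearest
source vertices within the hemisphere (LP1-LP9), and the mirror image
of each seed through the mid-sagittal plane generates the matching
right-hemisphere electrode (RP1-RP9).  The aggregated source time
course of a patch substitutes a physical sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .headmodel import SourceSpace


@dataclass(frozen=True)
class VirtualElectrode:
    """One 20-vertex cortical patch."""

    label: str            # LP1..LP9 / RP1..RP9
    hemisphere: str       # "L" or "R"
    pair: str             # P1..P9
    seed: int             # source-space vertex id
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 20:
            raise ValueError(
                f"{self.label}: virtual electrodes span exactly 20 vertices, "
                f"got {len(self.members)}")


@dataclass
class ElectrodeSeries:
    """Aggregated source amplitude of one virtual electrode over time."""

    values: np.ndarray
    label: str
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


def default_seed_coordinates(radius: float = 0.072) -> np.ndarray:
    """Nine left-hemisphere seed positions along the sensorimotor strip.

    The strip runs from near the vertex down the lateral surface
    (roughly the hand/arm/foot representations of the pre- and
    post-central gyri); seeds are spaced every ~8 degrees of polar angle
    in a coronal arc tilted slightly posteriorly.  Configurable: any
    (9, 3) coordinate array may replace them.
    """
    polar = np.deg2rad(np.linspace(12, 76, 9))   # from vertex toward ear
    y = -0.1  # slight posterior tilt of the central-sulcus arc
    seeds = np.stack([
        -np.sin(polar),                          # left: x < 0
        np.full(9, y),
        np.cos(polar),
    ], axis=1)
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    return seeds * radius


def _geodesic_from(src: SourceSpace, seed: int,
                   allowed: np.ndarray) -> np.ndarray:
    """Geodesic distances from one vertex along mesh edges restricted to
    ``allowed`` vertices (boolean mask)."""
    edges = src.edges()
    keep = allowed[edges[:, 0]] & allowed[edges[:, 1]]
    edges = edges[keep]
    w = np.linalg.norm(src.vertices[edges[:, 0]] - src.vertices[edges[:, 1]],
                       axis=1)
    n = src.n_sources
    A = sparse.coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    A = A + A.T
    return dijkstra(A.tocsr(), directed=False, indices=seed)


def define_virtual_pairs(
    source_space: SourceSpace,
    seeds: np.ndarray | None = None,
) -> list[VirtualElectrode]:
    """Build the 18 virtual electrodes (9 mirrored pairs) from left seeds.

    Each seed coordinate snaps to the nearest left-hemisphere source
    vertex and is grown to its 20 geodesically nearest vertices within
    that hemisphere (ties broken by vertex index); the x-mirrored seed
    does the same on the right.  Returns LP1..LP9 followed by RP1..RP9.
    """
    if seeds is None:
        r = np.median(np.linalg.norm(source_space.vertices, axis=1))
        seeds = default_seed_coordinates(r)
    seeds = np.asarray(seeds, float)
    if seeds.shape != (9, 3):
        raise ValueError(f"expected 9 seed coordinates, got {seeds.shape}")
    hemi = source_space.hemisphere()
    out: list[VirtualElectrode] = []
    for side, sign, prefix in (("L", -1, "LP"), ("R", 1, "RP")):
        allowed = hemi == sign
        if allowed.sum() < 20:
            raise ValueError(
                f"hemisphere {side} has only {int(allowed.sum())} source "
                "vertices; need at least 20 (increase the mesh resolution)")
        for i, seed_xyz in enumerate(seeds, start=1):
            target = seed_xyz if sign < 0 \
                else seed_xyz * np.array([-1.0, 1.0, 1.0])
            d_euclid = np.linalg.norm(source_space.vertices - target, axis=1)
            d_euclid[~allowed] = np.inf
            seed_id = int(np.argmin(d_euclid))
            d_geo = _geodesic_from(source_space, seed_id, allowed)
            d_geo[~allowed] = np.inf
            order = np.lexsort((np.arange(len(d_geo)), d_geo))
            members = tuple(int(v) for v in order[:20])
            out.append(VirtualElectrode(
                label=f"{prefix}{i}", hemisphere=side, pair=f"P{i}",
                seed=seed_id, members=members))
    return out


def extract_series(J: np.ndarray, ve: VirtualElectrode,
                   fs: float = 128.0) -> ElectrodeSeries:
    """Sign-aligned mean of the member dipole time courses.

    Fixed-orientation dipole signs flip across sulci, so a naive mean
    cancels; each member is flipped to correlate non-negatively with the
    seed vertex before averaging.  ``J`` is (n_sources, n_times).
    """
    J = np.asarray(J, float)
    if max(ve.members) >= J.shape[0]:
        raise ValueError(f"{ve.label}: member vertex {max(ve.members)} "
                         f"missing from estimate with {J.shape[0]} sources")
    block = J[list(ve.members)]
    seed_row = J[ve.seed]
    signs = np.sign(block @ seed_row)
    signs[signs == 0] = 1.0
    return ElectrodeSeries(values=(signs[:, None] * block).mean(axis=0),
                           label=ve.label, fs=fs)


def electrodes_to_frame(ves: list[VirtualElectrode]) -> pd.DataFrame:
    """Tabular serialization: label, pair, seed and the 20 member ids."""
    return pd.DataFrame([
        {"label": v.label, "pair": v.pair, "hemisphere": v.hemisphere,
         "seed": v.seed,
         **{f"m{j}": m for j, m in enumerate(v.members)}}
        for v in ves
    ])


def frame_to_electrodes(frame: pd.DataFrame) -> list[VirtualElectrode]:
    out = []
    mcols = [c for c in frame.columns if c.startswith("m") and c[1:].isdigit()]
    for _, row in frame.iterrows():
        out.append(VirtualElectrode(
            label=row["label"], hemisphere=row["hemisphere"],
            pair=row["pair"], seed=int(row["seed"]),
            members=tuple(int(row[c]) for c in sorted(
                mcols, key=lambda c: int(c[1:])))))
    return out
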