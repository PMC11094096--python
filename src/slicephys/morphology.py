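"""Sholl analysis, cable length and spine morphometrics on SWC trees.

Sholl analysis counts dendritic crossings of concentric spheres centered on
the soma at fixed radial increments (20 um by default).  A straight
parent-child segment crosses the sphere of radius r when its endpoints lie
strictly on opposite sides; an endpoint exactly on the sphere counts as no
crossing (a deterministic rule for a measure-zero case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParameterError


class SWCFormatError(ValueError):
    """Raised for structurally invalid SWC trees."""


@dataclass
class MorphTree:
    """SWC-style node graph rooted at the soma.

    ``nodes`` is a DataFrame with columns id, type, x, y, z, radius, parent;
    ``spines`` is an optional list of ``{attach_id, length_um}`` records.
    """

    nodes: pd.DataFrame
    spines: list = field(default_factory=list)

    @classmethod
    def from_records(cls, records: list[dict]) -> "MorphTree":
        df = pd.DataFrame(records, columns=["id", "type", "x", "y", "z", "radius", "parent"])
        tree = cls(df)
        tree.validate()
        return tree

    def validate(self) -> None:
        df = self.nodes
        if df.empty:
            raise SWCFormatError("empty tree")
        roots = df[df.parent == -1]
        if len(roots) != 1:
            raise SWCFormatError(f"expected exactly one root, found {len(roots)}")
        ids = set(df.id)
        if len(ids) != len(df):
            raise SWCFormatError("duplicate node ids")
        for _, row in df.iterrows():
            if row.parent != -1 and row.parent not in ids:
                raise SWCFormatError(f"node {int(row.id)} references missing parent {int(row.parent)}")
        # cycle check by walking to the root from every node
        parent = dict(zip(df.id, df.parent))
        for start in df.id:
            seen = set()
            n = start
            while n != -1:
                if n in seen:
                    raise SWCFormatError(f"cycle involving node {int(start)}")
                seen.add(n)
                n = parent[n]

    @property
    def root(self) -> pd.Series:
        return self.nodes[self.nodes.parent == -1].iloc[0]

    def soma_center(self) -> np.ndarray:
        """Root coordinate; multi-node somas collapse to their centroid."""
        soma = self.nodes[self.nodes.type == 1]
        if soma.empty:
            soma = self.nodes[self.nodes.parent == -1]
        return soma[["x", "y", "z"]].mean().to_numpy()

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent/child coordinate arrays for every non-root node."""
        df = self.nodes
        coords = df.set_index("id")[["x", "y", "z"]]
        child = df[df.parent != -1]
        p1 = coords.loc[child.parent].to_numpy(dtype=float)
        p2 = child[["x", "y", "z"]].to_numpy(dtype=float)
        return p1, p2

    def total_length(self) -> float:
        """Total cable length: sum of Euclidean inter-node distances, um."""
        p1, p2 = self.segments()
        if p1.size == 0:
            return 0.0
        return float(np.linalg.norm(p2 - p1, axis=1).sum())


def read_swc(path: str | Path) -> MorphTree:
    """Parse a standard 7-column SWC file (units assumed um)."""
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCFormatError(f"line {ln}: expected 7 columns, got {len(parts)}")
        records.append(dict(
            id=int(parts[0]), type=int(parts[1]),
            x=float(parts[2]), y=float(parts[3]), z=float(parts[4]),
            radius=float(parts[5]), parent=int(parts[6]),
        ))
    return MorphTree.from_records(records)


def write_swc(tree: MorphTree, path: str | Path) -> None:
    lines = ["# id type x y z radius parent"]
    for _, r in tree.nodes.iterrows():
        lines.append(f"{int(r.id)} {int(r.type)} {float(r.x)!r} {float(r.y)!r} "
                     f"{float(r.z)!r} {float(r.radius)!r} {int(r.parent)}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ShollResult:
    radii: list          # um, strictly increasing
    intersections: list  # crossings per radius
    total_intersections: int
    total_length: float  # um


def sholl_analysis(tree: MorphTree, step: float = 20.0,
                   max_radius: float | None = None,
                   projection_2d: bool = False) -> ShollResult:
    """Count sphere crossings at radii step, 2*step, ... around the soma.

    ``projection_2d`` drops the z coordinate first (circle crossings in the
    projected plane), matching 2D image-based Sholl implementations.
    """
    if tree.nodes.empty:
        raise ParameterError("empty tree")
    if step <= 0:
        raise ParameterError("step must be positive")
    center = tree.soma_center()
    p1, p2 = tree.segments()
    if p1.size == 0:
        raise ParameterError("tree has no segments")
    p1 = p1 - center
    p2 = p2 - center
    if projection_2d:
        p1 = p1[:, :2]
        p2 = p2[:, :2]
    r1 = np.linalg.norm(p1, axis=1)
    r2 = np.linalg.norm(p2, axis=1)
    r_max = max_radius if max_radius is not None else max(r1.max(), r2.max())
    radii = np.arange(step, r_max + step * 1e-9, step)
    counts = [int(np.sum((r1 - r) * (r2 - r) < 0)) for r in radii]
    total_len = float(np.linalg.norm(p2 - p1, axis=1).sum())
    return ShollResult(radii=[float(r) for r in radii], intersections=counts,
                       total_intersections=int(sum(counts)), total_length=total_len)


def sholl_brute_force(tree: MorphTree, step: float = 20.0,
                      max_radius: float | None = None,
                      resolution_um: float = 0.01) -> ShollResult:
    """Independent dense-sampling oracle: sample each segment at
    ``resolution_um`` and count sign changes of (||p|| - r)."""
    center = tree.soma_center()
    p1, p2 = tree.segments()
    p1 = p1 - center
    p2 = p2 - center
    lengths = np.linalg.norm(p2 - p1, axis=1)
    r_max = max_radius if max_radius is not None else max(
        np.linalg.norm(p1, axis=1).max(), np.linalg.norm(p2, axis=1).max())
    radii = np.arange(step, r_max + step * 1e-9, step)
    counts = np.zeros(radii.size, dtype=int)
    for a, b, L in zip(p1, p2, lengths):
        n = max(2, int(np.ceil(L / resolution_um)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        d = np.linalg.norm(pts, axis=1)
        for i, r in enumerate(radii):
            s = np.sign(d - r)
            counts[i] += int(np.sum(s[:-1] * s[1:] < 0))
    return ShollResult(radii=[float(r) for r in radii],
                       intersections=[int(c) for c in counts],
                       total_intersections=int(counts.sum()),
                       total_length=float(lengths.sum()))


@dataclass
class SpineResult:
    per_segment: pd.DataFrame     # segment_length_um, n_spines, density_per_um, mean_spine_length_um
    grand_mean_density: float     # per um, unweighted mean over segments
    grand_mean_length: float      # um, unweighted mean over segments


def spine_metrics(segments: list[dict]) -> SpineResult:
    """Spine density and length over a handful of dendritic segments.

    ``segments`` is a list of ``{length_um, spine_lengths_um}`` records
    (typically five 15-20 um stretches of apical dendrite).  Grand means are
    unweighted averages over segments, not pooled over spines.
    """
    if not segments:
        raise ParameterError("need at least one segment")
    rows = []
    for i, seg in enumerate(segments):
        L = float(seg["length_um"])
        if L <= 0:
            raise ParameterError(f"segment {i}: zero or negative length")
        spl = list(seg.get("spine_lengths_um", []))
        rows.append({
            "segment_length_um": L,
            "n_spines": len(spl),
            "density_per_um": len(spl) / L,
            "mean_spine_length_um": float(np.mean(spl)) if spl else np.nan,
        })
    df = pd.DataFrame(rows)
    return SpineResult(
        per_segment=df,
        grand_mean_density=float(df.density_per_um.mean()),
        grand_mean_length=float(df.mean_spine_length_um.mean()),
    )
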