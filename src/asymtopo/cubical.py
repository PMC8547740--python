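"""Cubical persistent homology of the sublevel-set filtration of a 3D image.

The filtration raises an intensity threshold through the image: voxels
enter in ascending value order, so the sublevel sets form a nested
sequence from the empty set to the full grid.  Two kinds of topological
structure are tracked:

* **0-cycles** (connected components): born at local minima, dying when
  two components merge (the younger one dies — the elder rule).  In an
  asymmetry image read on the left-hemisphere grid these encode rightward
  (negative-valued) asymmetric structures.
* **2-cycles** (cavities, enclosed voids): born when a hyper-intense
  region becomes fully enclosed by the sublevel set, dying at their
  interior local maximum.  These encode leftward (positive-valued)
  structures.

1-cycles (loops) are not computed; the analysis uses only components and
cavities.  0-cycles use 6-connectivity; 2-cycles are computed by duality
on the negated, boundary-padded image with the complementary
26-connectivity, which is the consistent digital-topology pairing.

Ties are broken by ascending row-major linear voxel index throughout, so
all outputs are deterministic.  The single component that never dies is
paired with the global maximum (min-max pairing) and flagged essential
rather than given an infinite death, so landscapes can use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid

Voxel = tuple[int, int, int]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)

#: Largest grid the brute-force oracle will accept (about 12^3 voxels).
ORACLE_MAX_VOXELS = 12 ** 3


@dataclass(frozen=True)
class PersistencePair:
    """One topological structure: birth/death values and critical voxels.

    ``birth_voxel`` is a local minimum for 0-cycles; ``death_voxel`` is a
    local maximum for 2-cycles.  ``lifespan = death - birth`` is the range
    of asymmetry values the structure spans.
    """

    dim: int
    birth_value: float
    death_value: float
    birth_voxel: Voxel | None = None
    death_voxel: Voxel | None = None
    essential: bool = False

    def __post_init__(self) -> None:
        if self.dim not in (0, 2):
            raise ValueError(f"dim must be 0 or 2, got {self.dim}")
        if self.birth_value > self.death_value:
            raise ValueError(
                f"birth {self.birth_value} exceeds death {self.death_value}"
            )

    @property
    def lifespan(self) -> float:
        return self.death_value - self.birth_value

    @property
    def zero_persistence(self) -> bool:
        return self.death_value == self.birth_value


@dataclass
class PersistenceDiagram:
    """All persistence pairs of one image (optionally one ROI / one dim)."""

    pairs: list[PersistencePair]
    source_id: str = ""

    def of_dim(self, dim: int) -> "PersistenceDiagram":
        return PersistenceDiagram(
            [p for p in self.pairs if p.dim == dim], self.source_id
        )

    def nonzero(self) -> "PersistenceDiagram":
        """Drop zero-lifespan (diagonal) pairs; essential pairs are kept."""
        return PersistenceDiagram(
            [p for p in self.pairs if p.essential or not p.zero_persistence],
            self.source_id,
        )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def multiset(self, dim: int | None = None) -> list[tuple[int, float, float]]:
        """Sorted multiset of (dim, birth, death) triples for comparison."""
        out = [
            (p.dim, p.birth_value, p.death_value)
            for p in self.pairs
            if dim is None or p.dim == dim
        ]
        return sorted(out)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            bx, by, bz = p.birth_voxel if p.birth_voxel is not None else (-1, -1, -1)
            dx, dy, dz = p.death_voxel if p.death_voxel is not None else (-1, -1, -1)
            rows.append(
                dict(dim=p.dim, birth=p.birth_value, death=p.death_value,
                     bx=bx, by=by, bz=bz, dx=dx, dy=dy, dz=dz,
                     essential=p.essential)
            )
        return pd.DataFrame(
            rows,
            columns=["dim", "birth", "death", "bx", "by", "bz",
                     "dx", "dy", "dz", "essential"],
        )


def _connectivity_offsets(connectivity: int) -> list[Voxel]:
    if connectivity == 6:
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    if connectivity == 26:
        return [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _neighbor_table(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """(n_voxels, n_neighbors) table of linear neighbor indices, -1 off-grid."""
    n = int(np.prod(shape))
    idx = np.arange(n, dtype=np.int64).reshape(shape)
    cols = []
    for off in _connectivity_offsets(connectivity):
        shifted = np.full(shape, -1, dtype=np.int64)
        dst = tuple(
            slice(max(0, -d), s - max(0, d)) for d, s in zip(off, shape)
        )
        src = tuple(
            slice(max(0, d), s - max(0, -d)) for d, s in zip(off, shape)
        )
        shifted[dst] = idx[src]
        cols.append(shifted.ravel())
    return np.stack(cols, axis=1)


def _sublevel_union_find(values: np.ndarray, connectivity: int):
    """Union-find over voxels in ascending (value, linear index) order.

    Returns ``(finite_pairs, essential_pairs)`` where each entry is
    ``(birth_value, birth_linidx, death_value, death_linidx)``.  Elder
    rule: at a merge the component with the later (value, index) birth
    dies at the merging voxel.  Each surviving root yields an essential
    pair with death at its component maximum.
    """
    flat = values.ravel()
    n = flat.size
    if n == 0:
        raise ValueError("empty grid")
    order = np.argsort(flat, kind="stable")
    nbrs = _neighbor_table(values.shape, connectivity)
    parent = np.full(n, -1, dtype=np.int64)
    birth = np.empty(n, dtype=np.int64)    # per-root birth voxel linear index
    comp_max = np.empty(n, dtype=np.int64)  # per-root argmax voxel so far

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    finite = []
    for v in order:
        v = int(v)
        # roots of distinct already-present neighbor components
        roots = []
        for u in nbrs[v]:
            u = int(u)
            if u < 0 or parent[u] < 0:
                continue
            ru = find(u)
            if ru not in roots:
                roots.append(ru)
        if not roots:
            # no processed neighbor: v is a (plateau-representative) local
            # minimum and births a new component
            parent[v] = v
            birth[v] = v
        else:
            rv = roots[0]
            parent[v] = rv
            for ru in roots[1:]:
                bu, bv = int(birth[ru]), int(birth[rv])
                if (flat[bu], bu) <= (flat[bv], bv):
                    elder, younger = ru, rv
                else:
                    elder, younger = rv, ru
                yb = int(birth[younger])
                finite.append((float(flat[yb]), yb, float(flat[v]), v))
                parent[younger] = elder
                rv = elder
        # v entered last, so it is the running maximum of its component
        comp_max[find(v)] = v

    roots = {find(int(i)) for i in range(n)}
    essential = []
    for r in sorted(roots):
        b = int(birth[r])
        m = int(comp_max[r])
        essential.append((float(flat[b]), b, float(flat[m]), m))
    return finite, essential


def _unravel(lin: int, shape: tuple[int, int, int]) -> Voxel:
    return tuple(int(c) for c in np.unravel_index(lin, shape))


def sublevel_zero_cycles(grid: VoxelGrid, connectivity: int = 6) -> list[PersistencePair]:
    """0-cycle persistence pairs of the sublevel filtration.

    Each non-essential pair is born at a local minimum and dies where two
    components merge; the essential pair spans the global minimum to the
    global maximum.
    """
    values = grid.values
    if values.size == 0:
        raise ValueError("empty grid")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    finite, essential = _sublevel_union_find(values, connectivity)
    shape = values.shape
    pairs = [
        PersistencePair(0, b, d, _unravel(bi, shape), _unravel(di, shape))
        for b, bi, d, di in finite
    ]
    pairs.extend(
        PersistencePair(0, b, d, _unravel(bi, shape), _unravel(di, shape),
                        essential=True)
        for b, bi, d, di in essential
    )
    return pairs


def sublevel_two_cycles(grid: VoxelGrid, connectivity: int = 26) -> list[PersistencePair]:
    """2-cycle (cavity) persistence pairs, computed by duality.

    The 0-cycle union-find runs on the negated image with the dual
    connectivity (26 when 0-cycles use 6), padded by one layer introduced
    after every real voxel so that the exterior of the image counts as
    the surrounding void: a cavity is born when a hyper-intense region
    becomes enclosed and dies at its interior maximum.  The dual
    essential component (the outside) is discarded; reported births and
    deaths are on the original value scale.
    """
    values = grid.values
    if values.size == 0:
        raise ValueError("empty grid")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    padded = np.pad(-values, 1, constant_values=-np.inf)
    finite, _essential = _sublevel_union_find(padded, connectivity)
    pshape = padded.shape
    pairs = []
    for b, bi, d, di in finite:
        # dual birth voxel = local maximum of f (cavity death);
        # dual death (merge) voxel = voxel completing the enclosure (cavity birth)
        death_voxel = tuple(c - 1 for c in _unravel(bi, pshape))
        birth_voxel = tuple(c - 1 for c in _unravel(di, pshape))
        pairs.append(PersistencePair(2, -d, -b, birth_voxel, death_voxel))
    return pairs


def compute_persistence(grid: VoxelGrid, connectivity: int = 6,
                        source_id: str = "") -> PersistenceDiagram:
    """Full persistence diagram: 0-cycles plus 2-cycles.

    Zero-lifespan pairs (on the diagonal) are retained; they can be
    dropped with :meth:`PersistenceDiagram.nonzero`.
    """
    dual = 26 if connectivity == 6 else 6
    pairs = sublevel_zero_cycles(grid, connectivity)
    pairs += sublevel_two_cycles(grid, dual)
    return PersistenceDiagram(pairs, source_id)


def betti_at_threshold(grid: VoxelGrid, t: float,
                       connectivity: int = 6) -> tuple[int, int]:
    """(number of components, number of cavities) of the sublevel set at t.

    Components are labelled directly with the primal connectivity;
    cavities are complement components (dual connectivity) not connected
    to the exterior of the image.
    """
    values = grid.values
    mask = values <= t
    _, b0 = ndimage.label(mask, structure=_STRUCT_6 if connectivity == 6 else _STRUCT_26)
    comp = np.pad(~mask, 1, constant_values=True)
    lbl, nlab = ndimage.label(comp, structure=_STRUCT_26 if connectivity == 6 else _STRUCT_6)
    if nlab == 0:
        return int(b0), 0
    outside = lbl[0, 0, 0]
    b2 = len(set(np.unique(lbl[lbl > 0])) - {outside})
    return int(b0), int(b2)


def oracle_diagram(grid: VoxelGrid, connectivity: int = 6) -> PersistenceDiagram:
    """Brute-force reference diagram by exhaustive threshold sweep.

    At every distinct image value the sublevel set is labelled directly
    (components) and the complement labelled for enclosed cavities;
    births, merges and fills are tracked explicitly.  Independent of the
    union-find implementation, it serves as the correctness oracle on
    small grids (refuses more than about 12^3 voxels).  Only
    positive-lifespan and essential pairs are produced: events happening
    at a single threshold value are invisible to a value sweep.
    """
    values = grid.values
    if values.size == 0:
        raise ValueError("empty grid")
    if values.size > ORACLE_MAX_VOXELS:
        raise ValueError(
            f"oracle refuses grids over {ORACLE_MAX_VOXELS} voxels "
            f"(got {values.size})"
        )
    if connectivity != 6:
        raise ValueError("oracle supports the default 6/26 convention only")
    thresholds = np.unique(values)
    pairs: list[PersistencePair] = []
    pairs.extend(_oracle_zero_sweep(values, thresholds))
    pairs.extend(_oracle_two_sweep(values, thresholds))
    return PersistenceDiagram(pairs, source_id="oracle")


def _oracle_zero_sweep(values: np.ndarray, thresholds: np.ndarray):
    comp_birth: dict[int, float] = {}
    prev_assign = np.zeros(values.shape, dtype=np.int64)  # 0 = not yet present
    next_id = 1
    out = []
    for t in thresholds:
        mask = values <= t
        lbl, nlab = ndimage.label(mask, structure=_STRUCT_6)
        new_assign = np.zeros_like(prev_assign)
        for lab in range(1, nlab + 1):
            region = lbl == lab
            prev_ids = np.unique(prev_assign[region])
            prev_ids = prev_ids[prev_ids > 0]
            if prev_ids.size == 0:
                cid = next_id
                next_id += 1
                comp_birth[cid] = float(t)
            else:
                # elder continues; creation order breaks birth-value ties
                cid = min(prev_ids, key=lambda c: (comp_birth[c], c))
                for other in prev_ids:
                    if other != cid:
                        out.append(
                            PersistencePair(0, comp_birth[other], float(t))
                        )
            new_assign[region] = cid
        prev_assign = new_assign
    survivors = np.unique(prev_assign[prev_assign > 0])
    for cid in survivors:
        out.append(
            PersistencePair(0, comp_birth[int(cid)], float(thresholds[-1]),
                            essential=True)
        )
    return out


def _oracle_two_sweep(values: np.ndarray, thresholds: np.ndarray):
    """Track enclosed complement components forward through the sweep.

    A cavity is born when a complement region loses its connection to the
    exterior (or splits off an existing cavity at a saddle); on a split
    the piece holding the larger interior maximum continues the parent.
    A cavity dies at the threshold that fills its last voxel.
    """
    pvals = np.pad(values, 1, constant_values=np.inf)
    cav_birth: dict[int, float] = {}
    prev_assign = np.zeros(pvals.shape, dtype=np.int64)
    next_id = 1
    out = []
    for t in thresholds:
        comp = np.pad(values > t, 1, constant_values=True)
        lbl, nlab = ndimage.label(comp, structure=_STRUCT_26)
        outside = int(lbl[0, 0, 0])
        new_assign = np.zeros_like(prev_assign)
        children: dict[int, list[tuple[float, int]]] = {}  # parent -> [(max, lab)]
        fresh: list[int] = []
        for lab in range(1, nlab + 1):
            if lab == outside:
                continue
            region = lbl == lab
            prev_ids = np.unique(prev_assign[region])
            prev_ids = prev_ids[prev_ids > 0]
            if prev_ids.size == 0:
                fresh.append(lab)  # newly enclosed, was outside-connected
            else:
                # a connected shrunken region lies in exactly one old component
                parent = int(prev_ids[0])
                children.setdefault(parent, []).append(
                    (float(pvals[region].max()), lab)
                )
        lab_to_id: dict[int, int] = {}
        for lab in fresh:
            lab_to_id[lab] = next_id
            cav_birth[next_id] = float(t)
            next_id += 1
        for parent, pieces in children.items():
            pieces.sort(key=lambda mx_lab: (-mx_lab[0], mx_lab[1]))
            lab_to_id[pieces[0][1]] = parent  # dominant piece continues
            for _, lab in pieces[1:]:
                lab_to_id[lab] = next_id
                cav_birth[next_id] = float(t)
                next_id += 1
        alive_prev = set(np.unique(prev_assign[prev_assign > 0]).tolist())
        filled = alive_prev - set(children.keys())
        for cid in sorted(filled):
            out.append(PersistencePair(2, cav_birth[cid], float(t)))
            del cav_birth[cid]
        for lab, cid in lab_to_id.items():
            new_assign[lbl == lab] = cid
        prev_assign = new_assign
    # at the top threshold the complement is empty: nothing survives
    return out
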