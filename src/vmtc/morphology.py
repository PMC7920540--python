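"""Neuron geometry: SWC reading, surrogate tree generation, and cable discretization.

The model cell is a tree of cylindrical sections with three anatomical
regions: a single-compartment soma of fixed surface area (293 um^2), an
axon initial segment (AIS) of 70 um total length and 1.5 um diameter, and
a dendritic tree whose diameters follow the Rall 3/2-power branching rule.
Real reconstructions can be loaded from SWC; the default build uses a
parametric surrogate tree whose free knobs (stem diameter, section length
scale) are set by passive calibration in :mod:`vmtc.simulator`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "SurrogateConfig",
    "CompartmentGrid",
    "SOMA_AREA_UM2",
    "AIS_LENGTH_UM",
    "AIS_DIAMETER_UM",
    "load_swc",
    "write_swc",
    "apply_rall_diameters",
    "build_surrogate",
    "classify_regions",
    "discretize",
]

#: fixed somatic surface area of the model (um^2)
SOMA_AREA_UM2 = 293.0
#: retained initial-axon (AIS) length (um) and imposed diameter (um)
AIS_LENGTH_UM = 70.0
AIS_DIAMETER_UM = 1.5

# side of the equivalent soma cylinder with L = d and pi*d*L = SOMA_AREA
_SOMA_SIDE_UM = math.sqrt(SOMA_AREA_UM2 / math.pi)

REGIONS = ("soma", "ais", "dend")
DENSITY_LABELS = ("ais", "soma", "dend_class_1", "dend_class_2", "dend_class_3")


@dataclass(frozen=True)
class Section:
    """One unbranched cylindrical section of the morphology.

    ``path_distance_to_soma`` is measured from the soma surface to the
    section midpoint, in um.
    """

    id: int
    region: str
    parent_id: int | None
    length: float
    diameter: float
    branch_order: int
    path_distance_to_soma: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"section {self.id}: length and diameter must be > 0")

    @property
    def area_um2(self) -> float:
        """Lateral cylinder area pi*d*L; the soma uses the fixed model area."""
        if self.region == "soma":
            return SOMA_AREA_UM2
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class Morphology:
    sections: tuple[Section, ...]
    provenance: str = "surrogate"  # "swc" | "surrogate"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate section ids")
        somas = [s for s in self.sections if s.region == "soma"]
        if len(somas) != 1:
            raise ValueError(f"expected exactly one soma section, found {len(somas)}")
        by_id = {s.id: s for s in self.sections}
        roots = 0
        for s in self.sections:
            if s.parent_id is None:
                roots += 1
                if s.region != "soma":
                    raise ValueError("tree root must be the soma")
            else:
                if s.parent_id not in by_id:
                    raise ValueError(f"section {s.id}: unknown parent {s.parent_id}")
                parent = by_id[s.parent_id]
                if s.branch_order < parent.branch_order:
                    raise ValueError(
                        f"section {s.id}: branch order below its parent's"
                    )
        if roots != 1:
            raise ValueError("parent graph must have exactly one root")
        self._check_acyclic(by_id)

    def _check_acyclic(self, by_id: dict[int, Section]) -> None:
        for s in self.sections:
            seen = set()
            cur: Section | None = s
            while cur is not None:
                if cur.id in seen:
                    raise ValueError(f"cycle in parent graph at section {cur.id}")
                seen.add(cur.id)
                cur = by_id.get(cur.parent_id) if cur.parent_id is not None else None

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections if s.region == "soma")

    @property
    def soma_area(self) -> float:
        return SOMA_AREA_UM2

    def children_of(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sec_id]

    def total_area_um2(self, region: str | None = None) -> float:
        return sum(
            s.area_um2 for s in self.sections if region is None or s.region == region
        )


@dataclass(frozen=True)
class SurrogateConfig:
    """Parameters of the surrogate dendritic tree.

    ``max_branch_order`` is the highest dendritic branch order reached by
    symmetric binary splitting (0 or 1 means unbranched stems).  The Rall
    exponent of 3/2 gives the d^{3/2} branch-point rule whose inverse uses
    the 2/3 power.
    """

    n_stems: int = 5
    max_branch_order: int = 3
    section_length_mean: float = 40.0
    rall_exponent: float = 1.5
    stem_diameter: float = 2.5
    min_diameter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        if self.section_length_mean <= 0 or self.stem_diameter <= 0:
            raise ValueError("lengths and diameters must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateConfig":
        return cls(**json.loads(text))


def _soma_section(sec_id: int = 0) -> Section:
    return Section(
        id=sec_id,
        region="soma",
        parent_id=None,
        length=_SOMA_SIDE_UM,
        diameter=_SOMA_SIDE_UM,
        branch_order=0,
        path_distance_to_soma=0.0,
    )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_SOMA, _SWC_AXON = 1, 2


def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC reconstruction.

    The axon is truncated to its initial 70 um of path length and relabelled
    ``ais`` with the imposed 1.5 um diameter; the soma is replaced by the
    single fixed-area model compartment.  Runs of points between branch
    points are merged into unbranched sections.
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise ValueError(f"malformed SWC row at line {lineno}: {line!r}")
            try:
                pid = int(cols[0])
                ptype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise ValueError(f"malformed SWC row at line {lineno}: {line!r}") from exc
            if parent == pid:
                raise ValueError(f"structural error: point {pid} is its own parent")
            points[pid] = (ptype, x, y, z, r, parent)

    if not points:
        raise ValueError("empty SWC file")
    soma_pts = [pid for pid, p in points.items() if p[0] == _SWC_SOMA]
    if not soma_pts:
        raise ValueError("structural error: no soma points")
    roots = [pid for pid, p in points.items() if p[5] == -1]
    if len(roots) != 1:
        raise ValueError(f"structural error: expected one root, found {len(roots)}")
    # detect cycles / disconnected soma clusters
    for pid, p in points.items():
        seen = set()
        cur = pid
        while cur != -1:
            if cur in seen:
                raise ValueError(f"structural error: cycle through point {cur}")
            seen.add(cur)
            if cur not in points:
                raise ValueError(f"structural error: missing parent {cur}")
            cur = points[cur][5]
    soma_parent_types = {
        points[points[pid][5]][0] for pid in soma_pts if points[pid][5] != -1
    }
    if soma_parent_types - {_SWC_SOMA}:
        raise ValueError("structural error: multiple disconnected somas")

    sections: list[Section] = [_soma_section(0)]
    next_id = 1

    def _dist(a: int, b: int) -> float:
        pa, pb = points[a], points[b]
        return math.dist(pa[1:4], pb[1:4])

    children: dict[int, list[int]] = {}
    for pid, p in points.items():
        if p[5] != -1:
            children.setdefault(p[5], []).append(pid)

    # neurite stems: non-soma points whose parent is a soma point
    stems = [
        pid
        for pid, p in points.items()
        if p[0] != _SWC_SOMA and p[5] in points and points[p[5]][0] == _SWC_SOMA
    ]

    def _walk(start: int, parent_sec: int, order: int, path0: float) -> None:
        nonlocal next_id
        run = [start]
        while True:
            kids = [k for k in children.get(run[-1], []) if points[k][0] != _SWC_SOMA]
            if len(kids) == 1:
                run.append(kids[0])
            else:
                break
        ptype = points[start][0]
        prev = points[start][5]
        seg_len = _dist(prev, start) + sum(_dist(a, b) for a, b in zip(run, run[1:]))
        if seg_len <= 0:
            seg_len = 1.0  # degenerate single-point neurite: nominal 1 um stub
        radii = [points[pp][4] for pp in run]
        diam = 2.0 * float(np.mean(radii)) if max(radii) > 0 else 1.0
        if ptype == _SWC_AXON:
            # truncate the axon at 70 um path distance; impose AIS diameter
            if path0 >= AIS_LENGTH_UM:
                return
            seg_len = min(seg_len, AIS_LENGTH_UM - path0)
            region, diam = "ais", AIS_DIAMETER_UM
        else:
            region = "dend"
        sec = Section(
            id=next_id,
            region=region,
            parent_id=parent_sec,
            length=seg_len,
            diameter=diam,
            branch_order=order,
            path_distance_to_soma=path0 + seg_len / 2.0,
        )
        sections.append(sec)
        next_id += 1
        kids = [k for k in children.get(run[-1], []) if points[k][0] != _SWC_SOMA]
        for k in kids:
            _walk(k, sec.id, order + (1 if len(kids) > 1 else 0), path0 + seg_len)

    for stem in stems:
        _walk(stem, 0, 1, 0.0)
    return Morphology(sections=tuple(sections), provenance="swc")


def write_swc(m: Morphology, path) -> None:
    """Serialize a morphology back to SWC (one point per section end)."""
    type_code = {"soma": 1, "ais": 2, "dend": 3}
    rows = []
    # lay sections out along x for inspection purposes; geometry is abstract
    pos: dict[int, float] = {}
    sec_point: dict[int, int] = {}
    n = 0
    for s in sorted(m.sections, key=lambda s: s.id):
        n += 1
        parent_pt = -1 if s.parent_id is None else sec_point[s.parent_id]
        x0 = 0.0 if s.parent_id is None else pos[s.parent_id]
        x = x0 + s.length
        pos[s.id] = x
        sec_point[s.id] = n
        rows.append(
            f"{n} {type_code[s.region]} {x:.6f} 0.0 0.0 "
            f"{s.diameter / 2.0:.6f} {parent_pt}"
        )
    with open(path, "w") as fh:
        fh.write("# vmtc morphology export\n")
        fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Rall diameters and the surrogate tree
# ---------------------------------------------------------------------------

def apply_rall_diameters(
    m: Morphology,
    stem_diameter: float,
    rall_exponent: float = 1.5,
    min_diameter: float = 0.3,
) -> Morphology:
    """Assign dendritic diameters top-down from the Rall branching rule.

    At every branch point d_parent^p = sum(d_child^p) with p = 3/2 by
    default; sibling children receive equal diameters, so each child gets
    d_child = (d_parent^p / n_children)^(1/p).  Unbranched continuations
    keep the parent diameter.  Diameters are clamped at ``min_diameter``.
    """
    if stem_diameter <= 0:
        raise ValueError("stem_diameter must be > 0")
    p = rall_exponent
    new: dict[int, Section] = {}
    children: dict[int | None, list[Section]] = {}
    for s in m.sections:
        children.setdefault(s.parent_id, []).append(s)

    def _descend(sec: Section, diam: float) -> None:
        diam = max(diam, min_diameter)
        new[sec.id] = replace(sec, diameter=diam)
        kids = children.get(sec.id, [])
        if not kids:
            return
        child_d = diam if len(kids) == 1 else (diam**p / len(kids)) ** (1.0 / p)
        for k in kids:
            _descend(k, child_d)

    for s in m.sections:
        if s.region != "dend":
            new[s.id] = s
    for stem in children.get(m.soma.id, []):
        if stem.region == "dend":
            _descend(stem, stem_diameter)
    ordered = tuple(new[s.id] for s in m.sections)
    return Morphology(sections=ordered, provenance=m.provenance)


def build_surrogate(config: SurrogateConfig = SurrogateConfig()) -> Morphology:
    """Build the parametric surrogate morphology.

    Soma (fixed 293 um^2) + AIS (70 um x 1.5 um) + ``n_stems`` symmetric
    binary dendritic trees with ``section_length_mean``-long sections and
    Rall-rule diameters.  Deterministic for a fixed config.
    """
    sections: list[Section] = [_soma_section(0)]
    next_id = 1
    # AIS as a two-section chain attached to the soma
    for i in range(2):
        half = AIS_LENGTH_UM / 2.0
        sections.append(
            Section(
                id=next_id,
                region="ais",
                parent_id=0 if i == 0 else next_id - 1,
                length=half,
                diameter=AIS_DIAMETER_UM,
                branch_order=0,
                path_distance_to_soma=half * i + half / 2.0,
            )
        )
        next_id += 1

    L = config.section_length_mean

    def _grow(parent_id: int, order: int, path0: float) -> None:
        nonlocal next_id
        sec = Section(
            id=next_id,
            region="dend",
            parent_id=parent_id,
            length=L,
            diameter=1.0,  # placeholder, replaced by the Rall pass
            branch_order=order,
            path_distance_to_soma=path0 + L / 2.0,
        )
        sections.append(sec)
        next_id += 1
        if order < config.max_branch_order:
            for _ in range(2):
                _grow(sec.id, order + 1, path0 + L)

    for _ in range(config.n_stems):
        _grow(0, 1, 0.0)

    m = Morphology(sections=tuple(sections), provenance="surrogate")
    return apply_rall_diameters(
        m,
        stem_diameter=config.stem_diameter,
        rall_exponent=config.rall_exponent,
        min_diameter=config.min_diameter,
    )


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def classify_regions(
    m: Morphology, proximal_path_cutoff: float = 100.0
) -> dict[int, str]:
    """Map every section to a channel-density column label.

    Default scheme: dendrites beyond ``proximal_path_cutoff`` um of path
    distance are 'distal' (``dend_class_1``); proximal first-order dendrites
    are ``dend_class_2``; proximal second-and-higher-order dendrites are
    ``dend_class_3``.  The cutoff is the configurable knob of the scheme.
    """
    out: dict[int, str] = {}
    for s in m.sections:
        if s.region == "soma":
            out[s.id] = "soma"
        elif s.region == "ais":
            out[s.id] = "ais"
        elif s.path_distance_to_soma > proximal_path_cutoff:
            out[s.id] = "dend_class_1"
        elif s.branch_order <= 1:
            out[s.id] = "dend_class_2"
        else:
            out[s.id] = "dend_class_3"
    return out


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class CompartmentGrid:
    """Flat compartment arrays for the cable solver.

    Compartments are ordered root-first so that ``parent[i] < i`` for all
    non-root compartments (the ordering required by the Hines solve).
    Areas are in um^2, lengths/diameters in um.
    """

    section_id: np.ndarray  # (n,) int
    parent: np.ndarray  # (n,) int, -1 for the root
    length_um: np.ndarray
    diam_um: np.ndarray
    area_um2: np.ndarray
    is_soma: np.ndarray  # bool

    @property
    def n(self) -> int:
        return self.section_id.size

    def axial_conductance_uS(self, ri_ohm_cm: float) -> np.ndarray:
        """Conductance (uS) between each compartment and its parent.

        Series half-cylinder resistances: R = 4*ri*(L/2)/(pi*d^2) per side,
        in MOhm with L, d in cm.  Entry 0 (root) is 0.
        """
        L_cm = self.length_um * 1e-4
        d_cm = self.diam_um * 1e-4
        rhalf = 4.0 * ri_ohm_cm * (L_cm / 2.0) / (math.pi * d_cm**2) * 1e-6  # MOhm
        g = np.zeros(self.n)
        for i in range(self.n):
            p = self.parent[i]
            if p < 0:
                continue
            g[i] = 1.0 / (rhalf[i] + rhalf[p])
        return g


def discretize(m: Morphology, max_seg_length: float = 40.0) -> CompartmentGrid:
    """Split each section into ceil(L / max_seg_length) equal compartments.

    The soma stays a single compartment with the fixed model area.  Total
    membrane area is conserved exactly (each compartment keeps pi*d*L of its
    slice of the parent section).
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be > 0")
    order = _root_first_order(m)
    sec_ids: list[int] = []
    parents: list[int] = []
    lengths: list[float] = []
    diams: list[float] = []
    areas: list[float] = []
    is_soma: list[bool] = []
    last_comp_of_section: dict[int, int] = {}
    for s in order:
        if s.region == "soma":
            nseg = 1
        else:
            nseg = max(1, math.ceil(s.length / max_seg_length))
        seg_len = s.length / nseg
        for k in range(nseg):
            idx = len(sec_ids)
            if k == 0:
                parent = (
                    -1 if s.parent_id is None else last_comp_of_section[s.parent_id]
                )
            else:
                parent = idx - 1
            sec_ids.append(s.id)
            parents.append(parent)
            lengths.append(seg_len)
            diams.append(s.diameter)
            areas.append(
                SOMA_AREA_UM2 if s.region == "soma" else math.pi * s.diameter * seg_len
            )
            is_soma.append(s.region == "soma")
        last_comp_of_section[s.id] = len(sec_ids) - 1
    return CompartmentGrid(
        section_id=np.array(sec_ids, dtype=np.int64),
        parent=np.array(parents, dtype=np.int64),
        length_um=np.array(lengths),
        diam_um=np.array(diams),
        area_um2=np.array(areas),
        is_soma=np.array(is_soma, dtype=bool),
    )


def _root_first_order(m: Morphology) -> list[Section]:
    by_parent: dict[int | None, list[Section]] = {}
    for s in m.sections:
        by_parent.setdefault(s.parent_id, []).append(s)
    out: list[Section] = []
    stack = [m.soma]
    while stack:
        s = stack.pop()
        out.append(s)
        stack.extend(reversed(by_parent.get(s.id, [])))
    return out
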