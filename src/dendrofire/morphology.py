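"""SWC neuronal morphologies: parsing, validation, writing, and tree surgery.

The SWC format is a plain-text table with seven whitespace-separated columns
per point: ``id structure x y z radius parent_id``. Coordinates and radii are
micrometres; ``structure`` is the standard code (1 soma, 2 axon, 3 basal
dendrite, 4 apical dendrite); ``parent_id`` is ``-1`` for the single root.

A parsed :class:`Morphology` carries the raw point table plus a *section
partition*: maximal unbranched runs of same-structure points. A section ends
at a branch point, at a terminal, or where the structure code changes. Every
non-root point belongs to exactly one section; each section additionally
stores its proximal attachment point (the parent of its first owned point) so
that inter-point geometry is complete.

Tree surgery (:func:`graft`, :func:`split_section`) operates on whole
morphologies and returns new, revalidated objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SwcPoint",
    "Section",
    "Morphology",
    "SwcError",
    "SwcStructureError",
    "SwcValidationError",
    "GraftError",
    "SOMA",
    "AXON",
    "BASAL",
    "APICAL",
    "parse_swc",
    "parse_swc_text",
    "write_swc",
    "to_swc_text",
    "graft",
    "split_section",
]

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
_KNOWN_STRUCTURES = {SOMA, AXON, BASAL, APICAL}


class SwcError(Exception):
    """Base class for morphology errors."""


class SwcStructureError(SwcError):
    """Topological defect: cycle, unordered parent reference, orphan point."""


class SwcValidationError(SwcError):
    """Semantic defect: unknown structure code, bad radius, multiple roots."""


class GraftError(SwcError):
    """A donor lacks the requested subtree class."""


@dataclass(frozen=True)
class SwcPoint:
    """One reconstruction sample point.

    Attributes
    ----------
    id : int
        Positive identifier, unique within a file.
    structure : int
        SWC structure code (1 soma, 2 axon, 3 basal, 4 apical).
    x, y, z : float
        Position in micrometres.
    radius : float
        Radius in micrometres; strictly positive.
    parent_id : int
        Identifier of the parent point, or ``-1`` for the root.
    """

    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _dist(a: SwcPoint, b: SwcPoint) -> float:
    return math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)


@dataclass(frozen=True)
class Section:
    """A maximal unbranched run of same-structure points.

    ``points`` lists the attachment point first (the parent of the first
    owned point; it may belong to a different section or be the root),
    followed by the owned points in root-to-tip order.
    """

    points: tuple[SwcPoint, ...]
    structure: int

    @property
    def owned(self) -> tuple[SwcPoint, ...]:
        """Points this section is responsible for (all but the attachment)."""
        return self.points[1:]

    @property
    def length(self) -> float:
        """Arc length in micrometres: sum of 3D inter-point distances."""
        return sum(
            _dist(a, b) for a, b in zip(self.points[:-1], self.points[1:])
        )

    @property
    def diameter(self) -> float:
        """Length-weighted mean diameter over the section, in micrometres.

        In SWC each point's radius describes the cable arriving at it, so
        each inter-point segment contributes the diameter of its *distal*
        endpoint, weighted by the segment length. The attachment point's
        radius (which may be a soma radius for stem sections) never enters.
        A zero-length section falls back to the plain mean over owned
        points.
        """
        total = 0.0
        wsum = 0.0
        for a, b in zip(self.points[:-1], self.points[1:]):
            ell = _dist(a, b)
            total += ell * 2.0 * b.radius
            wsum += ell
        if wsum == 0.0:
            return 2.0 * sum(p.radius for p in self.owned) / len(self.owned)
        return total / wsum

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class Morphology:
    """A validated neuronal reconstruction with its section partition.

    Construct with :meth:`from_points`, :func:`parse_swc`, or the surgery
    functions; direct construction skips validation.
    """

    points: tuple[SwcPoint, ...]
    sections: tuple[Section, ...]
    provenance: str = ""
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _by_id: dict[int, SwcPoint] = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------
    @classmethod
    def from_points(
        cls, points: list[SwcPoint], provenance: str = ""
    ) -> "Morphology":
        """Validate a point table and build the section partition.

        Raises
        ------
        SwcValidationError
            Unknown structure code, non-positive radius, duplicate or
            non-positive id, multiple roots, or no root.
        SwcStructureError
            A point whose ``parent_id >= id`` (the table must be
            topologically sorted, which also excludes cycles) or whose
            parent does not exist.
        """
        by_id: dict[int, SwcPoint] = {}
        roots = []
        for p in points:
            if p.id <= 0:
                raise SwcValidationError(f"non-positive id {p.id}")
            if p.id in by_id:
                raise SwcValidationError(f"duplicate id {p.id}")
            if p.structure not in _KNOWN_STRUCTURES:
                raise SwcValidationError(
                    f"unknown structure code {p.structure} at point id {p.id}"
                )
            if not (p.radius > 0):
                raise SwcValidationError(
                    f"non-positive radius at point id {p.id}"
                )
            if p.parent_id == -1:
                roots.append(p.id)
            elif p.parent_id >= p.id:
                raise SwcStructureError(
                    f"point id {p.id} references parent {p.parent_id} >= "
                    "its own id; table must be topologically sorted"
                )
            by_id[p.id] = p
        if not roots:
            raise SwcValidationError("no root point (parent_id == -1)")
        if len(roots) > 1:
            raise SwcValidationError(f"multiple roots: ids {roots}")
        children: dict[int, list[int]] = {p.id: [] for p in points}
        for p in points:
            if p.parent_id != -1:
                if p.parent_id not in by_id:
                    raise SwcStructureError(
                        f"point id {p.id} references missing parent "
                        f"{p.parent_id}"
                    )
                children[p.parent_id].append(p.id)
        sections = _build_sections(points, by_id, children)
        return cls(
            points=tuple(points),
            sections=tuple(sections),
            provenance=provenance,
            _children=children,
            _by_id=by_id,
        )

    # ------------------------------------------------------------------
    @property
    def root(self) -> SwcPoint:
        return next(p for p in self.points if p.parent_id == -1)

    def point(self, pid: int) -> SwcPoint:
        return self._by_id[pid]

    def children_of(self, pid: int) -> list[SwcPoint]:
        return [self._by_id[c] for c in self._children.get(pid, [])]

    @property
    def soma_points(self) -> tuple[SwcPoint, ...]:
        return tuple(p for p in self.points if p.structure == SOMA)

    def sections_of(self, structure: int) -> tuple[Section, ...]:
        """All sections of one structure class (e.g. ``BASAL``)."""
        return tuple(s for s in self.sections if s.structure == structure)

    def has_structure(self, structure: int) -> bool:
        return any(p.structure == structure for p in self.points)

    def stems(self, structure: int) -> tuple[SwcPoint, ...]:
        """Subtree roots of a class: points of that class whose parent is soma
        (or the root itself for somaless single-class files)."""
        out = []
        for p in self.points:
            if p.structure != structure:
                continue
            if p.parent_id == -1:
                out.append(p)
            else:
                par = self._by_id[p.parent_id]
                if par.structure != structure:
                    out.append(p)
        return tuple(out)

    # -- soma geometry --------------------------------------------------
    def soma_equivalent_cylinder(self) -> tuple[float, float]:
        """Reduce the soma to a cylinder of equal lateral surface area.

        NeuroMorpho files mix soma conventions. A single-point soma is a
        sphere of the given radius, mapped to a cylinder with ``L = D = 2r``
        (same area, 4*pi*r^2). A multi-point soma contributes its frustum
        lateral areas; the cylinder keeps the soma path length and matches
        the total area.

        Returns
        -------
        (length_um, diameter_um)
        """
        soma = self.soma_points
        if not soma:
            raise SwcValidationError("morphology has no soma points")
        if len(soma) == 1:
            r = soma[0].radius
            return 2.0 * r, 2.0 * r
        area = 0.0
        length = 0.0
        for sec in self.sections_of(SOMA):
            for a, b in zip(sec.points[:-1], sec.points[1:]):
                ell = _dist(a, b)
                length += ell
                area += math.pi * (a.radius + b.radius) * ell
        if length == 0.0:
            r = max(p.radius for p in soma)
            return 2.0 * r, 2.0 * r
        return length, area / (math.pi * length)

    def soma_centroid(self) -> np.ndarray:
        pts = self.soma_points or self.points
        return np.mean([[p.x, p.y, p.z] for p in pts], axis=0)


def _build_sections(points, by_id, children) -> list[Section]:
    """Partition non-root points into maximal unbranched same-structure runs."""
    sections: list[Section] = []
    # A point starts a section if its parent is the root, is a branch point,
    # or has a different structure code.
    for p in points:
        if p.parent_id == -1:
            continue
        par = by_id[p.parent_id]
        starts = (
            par.parent_id == -1
            or len(children[par.id]) > 1
            or par.structure != p.structure
        )
        if not starts:
            continue
        run = [par, p]
        cur = p
        while True:
            kids = children[cur.id]
            if len(kids) != 1:
                break
            nxt = by_id[kids[0]]
            if nxt.structure != cur.structure:
                break
            run.append(nxt)
            cur = nxt
        sections.append(Section(points=tuple(run), structure=p.structure))
    return sections


# ----------------------------------------------------------------------
# Parsing / writing
# ----------------------------------------------------------------------

def parse_swc_text(text: str, provenance: str = "") -> Morphology:
    """Parse SWC content from a string. See :func:`parse_swc`."""
    points: list[SwcPoint] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SwcValidationError(
                f"line {lineno}: expected 7 columns, got {len(cols)}"
            )
        try:
            pid = int(cols[0])
            structure = int(cols[1])
            x, y, z, radius = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SwcValidationError(f"line {lineno}: {exc}") from exc
        points.append(SwcPoint(pid, structure, x, y, z, radius, parent))
    if not points:
        raise SwcValidationError("no data lines in SWC input")
    return Morphology.from_points(points, provenance=provenance)


def parse_swc(path) -> Morphology:
    """Read and validate an SWC file.

    Parameters
    ----------
    path : str or pathlib.Path
        Standard 7-column SWC file; ``#`` lines are comments. Coordinates
        and radii are taken as micrometres; column 6 is the *radius*.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_swc_text(text, provenance=str(path))


def to_swc_text(m: Morphology, header: str | None = None) -> str:
    """Serialize to SWC text; coordinates and radii printed to 1e-6 um."""
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(h if h.startswith("#") else "# " + h)
    elif m.provenance:
        lines.append(f"# provenance: {m.provenance}")
    for p in m.points:
        lines.append(
            f"{p.id} {p.structure} {p.x:.6f} {p.y:.6f} {p.z:.6f} "
            f"{p.radius:.6f} {p.parent_id}"
        )
    return "\n".join(lines) + "\n"


def write_swc(m: Morphology, path, header: str | None = None) -> None:
    """Write an SWC file (see :func:`to_swc_text`)."""
    with open(path, "w") as fh:
        fh.write(to_swc_text(m, header=header))


# ----------------------------------------------------------------------
# Surgery
# ----------------------------------------------------------------------

def _renumber(points: list[SwcPoint], provenance: str) -> Morphology:
    """Renumber ids consecutively in the given (topological) order."""
    newid = {}
    out = []
    for i, p in enumerate(points, start=1):
        newid[p.id] = i
        parent = -1 if p.parent_id == -1 else newid[p.parent_id]
        out.append(replace(p, id=i, parent_id=parent))
    return Morphology.from_points(out, provenance=provenance)


def _collect_subtree(m: Morphology, root: SwcPoint) -> list[SwcPoint]:
    """Subtree points in topological (preorder) order, root first."""
    out = []
    stack = [root]
    while stack:
        p = stack.pop()
        out.append(p)
        stack.extend(reversed(m.children_of(p.id)))
    return out


def graft(
    soma_donor: Morphology,
    basal_donor: Morphology,
    apical_donor: Morphology,
) -> Morphology:
    """Assemble a chimeric cell: one donor's soma (and axon), another's basal
    trees, a third's apical trees.

    Each donor subtree is rigidly translated so that its root sits at the
    same offset from its new somatic attachment point as it had from its
    original one; all inter-point distances — including the stem's first
    segment — are therefore conserved exactly, and every per-tree
    morphometric of the output equals that of the corresponding donor. The
    attachment point is the soma point of ``soma_donor`` whose direction
    from the soma centroid best matches the subtree's original offset
    direction.

    Raises
    ------
    GraftError
        ``basal_donor`` has no basal points or ``apical_donor`` no apical
        points.
    """
    if not basal_donor.has_structure(BASAL):
        raise GraftError("basal donor has no basal (structure 3) points")
    if not apical_donor.has_structure(APICAL):
        raise GraftError("apical donor has no apical (structure 4) points")
    soma_pts = soma_donor.soma_points
    if not soma_pts:
        raise GraftError("soma donor has no soma (structure 1) points")

    out: list[SwcPoint] = []
    # soma and axon come from the soma donor, in original order
    keep = {SOMA, AXON}
    kept_ids = set()
    for p in soma_donor.points:
        if p.structure in keep:
            # axon must attach within the kept set
            if p.parent_id == -1 or p.parent_id in kept_ids:
                out.append(p)
                kept_ids.add(p.id)
    target_centroid = soma_donor.soma_centroid()
    soma_xyz = np.array([[p.x, p.y, p.z] for p in soma_pts])

    next_id = max(p.id for p in out) + 1

    def attach_trees(donor: Morphology, structure: int, next_id: int) -> int:
        donor_centroid = donor.soma_centroid()
        for stem in donor.stems(structure):
            if stem.parent_id == -1:
                old_parent_xyz = donor_centroid
            else:
                old_parent_xyz = donor.point(stem.parent_id).xyz
            offset = stem.xyz - donor_centroid
            norm = np.linalg.norm(offset)
            if norm == 0 or len(soma_pts) == 1:
                target = soma_pts[0]
            else:
                dirs = soma_xyz - target_centroid
                scores = dirs @ (offset / norm)
                target = soma_pts[int(np.argmax(scores))]
            delta = target.xyz - old_parent_xyz
            sub = _collect_subtree(donor, stem)
            idmap = {}
            for p in sub:
                idmap[p.id] = next_id
                parent = (
                    target.id if p.id == stem.id else idmap[p.parent_id]
                )
                out.append(
                    replace(
                        p,
                        id=next_id,
                        parent_id=parent,
                        x=p.x + delta[0],
                        y=p.y + delta[1],
                        z=p.z + delta[2],
                    )
                )
                next_id += 1
        return next_id

    next_id = attach_trees(basal_donor, BASAL, next_id)
    attach_trees(apical_donor, APICAL, next_id)
    prov = (
        f"graft(soma={soma_donor.provenance or '?'}, "
        f"basal={basal_donor.provenance or '?'}, "
        f"apical={apical_donor.provenance or '?'})"
    )
    return _renumber(out, provenance=prov)


def split_section(m: Morphology, section: Section, fraction: float) -> Morphology:
    """Insert a point at an arc-length fraction of a section.

    Geometry-preserving: the new point lies on the existing polyline and
    takes the radius of the distal endpoint of the split segment (the
    radius that segment's cable already carried), so total length is
    unchanged exactly and volume/MEP are unchanged for sections of uniform
    owned radius (the shipped generators produce only those; within-section
    taper makes any section-level cylinder reduction split-dependent).

    Parameters
    ----------
    fraction : float
        Strictly between 0 and 1.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    total = section.length
    if total == 0.0:
        raise SwcValidationError("cannot split a zero-length section")
    target = fraction * total
    acc = 0.0
    for a, b in zip(section.points[:-1], section.points[1:]):
        ell = _dist(a, b)
        if acc + ell >= target and ell > 0:
            t = (target - acc) / ell
            break
        acc += ell
    else:  # pragma: no cover - fraction<1 guarantees a segment is found
        raise AssertionError("split position beyond section end")
    new_pt = SwcPoint(
        id=0,  # placeholder; renumbered below
        structure=b.structure,
        x=a.x + t * (b.x - a.x),
        y=a.y + t * (b.y - a.y),
        z=a.z + t * (b.z - a.z),
        radius=b.radius,
        parent_id=a.id,
    )
    # Rebuild the point list with the new point inserted before b, b's
    # parent rewired to it. Use a temporary id above all existing ones.
    tmp_id = max(p.id for p in m.points) + 1
    new_pt = replace(new_pt, id=tmp_id)
    out = []
    new_index = None
    for p in m.points:
        if p.id == b.id:
            new_index = len(out)
            out.append(new_pt)
            out.append(replace(p, parent_id=tmp_id))
        else:
            out.append(p)
    m2 = _renumber(out, provenance=m.provenance)
    # _renumber rebuilds maximal unbranched runs, which would absorb the
    # degree-1 split point; refine the partition so the split is visible
    # as two sections.
    split_id = new_index + 1  # renumbered ids follow list order
    refined: list[Section] = []
    for sec in m2.sections:
        interior = [p.id for p in sec.points[1:-1]]
        if split_id in interior:
            j = [p.id for p in sec.points].index(split_id)
            refined.append(Section(points=sec.points[: j + 1],
                                   structure=sec.structure))
            refined.append(Section(points=sec.points[j:],
                                   structure=sec.structure))
        else:
            refined.append(sec)
    return replace(m2, sections=tuple(refined))
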