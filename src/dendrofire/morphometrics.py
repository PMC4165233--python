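"""Per-tree morphometric and electrotonic features of dendritic trees.

Five features characterise a basal or apical dendritic tree:

* **median diameter** — median of per-section length-weighted mean
  diameters (um);
* **total length** — sum of section arc lengths (um);
* **volume** — sum over sections of cylinder volumes,
  ``V = sum_i pi * L_i * (D_i / 2)**2`` (um^3);
* **branch number** — the count of topological segments (stem->fork,
  fork->fork, fork->tip); for a strictly binary tree with ``T`` tips this is
  ``2T - 1`` per stem;
* **MEP** — Mean Electrotonic Path length: each section's length is
  normalised by its electrotonic length constant
  ``lambda_i = sqrt(b_i * r_m / (2 * r_a))`` (``b_i`` the section radius),
  giving a dimensionless ``Lambda_i = l_i / lambda_i``; the tree's MEP is
  the mean, over its terminal sections, of the summed ``Lambda_i`` along
  each tip-to-stem-root path. Paths stop at the stem root (the somatic
  attachment), not inside the soma.

``r_m`` and ``r_a`` are held constant for the MEP (defaults: the somatic
membrane resistance 30 kOhm cm^2 and axial resistivity 210 Ohm cm), distinct
from any position-dependent membrane resistance used in simulation.

A "tree" here is the full set of same-class sections of a morphology — a
basal tree with several stems is one tree whose tips span all stems.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .morphology import Morphology, Section

__all__ = [
    "ElectrotonicConstants",
    "FeatureVector",
    "total_length",
    "volume",
    "median_diameter",
    "branch_number",
    "mep",
    "feature_vector",
]

_UM_PER_CM = 1e4


@dataclass(frozen=True)
class ElectrotonicConstants:
    """Constants of the electrotonic length normalisation.

    Attributes
    ----------
    r_m : float
        Specific membrane resistance, Ohm cm^2 (default 30 000 = 30 kOhm cm^2).
    r_a : float
        Intracellular (axial) resistivity, Ohm cm (default 210).
    """

    r_m: float = 30_000.0
    r_a: float = 210.0

    def __post_init__(self):
        if self.r_m <= 0 or self.r_a <= 0:
            raise ValueError("r_m and r_a must be positive")

    def length_constant_um(self, radius_um: float) -> float:
        """lambda = sqrt(b * r_m / (2 * r_a)) for a cylinder of radius b,
        returned in micrometres."""
        if radius_um <= 0:
            raise ValueError("radius must be positive")
        lam_cm = math.sqrt(radius_um / _UM_PER_CM * self.r_m / (2.0 * self.r_a))
        return lam_cm * _UM_PER_CM


@dataclass(frozen=True)
class FeatureVector:
    """The five per-tree features, in the field's usual units."""

    median_diameter: float  # um
    total_length: float  # um
    volume: float  # um^3
    branch_number: int
    mep: float  # dimensionless

    def as_dict(self) -> dict:
        return {
            "median_diameter_um": self.median_diameter,
            "total_length_um": self.total_length,
            "volume_um3": self.volume,
            "branch_number": self.branch_number,
            "mep": self.mep,
        }


def _tree_sections(tree, structure: int | None) -> tuple[Section, ...]:
    if isinstance(tree, Morphology):
        if structure is None:
            raise ValueError(
                "pass structure=BASAL or APICAL when giving a Morphology"
            )
        return tree.sections_of(structure)
    return tuple(tree)


def total_length(tree, structure: int | None = None) -> float:
    """Total arc length of a tree in micrometres (sum of section lengths)."""
    secs = _tree_sections(tree, structure)
    if not secs:
        warnings.warn("empty subtree: total_length = 0", stacklevel=2)
        return 0.0
    return float(sum(s.length for s in secs))


def volume(tree, structure: int | None = None) -> float:
    """Tree volume in um^3, summing per-section cylinder volumes."""
    secs = _tree_sections(tree, structure)
    return float(
        sum(math.pi * s.length * (s.diameter / 2.0) ** 2 for s in secs)
    )


def median_diameter(tree, structure: int | None = None) -> float:
    """Median of per-section diameters (um), one value per section.

    An even section count takes the midpoint of the two central values.
    """
    secs = _tree_sections(tree, structure)
    if not secs:
        raise ValueError("median_diameter is undefined for an empty tree")
    return float(np.median([s.diameter for s in secs]))


def branch_number(tree, structure: int | None = None) -> int:
    """Number of topological segments of the tree (stem->fork, fork->fork,
    fork->tip); for a strictly binary stem with ``T`` tips this is
    ``2T - 1``.

    A freshly parsed partition has exactly one section per topological
    segment, but surgery may refine a segment into several collinear
    sections; only sections ending at a fork or a tip are counted, so the
    branch number is invariant under such refinement.
    """
    secs = _tree_sections(tree, structure)
    if not secs:
        return 0
    child_count = [0] * len(secs)
    by_tail = {s.points[-1].id: i for i, s in enumerate(secs)}
    for s in secs:
        pi = by_tail.get(s.points[0].id)
        if pi is not None:
            child_count[pi] += 1
    return sum(1 for c in child_count if c != 1)


def _section_topology(secs: tuple[Section, ...]):
    """Map each section to its parent section within the tree (or None) and
    flag terminals. Sections connect head-to-tail: a child's attachment
    point is its parent section's last point."""
    by_tail = {s.points[-1].id: i for i, s in enumerate(secs)}
    parent = []
    has_child = [False] * len(secs)
    for s in secs:
        head = s.points[0].id
        pi = by_tail.get(head)
        parent.append(pi)
        if pi is not None:
            has_child[pi] = True
    terminal = [not c for c in has_child]
    return parent, terminal


def mep(
    tree,
    consts: ElectrotonicConstants | None = None,
    structure: int | None = None,
) -> float:
    """Mean Electrotonic Path length of a tree (dimensionless).

    For each terminal section ``j``, ``P_j`` sums ``l_i / lambda_i`` over
    the sections on the path from that tip to the stem root; the MEP is the
    mean of ``P_j`` over all terminals. An empty or zero-length tree has
    MEP 0; a zero section radius is an error.
    """
    consts = consts or ElectrotonicConstants()
    secs = _tree_sections(tree, structure)
    if not secs:
        return 0.0
    lam = []
    for s in secs:
        r = s.radius
        if r <= 0:
            raise ValueError("section with non-positive radius")
        lam.append(consts.length_constant_um(r))
    big_lambda = [s.length / l for s, l in zip(secs, lam)]
    parent, terminal = _section_topology(secs)
    if not any(terminal):  # pragma: no cover - a tree always has tips
        return 0.0
    # accumulate path sums root-to-tip; sections are in topological order
    path = [0.0] * len(secs)
    for i in range(len(secs)):
        p = parent[i]
        path[i] = big_lambda[i] + (path[p] if p is not None else 0.0)
    tips = [path[i] for i in range(len(secs)) if terminal[i]]
    return float(np.mean(tips))


def feature_table(items, structure: int, consts=None):
    """Tabulate features for named trees.

    Parameters
    ----------
    items : iterable of (name, Morphology)
    structure : int
        Tree class to measure (``BASAL`` or ``APICAL``).

    Returns
    -------
    pandas.DataFrame
        Columns: file, tree, median_diameter_um, total_length_um,
        volume_um3, branch_number, mep.
    """
    import pandas as pd

    from .morphology import APICAL, BASAL

    tree_name = {BASAL: "basal", APICAL: "apical"}.get(structure, str(structure))
    rows = []
    for name, m in items:
        fv = feature_vector(m, consts=consts, structure=structure)
        rows.append({"file": name, "tree": tree_name, **fv.as_dict()})
    return pd.DataFrame(rows)


def feature_vector(
    tree,
    consts: ElectrotonicConstants | None = None,
    structure: int | None = None,
) -> FeatureVector:
    """Compute all five features of one tree."""
    secs = _tree_sections(tree, structure)
    if not secs:
        raise ValueError("cannot compute features of an empty tree")
    return FeatureVector(
        median_diameter=median_diameter(secs),
        total_length=total_length(secs),
        volume=volume(secs),
        branch_number=branch_number(secs),
        mep=mep(secs, consts),
    )
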