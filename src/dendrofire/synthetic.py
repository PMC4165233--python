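"""Synthetic dendritic morphologies and two-class populations.

Real reconstructions (e.g. the NeuroMorpho layer V PFC archive) are optional
inputs to this package; every analysis stage is exercised instead on
generated SWC trees with controllable size and topology. Trees are strictly
binary: stems leave the soma, sections are straight runs of constant radius,
and diameters follow a fixed taper ratio at each bifurcation. Randomness
comes from :func:`numpy.random.default_rng` (PCG64), so a seed reproduces a
tree bit-identically on any platform.

Two-class populations emulate the empirical contrast between basal trees of
regular-spiking and bursting pyramidal cells: the RS-like class is longer
and bushier (more branches) than the IB-like class, with only slightly
larger diameters. Class targets default to realistic layer V basal-tree
scales (median total length ~1.7 mm vs ~1.15 mm, branch numbers ~15 vs ~10,
median diameters just under 1 um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import (
    APICAL,
    BASAL,
    SOMA,
    Morphology,
    SwcPoint,
)
from .morphometrics import ElectrotonicConstants, total_length

__all__ = [
    "TreeRecipe",
    "ClassSpec",
    "PopulationRecipe",
    "generate_tree",
    "generate_population",
    "fixture_suite",
    "control_cell",
]


@dataclass(frozen=True)
class TreeRecipe:
    """Parameters of one synthetic dendritic tree.

    Attributes
    ----------
    n_stems : int
        Stems leaving the soma (>= 1).
    bifurcation_prob : float
        Probability that a section ends in a bifurcation rather than a tip
        (ignored when ``n_branches`` is given).
    segment_length_mean, segment_length_sd : float
        Per-section length distribution, um (normal, clipped to >= 1 um).
    stem_diameter : float
        Diameter of stem sections, um.
    taper : float
        Child/parent diameter ratio at each bifurcation, in (0, 1].
    max_depth : int
        Maximum bifurcation depth.
    diameter_jitter : float
        Lognormal sigma of per-section diameter fluctuation around the
        taper rule (0 = deterministic taper). Section-level noise averages
        out in aggregate quantities (area, volume) but keeps the median
        section diameter a noisy summary, as in real reconstructions.
    n_branches : int or None
        When set, grow to exactly this many sections (must equal
        ``n_stems + 2k`` for integer k >= 0); bifurcation sites are chosen
        uniformly among open tips.
    seed : int
        Generator seed; same seed, same tree.
    """

    n_stems: int = 3
    bifurcation_prob: float = 0.5
    segment_length_mean: float = 80.0
    segment_length_sd: float = 20.0
    stem_diameter: float = 1.2
    taper: float = 0.85
    max_depth: int = 6
    n_branches: int | None = None
    diameter_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1 (zero-segment recipe)")
        if not (0.0 < self.taper <= 1.0):
            raise ValueError("taper must be in (0, 1]")
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be positive")
        if self.n_branches is not None:
            extra = self.n_branches - self.n_stems
            if extra < 0 or extra % 2:
                raise ValueError(
                    "n_branches must be n_stems + 2k for some k >= 0"
                )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _child_dir(rng, parent_dir: np.ndarray, jitter: float = 0.8) -> np.ndarray:
    return _unit(parent_dir + jitter * rng.standard_normal(3))


def generate_tree(
    recipe: TreeRecipe,
    structure: int = BASAL,
    soma_radius: float = 8.0,
) -> Morphology:
    """Grow one strictly-binary synthetic tree on a single-point soma.

    Sections are straight two-point runs of constant radius; the soma is the
    SWC one-point sphere convention. Deterministic for a fixed recipe.
    """
    rng = np.random.default_rng(recipe.seed)
    points = [SwcPoint(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)]
    next_id = 2

    def sample_len() -> float:
        return float(
            max(1.0, rng.normal(recipe.segment_length_mean,
                                recipe.segment_length_sd))
        )

    def add_point(parent: SwcPoint, direction, length, radius) -> SwcPoint:
        nonlocal next_id
        pos = parent.xyz + direction * length
        p = SwcPoint(next_id, structure, float(pos[0]), float(pos[1]),
                     float(pos[2]), radius, parent.id)
        points.append(p)
        next_id += 1
        return p

    soma = points[0]
    # open tips: (tip point, direction, depth, diameter)
    tips: list[tuple[SwcPoint, np.ndarray, int, float]] = []
    n_sections = 0
    for _ in range(recipe.n_stems):
        direction = _unit(rng.standard_normal(3))
        tip = add_point(soma, direction, soma_radius + sample_len(),
                        recipe.stem_diameter / 2.0)
        tips.append((tip, direction, 0, recipe.stem_diameter))
        n_sections += 1

    def child_diam(diam: float) -> float:
        d = diam * recipe.taper
        if recipe.diameter_jitter > 0:
            d *= math.exp(rng.normal(0.0, recipe.diameter_jitter))
        return max(d, 0.2)

    if recipe.n_branches is not None:
        # Grow balanced: bifurcate a (random) shallowest open tip, as real
        # basal arbors are nearly depth-balanced. This keeps the tree's
        # electrotonic extent a tight function of its total length.
        n_bif = (recipe.n_branches - recipe.n_stems) // 2
        for _ in range(n_bif):
            dmin = min(t[2] for t in tips)
            shallow = [k for k, t in enumerate(tips) if t[2] == dmin]
            i = shallow[int(rng.integers(len(shallow)))]
            tip, direction, depth, diam = tips.pop(i)
            for _ in range(2):
                cdir = _child_dir(rng, direction)
                cd = child_diam(diam)
                ctip = add_point(tip, cdir, sample_len(), cd / 2.0)
                tips.append((ctip, cdir, depth + 1, cd))
            n_sections += 2
    else:
        frontier = tips
        tips = []
        while frontier:
            tip, direction, depth, diam = frontier.pop()
            branch = (
                depth < recipe.max_depth
                and rng.random() < recipe.bifurcation_prob
            )
            if branch:
                for _ in range(2):
                    cdir = _child_dir(rng, direction)
                    cd = child_diam(diam)
                    ctip = add_point(tip, cdir, sample_len(), cd / 2.0)
                    frontier.append((ctip, cdir, depth + 1, cd))
                n_sections += 2
            else:
                tips.append((tip, direction, depth, diam))

    if n_sections == 0:  # pragma: no cover - n_stems >= 1 prevents this
        raise ValueError("recipe produced zero segments")
    return Morphology.from_points(
        points, provenance=f"synthetic(seed={recipe.seed})"
    )


# ----------------------------------------------------------------------
# Two-class populations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """Feature targets for one population class (medians, not assertions)."""

    label: str
    total_length_um: float
    branch_number: int
    stem_diameter_um: float
    n_stems: int = 4
    # Tree-to-tree spreads (log scale). Total length: the class-median
    # difference is about two within-class standard deviations. Diameter
    # uses the same absolute spread, so its much smaller median difference
    # makes it a weak discriminator — mirroring the empirical pattern where
    # length separates firing classes far more strongly than diameter.
    length_cv: float = 0.20
    diameter_cv: float = 0.06
    branch_sd: float = 3.0
    taper: float = 0.8
    diameter_jitter: float = 0.10


# Defaults follow the empirical direction for layer V PFC basal trees:
# RS-like trees are longer and bushier than IB-like trees, with a slightly
# larger stem calibre (the distal taper brings per-section medians down to
# about a micrometre). The input-class diameter gap is kept modest: the
# empirical diameter contrast between firing groups is largely an outcome
# of the mechanism itself (thicker trees load the soma more and fire RS),
# so the realized RS/IB-group medians separate further than the input
# classes do.
RS_LIKE = ClassSpec("RS", total_length_um=1739.0, branch_number=16,
                    stem_diameter_um=1.62)
IB_LIKE = ClassSpec("IB", total_length_um=1152.0, branch_number=10,
                    stem_diameter_um=1.54)


@dataclass(frozen=True)
class PopulationRecipe:
    """Two-class synthetic population of basal (or apical) trees."""

    n_per_class: int = 25
    classes: tuple[ClassSpec, ClassSpec] = (RS_LIKE, IB_LIKE)
    structure: int = BASAL
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1 (empty population)")
        for c in self.classes:
            if c.total_length_um <= 0 or c.branch_number < c.n_stems:
                raise ValueError(f"infeasible class targets for {c.label!r}")


def generate_population(
    recipe: PopulationRecipe,
) -> tuple[list[Morphology], list[str]]:
    """Generate a labelled two-class population of synthetic trees.

    Per tree, a branch count is drawn around the class target (kept at the
    same parity as ``n_stems`` so strict binarity holds) and the mean
    section length is set to hit the class total-length target on average.
    The realized class medians of total length must come out in the same
    order as the recipe targets; a violation raises ``ValueError`` (it
    indicates targets too close for the requested sample size).

    Returns
    -------
    (morphologies, labels)
        Labels are the ``ClassSpec.label`` strings, ground truth for
        recovery tests.
    """
    rng = np.random.default_rng(recipe.seed)
    trees: list[Morphology] = []
    labels: list[str] = []
    for cls in recipe.classes:
        for _ in range(recipe.n_per_class):
            # One lognormal size factor scales total length, stem count and
            # branch count together — the allometry of real dendritic
            # populations, where bigger arbors are bushier (more primary
            # dendrites and more branches) rather than deeper. Keeping
            # large trees shallow matters electrically: membrane beyond
            # about one length constant barely loads the soma, so depth-
            # grown length would be electrotonically invisible.
            size = math.exp(rng.normal(0.0, cls.length_cv))
            tgt_len = cls.total_length_um * size
            n_stems = int(np.clip(round(cls.n_stems * size), 3, 8))
            extra = max(0, cls.branch_number - cls.n_stems)
            k = max(0, int(round(
                extra * size / 2.0 + rng.normal(0.0, cls.branch_sd / 4.0)
            )))
            n_branches = n_stems + 2 * k
            seg_mean = max(5.0, tgt_len / n_branches)
            diam = cls.stem_diameter_um * math.exp(
                rng.normal(0.0, cls.diameter_cv)
            )
            sub = TreeRecipe(
                n_stems=n_stems,
                segment_length_mean=seg_mean,
                segment_length_sd=0.2 * seg_mean,
                stem_diameter=diam,
                taper=cls.taper,
                n_branches=n_branches,
                diameter_jitter=cls.diameter_jitter,
                seed=int(rng.integers(2**31 - 1)),
            )
            trees.append(generate_tree(sub, structure=recipe.structure))
            labels.append(cls.label)
    # realized ordering check
    med = {}
    for cls in recipe.classes:
        vals = [
            total_length(t, structure=recipe.structure)
            for t, lab in zip(trees, labels)
            if lab == cls.label
        ]
        med[cls.label] = float(np.median(vals))
    a, b = recipe.classes
    want = a.total_length_um - b.total_length_um
    got = med[a.label] - med[b.label]
    if want * got < 0:
        raise ValueError(
            "realized class-median total_length ordering contradicts the "
            f"recipe targets (realized medians: {med})"
        )
    return trees, labels


# ----------------------------------------------------------------------
# Named fixtures
# ----------------------------------------------------------------------

def _straight_tree(
    seg_lengths_radii: list[tuple[float, float, int]],
    structure: int,
    soma_radius: float = 8.0,
) -> Morphology:
    """Build a tree from (length_um, radius_um, parent_section_index) specs;
    parent index -1 attaches the section to the soma. Sections point in
    distinct fixed directions so geometry is non-degenerate."""
    dirs = [
        np.array(d, dtype=float)
        for d in [(1, 0, 0), (0.3, 1, 0), (0.3, -1, 0), (0, 0.3, 1),
                  (0, 0.3, -1), (-1, 0.3, 0), (1, 1, 1), (-1, 1, -1)]
    ]
    points = [SwcPoint(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)]
    sec_tail = []
    nid = 2
    for i, (length, radius, parent_sec) in enumerate(seg_lengths_radii):
        parent = points[0] if parent_sec == -1 else sec_tail[parent_sec]
        d = _unit(dirs[i % len(dirs)])
        pos = parent.xyz + d * length
        p = SwcPoint(nid, structure, *map(float, pos), radius, parent.id)
        points.append(p)
        sec_tail.append(p)
        nid += 1
    return Morphology.from_points(points, provenance="fixture")


def fixture_suite(
    consts: ElectrotonicConstants | None = None,
) -> dict[str, Morphology]:
    """Small named morphologies used throughout tests and examples.

    Returns a dict with:

    * ``soma_only`` — one-point spherical soma;
    * ``unit_lambda_stick`` — soma plus a single basal cable of radius
      1 um whose length equals one electrotonic length constant, so its
      MEP is exactly 1;
    * ``y_tree`` — a basal stem of 0.2 lambda with two identical 0.3 lambda
      children (MEP 0.5, branch number 3);
    * ``mini_basal`` — a three-stem basal cell, one stem bifurcating;
    * ``complex_apical`` / ``simple_apical`` — a large bushy and a small
      sparse apical tree (high vs low total length and branch number).
    """
    consts = consts or ElectrotonicConstants()
    lam1 = consts.length_constant_um(1.0)  # ~845.2 um for the defaults
    out: dict[str, Morphology] = {}
    out["soma_only"] = Morphology.from_points(
        [SwcPoint(1, SOMA, 0.0, 0.0, 0.0, 8.0, -1)], provenance="fixture"
    )
    out["unit_lambda_stick"] = _straight_tree(
        [(lam1, 1.0, -1)], structure=BASAL
    )
    out["y_tree"] = _straight_tree(
        [(0.2 * lam1, 1.0, -1), (0.3 * lam1, 1.0, 0), (0.3 * lam1, 1.0, 0)],
        structure=BASAL,
    )
    out["mini_basal"] = _straight_tree(
        [
            (120.0, 0.6, -1),
            (100.0, 0.5, -1),
            (90.0, 0.5, -1),
            (80.0, 0.45, 0),
            (70.0, 0.45, 0),
        ],
        structure=BASAL,
    )
    out["complex_apical"] = generate_tree(
        TreeRecipe(
            n_stems=1,
            segment_length_mean=160.0,
            segment_length_sd=30.0,
            stem_diameter=2.2,
            taper=0.9,
            n_branches=15,
            seed=1001,
        ),
        structure=APICAL,
    )
    out["simple_apical"] = generate_tree(
        TreeRecipe(
            n_stems=1,
            segment_length_mean=180.0,
            segment_length_sd=30.0,
            stem_diameter=1.8,
            taper=0.9,
            n_branches=3,
            seed=1002,
        ),
        structure=APICAL,
    )
    out["mid_apical"] = generate_tree(
        TreeRecipe(
            n_stems=1,
            segment_length_mean=150.0,
            segment_length_sd=25.0,
            stem_diameter=2.0,
            taper=0.9,
            n_branches=7,
            seed=1003,
        ),
        structure=APICAL,
    )
    return out


def basal_ladder(
    lengths_um: tuple[float, ...] = (700.0, 1050.0, 1400.0, 1750.0, 2400.0),
    n_stems: int = 4,
    n_branches: int = 10,
    stem_diameter: float = 1.6,
    taper: float = 0.8,
    seed: int = 7,
) -> list[Morphology]:
    """A nested load ladder: one branching topology scaled in total length.

    Every rung uses the same seed, so the random draws (directions,
    normalised segment lengths, bifurcation sites) are identical and the
    rungs differ only by a uniform scaling of section lengths — a clean
    morphological load ladder for excitability experiments.
    """
    out = []
    for L in lengths_um:
        rec = TreeRecipe(
            n_stems=n_stems,
            n_branches=n_branches,
            segment_length_mean=L / n_branches,
            segment_length_sd=0.15 * L / n_branches,
            stem_diameter=stem_diameter,
            taper=taper,
            seed=seed,
        )
        out.append(generate_tree(rec, structure=BASAL))
    return out


def control_cell(consts: ElectrotonicConstants | None = None) -> Morphology:
    """The reference cell for current normalisation: the fixture soma with a
    mid-sized (~1.4 mm) basal tree and the simple apical tree grafted on."""
    from .morphology import graft

    fx = fixture_suite(consts)
    basal = basal_ladder(lengths_um=(1400.0,), seed=999)[0]
    return graft(fx["mini_basal"], basal, fx["simple_apical"])
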