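"""Population pipeline: simulation grids, majority-vote profiles, feature
statistics and single-feature Bayes classification.

The central experiment crosses a set of basal trees with a set of apical
trees on a fixed control soma: every (basal, apical) pair is grafted,
simulated under the normalized somatic step, and labelled RS / IB / Q. Each
basal tree then receives a majority-vote *profile*: RS if strictly more
than half of its row's model cells fired RS (quiescent cells count in the
denominator), IB otherwise.

Morphometric features are compared between firing groups with the
Mann-Whitney U test (exact enumeration for small tie-free samples, the
tie-corrected normal approximation otherwise) and used one at a time in a
Gaussian naive Bayes classifier evaluated with class balancing, an 80/20
train/test split per class, and 10 seeded repeats; sensitivity,
specificity and accuracy are reported as means over the 10 test sets, with
IB as the positive class.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biophysics import build_cell_spec
from .morphology import Morphology, graft
from .protocols import FiringLabel, firing_assay, measure_input_resistance
from .simulator import discretize

__all__ = [
    "GridResult",
    "ClassifierReport",
    "run_grid",
    "basal_profile",
    "mann_whitney",
    "bayes_train",
    "bayes_predict",
    "bayes_evaluate",
    "feature_correlation",
]

POSITIVE_CLASS = "IB"  # convention for sensitivity


# ----------------------------------------------------------------------
# Simulation grid
# ----------------------------------------------------------------------

@dataclass
class GridResult:
    """Labels for every (basal, apical) combination.

    ``labels[i][j]`` is the :class:`FiringLabel` of basal ``i`` with apical
    ``j``, or ``None`` where the simulation failed (the error message is in
    ``failures[(i, j)]``).
    """

    labels: list  # list[list[FiringLabel | None]]
    failures: dict = field(default_factory=dict)
    rin_control: float | None = None

    @property
    def n_basal(self) -> int:
        return len(self.labels)

    @property
    def n_apical(self) -> int:
        return len(self.labels[0]) if self.labels else 0

    def category_matrix(self) -> list:
        return [
            [lab.category if lab is not None else None for lab in row]
            for row in self.labels
        ]

    def counts(self) -> dict:
        out = {"RS": 0, "IB": 0, "Q": 0, "failed": 0}
        for row in self.labels:
            for lab in row:
                if lab is None:
                    out["failed"] += 1
                else:
                    out[lab.category] += 1
        return out

    def basal_profiles(self) -> list:
        """Majority-vote RS/IB profile per basal tree (from the matrix)."""
        return [basal_profile(row) for row in self.category_matrix()]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, row in enumerate(self.labels):
            for j, lab in enumerate(row):
                if lab is None:
                    rows.append((i, j, "FAILED", np.nan, np.nan, np.nan))
                else:
                    rows.append(
                        (i, j, lab.category,
                         np.nan if lab.first_isi is None else lab.first_isi,
                         lab.rin, lab.injected_current)
                    )
        return pd.DataFrame(
            rows,
            columns=["basal_id", "apical_id", "category", "first_isi_ms",
                     "rin_mohm", "injected_na"],
        )


def run_grid(
    basal_set: list[Morphology],
    apical_set: list[Morphology],
    soma: Morphology,
    basal_mode: str = "uniform",
    control: Morphology | None = None,
    rin_control: float | None = None,
    dt: float = 0.025,
    max_seg_length: float = 20.0,
    normalization: str = "as-worded",
    stim_dur_ms: float = 1000.0,
    settle_ms: float = 200.0,
) -> GridResult:
    """Simulate every basal x apical combination on the control soma.

    The control input resistance is computed once — from ``control`` if
    given, else passed directly as ``rin_control``. Per-cell simulation
    failures are recorded, not fatal. Deterministic given inputs.
    """
    if rin_control is None:
        if control is None:
            raise ValueError("provide either control morphology or "
                             "rin_control")
        gc = discretize(
            build_cell_spec(control, basal_mode=basal_mode), max_seg_length
        )
        rin_control = measure_input_resistance(gc, settle_ms=settle_ms)
    labels: list[list[FiringLabel | None]] = []
    failures: dict = {}
    for i, basal in enumerate(basal_set):
        row: list[FiringLabel | None] = []
        for j, apical in enumerate(apical_set):
            try:
                cell = graft(soma, basal, apical)
                g = discretize(
                    build_cell_spec(cell, basal_mode=basal_mode),
                    max_seg_length,
                )
                row.append(
                    firing_assay(
                        g, rin_control, dt=dt, stim_dur_ms=stim_dur_ms,
                        settle_ms=settle_ms, normalization=normalization,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - isolate per cell
                row.append(None)
                failures[(i, j)] = str(exc)
        labels.append(row)
    return GridResult(labels=labels, failures=failures,
                      rin_control=rin_control)


def basal_profile(row) -> str:
    """Majority-vote profile of one basal tree over its apical row.

    RS only if *strictly more than half* of the row's cells are RS;
    quiescent (and failed) cells count in the denominator. An empty row is
    an error.
    """
    cats = list(row)
    if not cats:
        raise ValueError("cannot profile an empty row")
    n_rs = sum(1 for c in cats if c == "RS")
    return "RS" if n_rs > len(cats) / 2 else "IB"


# ----------------------------------------------------------------------
# Mann-Whitney U
# ----------------------------------------------------------------------

def _mw_exact_p(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Two-sided exact p by full enumeration of rank assignments
    (tie-free samples)."""
    n, m = len(x), len(y)
    pooled = np.sort(np.concatenate([x, y]))
    ranks = np.arange(1, n + m + 1)
    total = math.comb(n + m, n)
    u_obs = min(u1, n * m - u1)
    count = 0
    base = n * (n + 1) / 2
    for subset in itertools.combinations(range(n + m), n):
        u = sum(ranks[list(subset)]) - base
        if min(u, n * m - u) <= u_obs:
            count += 1
    del pooled
    return min(1.0, count / total)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` with ``U`` the statistic of ``x``. For tie-free
    samples with ``min(n, m) <= 8`` the p-value is computed by exhaustive
    enumeration of all rank assignments; otherwise the tie-corrected normal
    approximation is used. Samples whose pooled values are all identical
    yield ``p = 1`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n, m = x.size, y.size
    # U1 from rank sums (midranks under ties)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate samples: all pooled values identical",
                      stacklevel=2)
        return n * m / 2.0, 1.0
    ranks = sps.rankdata(pooled)
    u1 = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and min(n, m) <= 8:
        return u1, _mw_exact_p(x, y, u1)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return u1, float(res.pvalue)


# ----------------------------------------------------------------------
# Single-feature Bayes classifier
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BayesModel:
    """Class-conditional 1-D densities with equal priors."""

    classes: tuple[str, str]
    density: str  # 'gaussian' or 'kde'
    params: dict  # class -> (mean, std) or gaussian_kde

    def log_like(self, cls: str, x: float) -> float:
        if self.density == "gaussian":
            mu, sd = self.params[cls]
            return float(sps.norm.logpdf(x, mu, sd))
        return float(np.log(np.maximum(self.params[cls](x), 1e-300))[0])


def bayes_train(
    values, labels, density: str = "gaussian"
) -> BayesModel:
    """Fit one-dimensional class-conditional densities (one per class)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    params = {}
    for cls in classes:
        vals = values[labels == cls]
        if vals.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 training points")
        if density == "gaussian":
            sd = float(np.std(vals, ddof=1))
            params[cls] = (float(np.mean(vals)), max(sd, 1e-12))
        elif density == "kde":
            params[cls] = sps.gaussian_kde(vals)
        else:
            raise ValueError(f"unknown density {density!r}")
    return BayesModel(classes=classes, density=density, params=params)


def bayes_predict(model: BayesModel, value: float) -> str:
    """Maximum-posterior class under equal priors; posterior ties go to the
    positive (IB) class when present, else to the first class."""
    a, b = model.classes
    la, lb = model.log_like(a, value), model.log_like(b, value)
    if la == lb:
        return POSITIVE_CLASS if POSITIVE_CLASS in model.classes else a
    return a if la > lb else b


@dataclass(frozen=True)
class ClassifierReport:
    """Balanced, repeated hold-out evaluation of a single-feature
    classifier. Reported metrics are means over the repeats' test sets."""

    feature: str
    sensitivity: float
    specificity: float
    accuracy: float
    per_repeat: pd.DataFrame
    n_per_class: int
    seeds: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_per_class": self.n_per_class,
            "n_repeats": len(self.per_repeat),
            "seeds": list(self.seeds),
        }


def bayes_evaluate(
    values,
    labels,
    n_repeats: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    density: str = "gaussian",
    feature: str = "feature",
    positive: str = POSITIVE_CLASS,
    min_per_class: int = 10,
) -> ClassifierReport:
    """Balanced repeated hold-out evaluation of the 1-D Bayes classifier.

    Per repeat: the majority class is downsampled (without replacement) to
    the minority size; each class is split ``train_frac`` / rest; densities
    are fitted on training values only; sensitivity (recall of the positive
    class), specificity and accuracy are measured on the held-out test
    points. The final metrics are means over repeats.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from labels")
    negative = classes[0] if classes[1] == positive else classes[1]
    idx = {cls: np.nonzero(labels == cls)[0] for cls in classes}
    n_min = min(len(v) for v in idx.values())
    if n_min < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} cells per class after balancing, "
            f"got {n_min}"
        )
    n_train = int(round(train_frac * n_min))
    n_test = n_min - n_train
    if n_train < 2 or n_test < 1:
        raise ValueError("train/test split leaves an empty set")
    seeds = tuple(
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(n_repeats)
    )
    rows = []
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        train_v, train_l, test_v, test_l = [], [], [], []
        for cls in classes:
            chosen = rng.choice(idx[cls], size=n_min, replace=False)
            perm = rng.permutation(n_min)
            tr = chosen[perm[:n_train]]
            te = chosen[perm[n_train:]]
            train_v.append(values[tr])
            train_l.extend([cls] * n_train)
            test_v.append(values[te])
            test_l.extend([cls] * n_test)
        model = bayes_train(
            np.concatenate(train_v), np.array(train_l), density=density
        )
        pred = [bayes_predict(model, v) for v in np.concatenate(test_v)]
        test_l = np.array(test_l)
        pred = np.array(pred)
        tp = int(np.sum((test_l == positive) & (pred == positive)))
        fn = int(np.sum((test_l == positive) & (pred != positive)))
        tn = int(np.sum((test_l == negative) & (pred == negative)))
        fp = int(np.sum((test_l == negative) & (pred != negative)))
        rows.append(
            {
                "repeat": rep,
                "seed": rep_seed,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "accuracy": (tp + tn) / (tp + tn + fp + fn),
            }
        )
    per = pd.DataFrame(rows)
    return ClassifierReport(
        feature=feature,
        sensitivity=float(per["sensitivity"].mean()),
        specificity=float(per["specificity"].mean()),
        accuracy=float(per["accuracy"].mean()),
        per_repeat=per,
        n_per_class=n_min,
        seeds=seeds,
    )


# ----------------------------------------------------------------------
# Feature correlation
# ----------------------------------------------------------------------

def feature_correlation(
    features: pd.DataFrame,
    columns: tuple[str, ...] = (
        "total_length_um", "volume_um3", "branch_number"
    ),
) -> pd.DataFrame:
    """Pairwise product-moment correlations of size features.

    Returns a tidy frame with one row per pair: ``feature_a``,
    ``feature_b``, ``r``, ``n``. A zero-variance feature yields ``NaN``
    with a warning.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    rows = []
    for a, b in itertools.combinations(columns, 2):
        xa = features[a].to_numpy(dtype=float)
        xb = features[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            warnings.warn(
                f"zero-variance feature in pair ({a}, {b}); r undefined",
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append({"feature_a": a, "feature_b": b, "r": r, "n": len(xa)})
    return pd.DataFrame(rows)
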