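"""Paired-comparison designs, proportion scores, planned contrasts and PSEs.

The experiments use a round-robin paired-comparison design: every stimulus is
shown once beside every other stimulus and the observer picks one (clearer
3-D shape, or more translucent).  The dependent measure per image is the
proportion of its comparisons won.  Condition effects are tested with planned
orthogonal contrasts evaluated within observers: each observer's contrast
score c_i = sum_j w_j * score_ij is tested against zero with a one-sample t,
reported as F = t^2 on (1, n_observers - 1) degrees of freedom at a
decision-wise alpha of 0.05.  Points of subjective equality (PSEs) are read
off an isotonically monotonized psychometric function by linear
interpolation at 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonTrial",
    "ProportionScores",
    "ContrastResult",
    "PSEResult",
    "all_pairs_design",
    "proportion_chosen",
    "planned_contrast_F",
    "contrast_weight_sets",
    "estimate_pse",
    "load_trials",
    "write_trials",
    "write_scores",
]

TRIAL_COLUMNS = ["observer", "image_a", "image_b", "chosen", "judgment"]


@dataclass(frozen=True)
class ComparisonTrial:
    observer: str
    image_a: str
    image_b: str
    chosen: str
    judgment: str = "shape_clarity"

    def __post_init__(self):
        if self.image_a == self.image_b:
            raise ValueError("a trial must compare two distinct images")
        if self.chosen not in (self.image_a, self.image_b):
            raise ValueError("chosen image must be one of the pair")


@dataclass
class ProportionScores:
    """Proportion-of-comparisons-won per image, per observer and pooled."""

    per_observer: pd.DataFrame  # index: observer, columns: image
    pooled: pd.Series  # index: image
    n_comparisons: pd.Series  # presentations per image (pooled)


@dataclass(frozen=True)
class ContrastResult:
    F: float
    df: tuple[int, int]
    p: float
    weights: tuple
    degenerate: bool = False


@dataclass(frozen=True)
class PSEResult:
    pse: float | None
    bracketing_levels: tuple | None
    method: str
    in_range: bool


def all_pairs_design(image_ids, observers, seed: int = 0) -> pd.DataFrame:
    """Round-robin schedule: each unordered pair once per observer.

    Left/right position is randomized by ``seed``.  Columns: observer,
    image_a (left), image_b (right).
    """
    ids = list(image_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate image ids")
    if len(ids) < 2:
        raise ValueError("need at least two images")
    rng = np.random.default_rng(seed)
    rows = []
    for obs in observers:
        for a, b in combinations(ids, 2):
            if rng.random() < 0.5:
                a, b = b, a
            rows.append((obs, a, b))
    return pd.DataFrame(rows, columns=["observer", "image_a", "image_b"])


def proportion_chosen(trials: pd.DataFrame) -> ProportionScores:
    """Wins divided by presentations, per observer and pooled.

    Accepts any trial table with observer/image_a/image_b/chosen columns;
    images that were never presented are excluded with a warning.
    """
    import warnings

    t = trials
    images = sorted(set(t["image_a"]) | set(t["image_b"]))
    observers = sorted(set(t["observer"]))
    pres = pd.DataFrame(0, index=observers, columns=images, dtype=float)
    wins = pres.copy()
    for col in ("image_a", "image_b"):
        counts = t.groupby(["observer", col]).size()
        for (obs, img), n in counts.items():
            pres.loc[obs, img] += n
    wcounts = t.groupby(["observer", "chosen"]).size()
    for (obs, img), n in wcounts.items():
        if img not in wins.columns:
            raise ValueError(f"chosen image {img!r} never presented")
        wins.loc[obs, img] += n
    never = pres.columns[(pres.sum(axis=0) == 0)]
    if len(never):
        warnings.warn(f"excluding images with zero presentations: {list(never)}")
        pres = pres.drop(columns=never)
        wins = wins.drop(columns=never)
    per_observer = wins / pres
    pooled = wins.sum(axis=0) / pres.sum(axis=0)
    return ProportionScores(per_observer, pooled, pres.sum(axis=0))


def planned_contrast_F(scores, weights) -> ContrastResult:
    """Within-subject planned contrast tested as F = t^2 on (1, n-1) df.

    ``scores`` is an (n_observers x n_conditions) array or DataFrame;
    ``weights`` must sum to zero.  Zero variance across observers with a
    non-zero mean is reported as degenerate rather than an infinite F.
    """
    from scipy.stats import f as f_dist

    S = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if S.ndim != 2 or S.shape[1] != len(w):
        raise ValueError("scores must be (n_observers, n_conditions)")
    if abs(w.sum()) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least two observers")
    c = S @ w
    mean = c.mean()
    se = c.std(ddof=1) / math.sqrt(n)
    if se == 0:
        if mean == 0:
            return ContrastResult(0.0, (1, n - 1), 1.0, tuple(w))
        return ContrastResult(math.inf, (1, n - 1), 0.0, tuple(w),
                              degenerate=True)
    t = mean / se
    F = t * t
    p = float(f_dist.sf(F, 1, n - 1))
    return ContrastResult(float(F), (1, n - 1), p, tuple(w))


def contrast_weight_sets(n_elevations: int = 7) -> dict[str, np.ndarray]:
    """Orthogonal planned contrasts for the 2-material x 7-elevation layout.

    Conditions are ordered (chromatic, elev_1..7, then achromatic,
    elev_1..7).  Returns the chromatic-vs-achromatic main effect, the linear
    elevation trend, and their interaction; all pairwise dot products are 0.
    """
    lin = np.arange(n_elevations, dtype=float)
    lin -= lin.mean()  # orthogonal-polynomial linear weights: -3..3 for 7
    main = np.concatenate([np.ones(n_elevations), -np.ones(n_elevations)])
    trend = np.concatenate([lin, lin])
    interaction = np.concatenate([lin, -lin])
    return {"main_effect": main, "linear_trend": trend,
            "interaction": interaction}


def estimate_pse(levels, proportions, method: str = "isotonic") -> PSEResult:
    """Level at which preference for the standard crosses 50%.

    ``proportions`` are the per-level probabilities of choosing the standard
    over the comparison at each ``level``.  The psychometric function is
    monotonized by isotonic regression (direction chosen by the data's
    trend) and the 0.5 crossing is located by linear interpolation.
    """
    from sklearn.isotonic import IsotonicRegression

    x = np.asarray(levels, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two levels")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if method == "isotonic":
        iso = IsotonicRegression(increasing="auto")
        y = iso.fit_transform(x, y)
    exact = np.isclose(y, 0.5)
    if exact.any():
        lvl = float(x[exact][0])
        return PSEResult(lvl, (lvl, lvl), method, True)
    sign = np.sign(y - 0.5)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        return PSEResult(None, None, method, False)
    i = crossings[0]
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    pse = x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)
    return PSEResult(float(pse), (float(x0), float(x1)), method, True)


def load_trials(path, column_map: dict | None = None,
                require_judgment: bool = False) -> pd.DataFrame:
    """Read a columnar trial table, validating every row.

    ``column_map`` renames alternative headers onto the canonical ones
    (observer, image_a, image_b, chosen, judgment).  Malformed rows are
    reported together, with their row numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = TRIAL_COLUMNS[:4] + (["judgment"] if require_judgment else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing trial columns: {missing}")
    if "judgment" not in df.columns:
        df["judgment"] = "shape_clarity"
    errors = []
    for i, row in df.iterrows():
        if row["image_a"] == row["image_b"]:
            errors.append(f"row {i}: image_a == image_b")
        elif row["chosen"] not in (row["image_a"], row["image_b"]):
            errors.append(f"row {i}: chosen not in the presented pair")
    if errors:
        raise ValueError("malformed trial rows:\n" + "\n".join(errors))
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def write_scores(scores: ProportionScores, path) -> None:
    """Per-observer score matrix with a pooled row appended."""
    out = scores.per_observer.copy()
    out.loc["pooled"] = scores.pooled
    out.to_csv(path, index_label="observer")
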