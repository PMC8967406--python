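"""Parametric synthetic observers for paired-comparison experiments.

Human choice data are stood in for by a Thurstone Case V observer: each
stimulus is reduced to image-computable cues, a judgment maps cues to an
internal utility u = w * cue, and the probability of choosing stimulus A
over B is

    P(A) = (1 - lapse) * Phi((u_A - u_B) / (sigma * sqrt(2))) + lapse / 2.

Cues operationalize the image structures the chromatic stimulus carries:

* a shading cue — the RMS contrast of the shading-like component of the
  luminance image (the mean of the three bands regressed onto the clamped
  Lambertian pattern of the generating surface).  Deep multiple scattering
  destroys this component, so the cue falls with albedo, and a chromatic
  surface's crisp shading in its dim bands is diluted by its bright
  deeply-scattered band;
* a curvature cue — the relative convex-minus-concave mean intensity of the
  most deeply scattered band, which grows with albedo;
* a saturation-contrast cue — the dispersion of the CIELAB saturation map,
  identically zero for achromatic stimuli.

Shape-clarity judgments read the shading and saturation cues; translucency
judgments read the curvature cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .surface_geometry import CONCAVE, CONVEX, ShapeIndexMap, classify_region

__all__ = [
    "ObserverModel",
    "CueVector",
    "compute_cues",
    "simulate_choice",
    "choice_probability",
    "generate_dataset",
    "fit_observer_model",
]


@dataclass(frozen=True)
class ObserverModel:
    w_shading: float = 1.0
    w_curvature: float = 1.0
    w_saturation: float = 0.25
    sigma: float = 0.02
    lapse: float = 0.02

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")


@dataclass(frozen=True)
class CueVector:
    shading: float  # Lambert-projected RMS contrast, averaged over bands
    curvature: float  # relative convex - concave mean, maximum-albedo band
    saturation: float = 0.0  # std of the CIELAB saturation map
    shading_defined: bool = True
    curvature_defined: bool = True


def shading_component_contrast(channel: np.ndarray,
                               lambert: np.ndarray) -> float:
    """RMS contrast of a band's shading-like component.

    The band image I is regressed on the clamped Lambertian pattern L
    (I ~ b0 + b1*L); the cue is the contrast std(b1*L)/mean(I) the fitted
    component contributes, clamped at zero for anti-correlated bands.  A
    band exactly proportional to L returns L's own RMS contrast.
    """
    mu = channel.mean()
    var_l = lambert.var()
    if mu <= 0 or var_l == 0:
        return 0.0
    cov = ((channel - mu) * (lambert - lambert.mean())).mean()
    b1 = cov / var_l
    return float(max(b1, 0.0) * lambert.std() / mu)


def compute_cues(stimulus, shape_map: ShapeIndexMap,
                 heightfield=None) -> CueVector:
    """Image-computable cues for one rendered stimulus.

    Shading cue: the shading-component contrast of the luminance (band
    mean) image — its regression onto the clamped Lambert map of
    ``heightfield`` under the stimulus's own illumination; without a height
    field it falls back to the luminance image's plain RMS contrast.
    Curvature cue: mean over
    convex-classified minus mean over concave-classified pixels of the
    highest-albedo band, relative to that band's mean.  Saturation cue:
    standard deviation of the CIELAB saturation map of the sRGB image
    (zero for any achromatic stimulus).
    """
    albedos = stimulus.material.albedo_rgb
    hi = int(np.argmax(albedos))
    if stimulus.linear.shape[1:] != shape_map.s.shape:
        raise ValueError("stimulus and geometry grids are misaligned")
    lum = stimulus.linear.mean(axis=0)
    sh_ok = lum.mean() > 0
    if not sh_ok:
        shading = 0.0
    elif heightfield is not None:
        from .translucent_renderer import lambert_map

        lam = lambert_map(heightfield, stimulus.illumination)
        shading = shading_component_contrast(lum, lam)
    else:
        shading = float(lum.std() / lum.mean())

    region = classify_region(shape_map)
    cvx = (region.classes == CONVEX) & region.mask
    ccv = (region.classes == CONCAVE) & region.mask
    hi_ch = stimulus.linear[hi]
    if cvx.any() and ccv.any() and hi_ch.mean() > 0:
        curvature = float(
            (hi_ch[cvx].mean() - hi_ch[ccv].mean()) / hi_ch.mean())
        cu_ok = True
    else:
        curvature, cu_ok = 0.0, False
    from .chroma_analysis import saturation_map, srgb_to_lab

    sat = saturation_map(srgb_to_lab(stimulus.srgb))
    sat_std = float(sat.saturation[sat.mask].std()) if sat.mask.any() else 0.0
    return CueVector(shading, curvature, sat_std, sh_ok, cu_ok)


def _utility(model: ObserverModel, cue: CueVector, judgment: str) -> float:
    if judgment == "shape_clarity":
        return (model.w_shading * cue.shading
                + model.w_saturation * cue.saturation)
    if judgment == "translucency":
        return model.w_curvature * cue.curvature
    raise ValueError(f"unknown judgment {judgment!r}")


def choice_probability(model: ObserverModel, cue_a: CueVector,
                       cue_b: CueVector, judgment: str) -> float:
    """P(choose A) under the Thurstone Case V rule with lapses."""
    du = _utility(model, cue_a, judgment) - _utility(model, cue_b, judgment)
    p = norm.cdf(du / (model.sigma * math.sqrt(2.0)))
    return (1.0 - model.lapse) * p + model.lapse / 2.0


def simulate_choice(model: ObserverModel, cue_a: CueVector, cue_b: CueVector,
                    judgment: str, rng: np.random.Generator) -> str:
    """'A' or 'B' drawn from the model's choice probability."""
    return "A" if rng.random() < choice_probability(
        model, cue_a, cue_b, judgment) else "B"


def generate_dataset(
    model: ObserverModel,
    cues: dict[str, CueVector],
    design: pd.DataFrame,
    judgment: str = "shape_clarity",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every trial of a paired-comparison schedule.

    ``design`` comes from :func:`chromashade.psychophysics.all_pairs_design`;
    ``cues`` maps image ids to their CueVector.  Returns a trial table in the
    psychophysics loader schema, reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in design.itertuples(index=False):
        a, b = rec.image_a, rec.image_b
        pick = simulate_choice(model, cues[a], cues[b], judgment, rng)
        rows.append(
            (rec.observer, a, b, a if pick == "A" else b, judgment)
        )
    return pd.DataFrame(
        rows, columns=["observer", "image_a", "image_b", "chosen", "judgment"]
    )


def fit_observer_model(trials: pd.DataFrame, cues: dict[str, "CueVector"],
                       judgment: str = "shape_clarity",
                       cue_attr: str | None = None):
    """Maximum-likelihood fit of (sensitivity w/sigma, lapse) on one cue.

    The decision rule only identifies w/sigma, so that ratio is the fitted
    parameter; ``cue_attr`` selects which cue carries the judgment (default:
    shading for shape clarity, curvature for translucency).  Returns a dict with the estimates, the log-likelihood, the
    null (coin-flip) log-likelihood, a profile-likelihood 95% CI for
    w/sigma, and a boundary flag when all choices are identical.
    """
    from scipy.optimize import minimize_scalar

    if len(trials) < 100:
        raise ValueError("need at least 100 trials to fit")
    t = trials[trials["judgment"] == judgment]
    attr = cue_attr or (
        "shading" if judgment == "shape_clarity" else "curvature")
    dcue = np.array(
        [getattr(cues[a], attr) - getattr(cues[b], attr)
         for a, b in zip(t["image_a"], t["image_b"])]
    )
    chose_a = (t["chosen"] == t["image_a"]).to_numpy()

    def nll(params):
        s, lapse = params
        p = norm.cdf(s * dcue / math.sqrt(2.0))
        p = (1.0 - lapse) * p + lapse / 2.0
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(np.where(chose_a, np.log(p), np.log(1.0 - p)))

    from scipy.optimize import minimize

    best = None
    for s0 in (0.0, 1.0, 5.0, -1.0):
        res = minimize(nll, x0=[s0, 0.02], method="L-BFGS-B",
                       bounds=[(-500.0, 500.0), (0.0, 0.1)])
        if best is None or res.fun < best.fun:
            best = res
    s_hat, lapse_hat = best.x
    ll = -best.fun
    ll_null = len(chose_a) * math.log(0.5)
    boundary = bool(chose_a.all() or (~chose_a).all())

    # profile-likelihood 95% CI for the sensitivity
    def profile(s):
        r = minimize_scalar(lambda l: nll([s, l]), bounds=(0.0, 0.1),
                            method="bounded")
        return -r.fun

    target = ll - 1.92  # chi2(1)/2 at 95%
    lo, hi = s_hat, s_hat
    step = max(0.1, abs(s_hat) * 0.05)
    while profile(lo - step) > target and lo - step > -500:
        lo -= step
    while profile(hi + step) > target and hi + step < 500:
        hi += step
    return {
        "sensitivity": float(s_hat),
        "lapse": float(lapse_hat),
        "log_likelihood": float(ll),
        "null_log_likelihood": float(ll_null),
        "ci_sensitivity": (float(lo - step), float(hi + step)),
        "boundary": boundary,
    }
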