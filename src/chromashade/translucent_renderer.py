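"""Forward photon-transport renderer for translucent bumpy planes.

Stands in for a physically based production renderer: per-channel images of a
height-field surface made of a translucent pigmented medium (refractive index
1.3, isotropic scattering by default), lit by one directional source at a
controlled elevation above the viewing direction plus a diffuse ambient term,
viewed orthographically from +z.

Transport inside the medium follows the same physics as
:mod:`chromashade.sss_photon_sim` — shifted-exponential free paths
P = 0.001 - alpha*ln(beta), scattering with probability ``albedo`` per
collision, Schlick/Snell boundary optics — but is evaluated with
variance-reduced estimators so a 10^6-photon render resolves a 67x67 grid:
absorption attenuates a photon weight by ``albedo`` per collision instead of
killing the photon, the Fresnel exit/reflect decision at each boundary hit is
split deterministically (weight (1-R) exits, weight R reflects back in), and
low-weight photons are terminated by Russian roulette.  Expected radiance is
identical to the analog rules.

The lateral boundary is periodic; photons deeper than ``depth_factor`` mean
free paths are dropped (semi-infinite slab).  Entry Fresnel reflection is
ignored, as in the beam simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .surface_geometry import HeightField

__all__ = [
    "MaterialSpec",
    "Illumination",
    "RenderedStimulus",
    "RED_ALBEDO",
    "GRAY_ALBEDO",
    "EXP2_ALBEDO_LEVELS",
    "render_channel",
    "render_stimulus",
    "encode_srgb",
    "srgb_transfer",
    "equate_max_intensity",
    "make_stimulus_set",
    "lambert_map",
]

#: Per-channel scatter probabilities of the red pigment (R, G, B).
RED_ALBEDO = (0.81, 0.13, 0.09)
#: The light-gray comparison pigment scatters 81% in every band.
GRAY_ALBEDO = (0.81, 0.81, 0.81)
#: Achromatic albedo ladder on the renderer's 0-255 scale: 17, 27, ..., 207.
EXP2_ALBEDO_LEVELS = tuple(k / 255.0 for k in range(17, 208, 10))


@dataclass(frozen=True)
class MaterialSpec:
    """Translucent pigment: per-channel albedo + bulk optical parameters.

    ``provenance`` carries the production-renderer settings the synthetic
    material emulates (attenuation 4.29 mm, particle density 305.41,
    roughness 100); they do not enter the transport, which is parameterised
    by (albedo, alpha, refractive index, phase_g).
    """

    albedo_rgb: tuple[float, float, float] = RED_ALBEDO
    alpha: float = 0.5
    refractive_index: float = 1.3
    phase_g: float = 0.0
    provenance: dict = field(
        default_factory=lambda: {
            "attenuation_mm": 4.29,
            "particle_density": 305.41,
            "roughness": 100,
        }
    )

    def __post_init__(self):
        if not all(0.0 <= a <= 1.0 for a in self.albedo_rgb):
            raise ValueError("albedos must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class Illumination:
    """One directional source + hemispheric ambient.

    ``elevation_deg`` is measured from the viewing direction: 0 = frontal
    (light arriving along the line of sight), 90 = light from directly above
    the surface, grazing the mean plane.  The source lies in the y-z plane
    at azimuth 0.
    """

    elevation_deg: float = 45.0
    azimuth_deg: float = 0.0
    ambient_fraction: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.elevation_deg <= 90.0:
            raise ValueError("elevation must lie in [0, 90] degrees")
        if not 0.0 <= self.ambient_fraction <= 1.0:
            raise ValueError("ambient_fraction must lie in [0, 1]")

    def source_direction(self) -> np.ndarray:
        """Unit vector from the surface toward the source."""
        e = math.radians(self.elevation_deg)
        az = math.radians(self.azimuth_deg)
        horiz = math.sin(e)
        return np.array(
            [horiz * math.sin(az), horiz * math.cos(az), math.cos(e)]
        )


@dataclass
class RenderedStimulus:
    """Per-channel linear radiance grids + sRGB encoding + provenance."""

    linear: np.ndarray  # (3, ny, nx)
    srgb: np.ndarray  # (ny, nx, 3) uint8
    material: MaterialSpec
    illumination: Illumination
    meta: dict = field(default_factory=dict)


def srgb_transfer(v: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 transfer function on linear values in [0, 1]."""
    v = np.clip(v, 0.0, 1.0)
    return np.where(
        v <= 0.0031308, 12.92 * v, 1.055 * np.power(v, 1.0 / 2.4) - 0.055
    )


def encode_srgb(linear: np.ndarray, percentile: float = 99.5) -> np.ndarray:
    """Expose a non-negative linear image and encode it as 8-bit sRGB.

    The exposure scalar maps the ``percentile``-th percentile of the image
    (all channels jointly, so color ratios survive) to linear 1.0; an
    all-zero image stays all-zero.
    """
    lin = np.asarray(linear, dtype=float)
    if np.any(lin < 0):
        raise ValueError("linear radiance must be non-negative")
    scale = np.percentile(lin, percentile)
    if scale <= 0:
        return np.zeros(lin.shape, dtype=np.uint8)
    return np.round(255.0 * srgb_transfer(lin / scale)).astype(np.uint8)


def lambert_map(h: HeightField, illum: Illumination) -> np.ndarray:
    """Clamped Lambertian shading max(0, n . l) on the height-field grid."""
    fx, fy = h.gradient_grids()
    w = np.sqrt(1.0 + fx**2 + fy**2)
    s = illum.source_direction()
    return np.maximum(0.0, (-fx * s[0] - fy * s[1] + s[2]) / w)


def _sample_cosine_hemisphere(rng: np.random.Generator, n: int) -> np.ndarray:
    u1 = rng.random(n)
    u2 = rng.random(n)
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    z = np.sqrt(1.0 - u1)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _refract_in(d: np.ndarray, n: np.ndarray, eta: float) -> np.ndarray:
    """Vectorised Snell refraction into the denser medium.

    ``d`` incident unit directions (pointing into the surface), ``n`` unit
    normals opposing them (n . d < 0); ``eta`` = n_outside / n_inside < 1 so
    total internal reflection cannot occur.
    """
    cos_i = -np.einsum("ij,ij->i", d, n)
    sin_t2 = eta**2 * (1.0 - cos_i**2)
    cos_t = np.sqrt(np.maximum(0.0, 1.0 - sin_t2))
    t = eta * d + (eta * cos_i - cos_t)[:, None] * n
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _scatter_directions(rng: np.random.Generator, old: np.ndarray,
                        g: float) -> np.ndarray:
    """Vectorised scatter: uniform sphere (g=0) or HG about ``old``."""
    n = len(old)
    if g == 0.0:
        z = 1.0 - 2.0 * rng.random(n)
        phi = 2.0 * np.pi * rng.random(n)
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    u = rng.random(n)
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = np.clip((1.0 + g * g - frac * frac) / (2.0 * g), -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * rng.random(n)
    w = old / np.linalg.norm(old, axis=1, keepdims=True)
    a = np.where(np.abs(w[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u1 = np.cross(w, a)
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = np.cross(w, u1)
    return (
        cos_t[:, None] * w
        + (sin_t * np.cos(phi))[:, None] * u1
        + (sin_t * np.sin(phi))[:, None] * u2
    )


def _splat(image: np.ndarray, x: np.ndarray, y: np.ndarray,
           w: np.ndarray, spacing: float) -> None:
    """Periodic bilinear deposition of weights into pixel bins."""
    ny, nx = image.shape
    u = x / spacing - 0.5
    v = y / spacing - 0.5
    i0 = np.floor(u).astype(np.int64)
    j0 = np.floor(v).astype(np.int64)
    du = u - i0
    dv = v - j0
    i0 %= nx
    j0 %= ny
    i1 = (i0 + 1) % nx
    j1 = (j0 + 1) % ny
    np.add.at(image, (j0, i0), w * (1 - du) * (1 - dv))
    np.add.at(image, (j0, i1), w * du * (1 - dv))
    np.add.at(image, (j1, i0), w * (1 - du) * dv)
    np.add.at(image, (j1, i1), w * dv * du)


def render_channel(
    h: HeightField,
    albedo: float,
    material: MaterialSpec,
    illum: Illumination,
    n_photons: int = 1_000_000,
    seed: int = 0,
    depth_factor: float = 10.0,
    rr_threshold: float = 0.005,
    max_iter: int = 400,
    path_offset: float = 0.001,
    kernel_sigma_px: float = 0.7,
    first_scatter_split: int | None = None,
) -> np.ndarray:
    """Trace one wavelength band and return its linear radiance grid.

    Entry points are sampled uniformly in (x, y); directional photons carry
    the local projected-flux weight max(0, n.l)/n_z, ambient photons a
    cosine-hemisphere direction.  Exited weight is accumulated into the
    orthographic pixel grid with a max(0, cos-toward-viewer) factor.  The
    RNG stream depends only on ``seed``, never on ``albedo``, so bands with
    equal albedo (and the same seed) produce bit-identical grids.

    Two density-estimation choices keep the pixel noise down at desk-scale
    photon budgets: the accumulated exit map is reconstructed with a small
    periodic Gaussian kernel (``kernel_sigma_px``, photon-mapping style),
    and each photon's first scatter event is split into several candidate
    directions when the albedo is low (short walks make the extra branches
    cheap; ``first_scatter_split=None`` picks the factor from the albedo).
    """
    if not 0.0 <= albedo <= 1.0:
        raise ValueError("albedo must lie in [0, 1]")
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1e3")
    rng = np.random.default_rng(seed)
    ny, nx = h.shape
    Lx, Ly = h.extent
    alpha = material.alpha
    n_in = material.refractive_index
    g = material.phase_g
    eta_in = 1.0 / n_in  # outside -> inside
    eta_out = n_in  # inside -> outside
    r0 = ((n_in - 1.0) / (n_in + 1.0)) ** 2
    depth_floor = -depth_factor * (path_offset + alpha)

    fx_grid, fy_grid = h.gradient_grids()

    n_amb = int(round(illum.ambient_fraction * n_photons))
    n_dir = n_photons - n_amb

    # stratified entry: photons are dealt round-robin over pixel cells and
    # jittered inside the cell, which suppresses entry-position shot noise
    cell = np.arange(n_photons) % (nx * ny)
    ix = cell % nx
    iy = cell // nx
    x0 = (ix + rng.random(n_photons) - 0.5) * h.spacing % Lx
    y0 = (iy + rng.random(n_photons) - 0.5) * h.spacing % Ly
    fx = h.interp(x0, y0, fx_grid)
    fy = h.interp(x0, y0, fy_grid)
    nz_inv = np.sqrt(1.0 + fx**2 + fy**2)
    normals = np.column_stack([-fx, -fy, np.ones(n_photons)]) / nz_inv[:, None]

    d_in = np.empty((n_photons, 3))
    weight = np.empty(n_photons)
    if n_dir:
        s = illum.source_direction()
        d_in[:n_dir] = -s
        # flux through the surface element per unit xy area
        weight[:n_dir] = np.maximum(
            0.0, normals[:n_dir] @ s
        ) * nz_inv[:n_dir]
    if n_amb:
        hemi = _sample_cosine_hemisphere(rng, n_amb)
        d_in[n_dir:] = -hemi
        # cosine-weighted sky sample; importance ratio vs the sampled pdf
        cos_local = np.einsum("ij,ij->i", normals[n_dir:], hemi)
        weight[n_dir:] = np.maximum(0.0, cos_local) * nz_inv[n_dir:] / hemi[:, 2]
    # the scene rotates one light map, so the beam's integrated power is
    # elevation-invariant: normalize each component to its energy fraction
    if n_dir and weight[:n_dir].sum() > 0:
        weight[:n_dir] *= (1.0 - illum.ambient_fraction) * n_photons \
            / weight[:n_dir].sum()
    if n_amb and weight[n_dir:].sum() > 0:
        weight[n_dir:] *= illum.ambient_fraction * n_photons \
            / weight[n_dir:].sum()

    live = weight > 0
    pos = np.column_stack([x0, y0, h.interp(x0, y0)])[live]
    d = _refract_in(d_in[live], normals[live], eta_in)
    w = weight[live]
    virgin = np.ones(len(w), dtype=bool)  # no scatter event yet

    if first_scatter_split is None:
        first_scatter_split = 8 if albedo < 0.5 else 1
    split = max(1, int(first_scatter_split))

    image = np.zeros((ny, nx))
    u_hat = np.array([0.0, 0.0, 1.0])

    for it in range(max_iter):
        if len(w) == 0:
            break
        if it == 0:
            # stratify the entry free-path draw across photons
            m = len(w)
            u_step = (rng.permutation(m) + rng.random(m)) / m
        else:
            u_step = rng.random(len(w))
        step = path_offset - alpha * np.log(1.0 - u_step)
        new = pos + step[:, None] * d
        surf = h.interp(new[:, 0], new[:, 1])
        crossing = new[:, 2] > surf
        deep = (~crossing) & (new[:, 2] < depth_floor)

        if np.any(crossing):
            # bisection for the boundary crossing along the step
            p0 = pos[crossing]
            dc = d[crossing]
            lo = np.zeros(crossing.sum())
            hi = step[crossing]
            for _b in range(30):
                mid = 0.5 * (lo + hi)
                pm = p0 + mid[:, None] * dc
                below = pm[:, 2] <= h.interp(pm[:, 0], pm[:, 1])
                lo = np.where(below, mid, lo)
                hi = np.where(below, hi, mid)
            t_hit = 0.5 * (lo + hi)
            hit = p0 + t_hit[:, None] * dc
            hfx = h.interp(hit[:, 0], hit[:, 1], fx_grid)
            hfy = h.interp(hit[:, 0], hit[:, 1], fy_grid)
            hw = np.sqrt(1.0 + hfx**2 + hfy**2)
            n_hat = np.column_stack([-hfx, -hfy, np.ones(len(hit))]) / hw[:, None]
            cos_i = np.einsum("ij,ij->i", dc, n_hat)
            cos_i_c = np.clip(cos_i, 0.0, 1.0)
            sin_t2 = eta_out**2 * (1.0 - cos_i_c**2)
            tir = (sin_t2 >= 1.0) | (cos_i <= 0.0)
            cos_t = np.sqrt(np.maximum(0.0, 1.0 - sin_t2))
            refl = np.where(
                tir, 1.0, r0 + (1.0 - r0) * (1.0 - cos_t) ** 5
            )
            # deterministic Fresnel split: (1-R) exits, R reflects back in
            d_out = eta_out * dc - (eta_out * cos_i_c - cos_t)[:, None] * n_hat
            nrm = np.linalg.norm(d_out, axis=1)
            d_out /= np.maximum(nrm, 1e-12)[:, None]
            view_cos = np.maximum(0.0, d_out @ u_hat)
            exit_w = w[crossing] * (1.0 - refl) * view_cos
            keep = exit_w > 0
            if np.any(keep):
                _splat(image, hit[keep, 0], hit[keep, 1], exit_w[keep],
                       h.spacing)
            # reflected continuation (grazing numerical hits with cos_i <= 0
            # keep their direction and are just nudged back inside)
            d_ref = np.where(
                (cos_i > 0.0)[:, None], dc - 2.0 * cos_i[:, None] * n_hat, dc
            )
            pos_c = hit - 1e-7 * n_hat
            w_c = w[crossing] * refl
            d[crossing] = d_ref
            pos[crossing] = pos_c
            w[crossing] = w_c

        interior = ~crossing & ~deep
        spawn_pos = spawn_d = spawn_w = None
        if np.any(interior):
            pos[interior] = new[interior]
            w[interior] = w[interior] * albedo
            if split > 1:
                first = interior & virgin
                later = interior & ~virgin
            else:
                first = np.zeros(len(w), dtype=bool)
                later = interior
            if np.any(later):
                d[later] = _scatter_directions(rng, d[later], g)
            if np.any(first):
                # branch the first scatter into `split` directions, w/split each
                k = int(first.sum())
                if g == 0.0:
                    # stratify the branch polar angles over the sphere
                    strata = np.tile(np.arange(split), k)
                    z = 1.0 - 2.0 * (strata + rng.random(k * split)) / split
                    phi = 2.0 * np.pi * rng.random(k * split)
                    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
                    dirs = np.column_stack(
                        [r * np.cos(phi), r * np.sin(phi), z]
                    )
                else:
                    dirs = _scatter_directions(
                        rng, np.repeat(d[first], split, axis=0), g
                    )
                w[first] = w[first] / split
                d[first] = dirs[::split]
                spawn_pos = np.repeat(pos[first], split - 1, axis=0)
                spawn_w = np.repeat(w[first], split - 1)
                keep_rows = np.ones(k * split, dtype=bool)
                keep_rows[::split] = False
                spawn_d = dirs[keep_rows]
            virgin[interior] = False

        w[deep] = 0.0
        if spawn_w is not None and len(spawn_w):
            pos = np.concatenate([pos, spawn_pos])
            d = np.concatenate([d, spawn_d])
            w = np.concatenate([w, spawn_w])
            virgin = np.concatenate(
                [virgin, np.zeros(len(spawn_w), dtype=bool)]
            )
        # Russian roulette on low weights
        u = rng.random(len(w))
        low = w < rr_threshold
        survive_p = np.where(low, w / rr_threshold, 1.0)
        killed = low & (u >= survive_p)
        w = np.where(low & ~killed, rr_threshold, w)
        w[killed] = 0.0
        alive = w > 0
        pos, d, w, virgin = pos[alive], d[alive], w[alive], virgin[alive]

    out = image / n_photons
    if kernel_sigma_px and kernel_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        out = gaussian_filter(out, kernel_sigma_px, mode="wrap")
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def render_stimulus(
    h: HeightField,
    material: MaterialSpec,
    illum: Illumination,
    n_photons: int = 1_000_000,
    seed: int = 0,
    **kwargs,
) -> RenderedStimulus:
    """Render the three wavelength bands with coupled entry/walk seeds.

    Every band uses the same RNG stream, so bands sharing an albedo come out
    bit-identical (and the R band of the red pigment matches the light-gray
    render at the same seed).  Equal-albedo bands are computed once.
    """
    cache: dict[float, np.ndarray] = {}
    chans = []
    for a in material.albedo_rgb:
        if a not in cache:
            cache[a] = render_channel(
                h, a, material, illum, n_photons=n_photons, seed=seed, **kwargs
            )
        chans.append(cache[a])
    linear = np.stack(chans)
    srgb = np.moveaxis(encode_srgb(linear), 0, -1)
    return RenderedStimulus(
        linear=linear,
        srgb=srgb,
        material=material,
        illumination=illum,
        meta={"n_photons": n_photons, "seed": seed},
    )


def equate_max_intensity(stimuli: list[RenderedStimulus]):
    """Multiplicatively rescale each stimulus so all maxima coincide.

    Returns (rescaled stimuli, scalars).  Stimuli whose maximum is zero are
    excluded with a warning.
    """
    import warnings

    if len(stimuli) < 2:
        raise ValueError("need at least two stimuli")
    maxima = np.array([s.linear.max() for s in stimuli])
    usable = maxima > 0
    if not np.all(usable):
        warnings.warn("excluding stimuli with zero maximum intensity")
    target = maxima[usable].max()
    out, scalars = [], []
    for stim, m, ok in zip(stimuli, maxima, usable):
        if not ok:
            continue
        c = target / m
        lin = stim.linear * c
        out.append(
            RenderedStimulus(
                linear=lin,
                srgb=np.moveaxis(encode_srgb(lin), 0, -1),
                material=stim.material,
                illumination=stim.illumination,
                meta={**stim.meta, "intensity_scalar": c},
            )
        )
        scalars.append(c)
    return out, scalars


def make_stimulus_set(
    experiment: str,
    h: HeightField,
    n_photons: int = 1_000_000,
    seed: int = 0,
    ambient_fraction: float = 0.25,
    alpha: float = 0.5,
    **kwargs,
) -> list[RenderedStimulus]:
    """Render the stimulus set of one experiment.

    exp1: 7 illumination elevations (0-90 deg in 15-deg steps) x
    {light-gray 0.81, red (0.81, 0.13, 0.09)} = 14 stimuli.
    exp2: 20 achromatic albedos (17/255 ... 207/255) plus the red pigment,
    all at 45-deg elevation = 21 stimuli.
    """
    stimuli = []
    if experiment == "exp1":
        for elev in range(0, 91, 15):
            illum = Illumination(elev, ambient_fraction=ambient_fraction)
            for name, alb in (("gray", GRAY_ALBEDO), ("red", RED_ALBEDO)):
                mat = MaterialSpec(albedo_rgb=alb, alpha=alpha)
                stim = render_stimulus(h, mat, illum, n_photons, seed, **kwargs)
                stim.meta.update(
                    {"id": f"{name}_e{elev:02d}", "material": name,
                     "elevation": elev}
                )
                stimuli.append(stim)
    elif experiment == "exp2":
        illum = Illumination(45.0, ambient_fraction=ambient_fraction)
        for a in EXP2_ALBEDO_LEVELS:
            mat = MaterialSpec(albedo_rgb=(a, a, a), alpha=alpha)
            stim = render_stimulus(h, mat, illum, n_photons, seed, **kwargs)
            stim.meta.update(
                {"id": f"achrom_{round(a * 255):03d}", "material": "achromatic",
                 "albedo_255": round(a * 255)}
            )
            stimuli.append(stim)
        mat = MaterialSpec(albedo_rgb=RED_ALBEDO, alpha=alpha)
        stim = render_stimulus(h, mat, illum, n_photons, seed, **kwargs)
        stim.meta.update({"id": "red", "material": "red"})
        stimuli.append(stim)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return stimuli
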