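"""Monte Carlo photon transport beneath a corrugated translucent boundary.

A narrow beam enters a semi-infinite medium whose upper boundary is an
alternating train of circular convex ridges and concave valleys (a 2-D
cross-section extruded along the y axis).  Each photon refracts in at the
ridge/valley inflection point, then performs a random walk: free-path lengths
are drawn from the shifted exponential

    P = 0.001 - alpha * ln(beta),       beta ~ Uniform(0, 1],

with alpha the inverse pigment density.  At each subsurface event the photon
is absorbed with probability (1 - albedo), otherwise it scatters into a
random 3-D direction (isotropic, or Henyey-Greenstein when ``phase_g`` is
nonzero).  When a step crosses the boundary the photon either re-emerges or
is internally reflected, with reflection probability from Schlick's
approximation to the Fresnel equations (total internal reflection detected
from Snell's law first).  Entry specular reflection is ignored: only light
refracting into the material is traced.

Coordinates: x across the corrugation, y along the cylinder axis, z up.  The
medium occupies z below the boundary profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RidgeProfile",
    "SimConfig",
    "PhotonPathRecord",
    "BeamSummary",
    "free_path_from_beta",
    "sample_free_path",
    "schlick_reflectance",
    "refract_direction",
    "sample_scatter_direction",
    "line_circle_intersect",
    "trace_photon",
    "run_beam",
    "write_paths_table",
    "write_summary_table",
]


@dataclass(frozen=True)
class RidgeProfile:
    """Alternating convex-ridge / concave-valley boundary of circular arcs.

    Ridge circles sit with centres on z = 0; valley circles are centred at
    z = valley_height = sqrt((2r)^2 - sep^2) so adjacent arcs join
    tangentially.  The junctions (inflection points) lie at
    x = sep/2 + k*sep, z = valley_height/2.
    """

    radius: float = 1.1148
    separation: float = 2.0268

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.separation > 2.0 * self.radius:
            raise ValueError(
                "circles must intersect: separation <= 2*radius required"
            )
        if self.separation <= 0:
            raise ValueError("separation must be positive")

    @property
    def valley_height(self) -> float:
        return math.sqrt((2.0 * self.radius) ** 2 - self.separation**2)

    def circle_center(self, index: int) -> tuple[float, float]:
        """Centre (x, z) of arc ``index``; even = ridge, odd = valley."""
        cx = index * self.separation
        cz = 0.0 if index % 2 == 0 else self.valley_height
        return cx, cz

    def is_ridge(self, index: int) -> bool:
        return index % 2 == 0

    def arc_index(self, x: float) -> int:
        """Index of the arc owning horizontal position x (cells of width sep)."""
        return int(math.floor(x / self.separation + 0.5))

    def height(self, x) -> np.ndarray:
        """Boundary elevation z(x) (vectorised)."""
        x = np.asarray(x, dtype=float)
        idx = np.floor(x / self.separation + 0.5).astype(np.int64)
        dx = x - idx * self.separation
        arc = np.sqrt(np.maximum(self.radius**2 - dx**2, 0.0))
        return np.where(idx % 2 == 0, arc, self.valley_height - arc)

    def entry_point(self) -> np.ndarray:
        """Inflection point between the first convexity and concavity."""
        return np.array(
            [self.separation / 2.0, 0.0, self.valley_height / 2.0]
        )

    def outward_normal(self, x: float, z: float, index: int) -> np.ndarray:
        """Unit outward (out of the medium) normal at a boundary point."""
        cx, cz = self.circle_center(index)
        nx, nz = x - cx, z - cz
        norm = math.hypot(nx, nz)
        if self.is_ridge(index):
            return np.array([nx / norm, 0.0, nz / norm])
        return np.array([-nx / norm, 0.0, -nz / norm])


@dataclass(frozen=True)
class SimConfig:
    n_photons: int = 200
    albedo: float = 0.81
    alpha: float = 0.5
    path_offset: float = 0.001
    n_inside: float = 1.3
    n_outside: float = 1.0
    phase_g: float = 0.0
    max_events: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError("albedo must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not -1.0 < self.phase_g < 1.0:
            raise ValueError("phase_g must lie in (-1, 1)")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")


@dataclass
class PhotonPathRecord:
    """Ordered subsurface vertices and the photon's fate."""

    vertices: np.ndarray  # (k, 3), starts at the entry point
    fate: str  # exited | absorbed | capped
    exit_position: np.ndarray | None = None
    exit_direction: np.ndarray | None = None
    n_events: int = 0


@dataclass
class BeamSummary:
    n_photons: int
    exit_fraction: float
    absorbed_fraction: float
    capped_fraction: float
    mean_lateral_displacement: float
    records: list = field(default_factory=list)


def free_path_from_beta(alpha: float, beta: float, offset: float = 0.001) -> float:
    """Shifted-exponential free path P = offset - alpha*ln(beta)."""
    return offset - alpha * math.log(beta)


def sample_free_path(alpha: float, rng: np.random.Generator,
                     offset: float = 0.001) -> float:
    """Draw a free-path length; beta uniform on (0, 1] so P >= offset."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    beta = 1.0 - rng.random()  # (0, 1]
    return free_path_from_beta(alpha, beta, offset)


def schlick_reflectance(cos_incident: float, n_from: float, n_to: float) -> float:
    """Schlick's approximation R = R0 + (1-R0)(1-cos)^5.

    ``cos_incident`` is the cosine of the incidence angle on the ``n_from``
    side.  Going from a denser to a rarer medium the (1-cos)^5 term uses the
    transmission-side cosine, and angles beyond the critical angle return 1.
    """
    if not 0.0 <= cos_incident <= 1.0 + 1e-12:
        raise ValueError("cos_incident must lie in [0, 1]")
    r0 = ((n_from - n_to) / (n_from + n_to)) ** 2
    cos_x = min(cos_incident, 1.0)
    if n_from > n_to:
        sin_t2 = (n_from / n_to) ** 2 * (1.0 - cos_x**2)
        if sin_t2 >= 1.0:
            return 1.0
        cos_x = math.sqrt(1.0 - sin_t2)
    return r0 + (1.0 - r0) * (1.0 - cos_x) ** 5


def refract_direction(direction: np.ndarray, normal: np.ndarray,
                      n_from: float, n_to: float):
    """Snell refraction of a unit ``direction`` across a unit ``normal``.

    The normal must oppose the incident direction (normal . direction <= 0).
    Returns ``(refracted_unit_vector, False)`` or ``(None, True)`` on total
    internal reflection.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    dn, nn = np.linalg.norm(d), np.linalg.norm(n)
    if dn < 1e-12 or nn < 1e-12:
        raise ValueError("direction and normal must be non-zero")
    d, n = d / dn, n / nn
    cos_i = -float(np.dot(d, n))
    if cos_i < 0:
        raise ValueError("normal must oppose the incident direction")
    eta = n_from / n_to
    sin_t2 = eta**2 * (1.0 - cos_i**2)
    if sin_t2 >= 1.0:
        return None, True
    cos_t = math.sqrt(1.0 - sin_t2)
    t = eta * d + (eta * cos_i - cos_t) * n
    return t / np.linalg.norm(t), False


def sample_scatter_direction(rng: np.random.Generator, g: float = 0.0,
                             incoming: np.ndarray | None = None) -> np.ndarray:
    """Random 3-D scatter direction: uniform sphere (g=0) or Henyey-Greenstein.

    For g != 0 the polar angle is drawn by inverting the HG CDF about the
    ``incoming`` direction.
    """
    if g == 0.0 or incoming is None:
        z = 1.0 - 2.0 * rng.random()
        phi = 2.0 * math.pi * rng.random()
        r = math.sqrt(max(0.0, 1.0 - z * z))
        return np.array([r * math.cos(phi), r * math.sin(phi), z])
    u = rng.random()
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
    cos_t = min(1.0, max(-1.0, cos_t))
    sin_t = math.sqrt(1.0 - cos_t * cos_t)
    phi = 2.0 * math.pi * rng.random()
    w = np.asarray(incoming, dtype=float)
    w = w / np.linalg.norm(w)
    # build an orthonormal frame about w
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u1 = np.cross(w, a)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(w, u1)
    return cos_t * w + sin_t * (math.cos(phi) * u1 + math.sin(phi) * u2)


def line_circle_intersect(origin, direction, center, radius, tol: float = 1e-9):
    """Smallest forward parameter t > tol where the 2-D line hits the circle.

    ``origin``/``direction`` are the in-profile (x, z) components; the
    direction need not be unit length, so t is in units of that direction.
    Returns None when the ray misses or both roots are behind the origin.
    """
    o = np.asarray(origin, dtype=float) - np.asarray(center, dtype=float)
    d = np.asarray(direction, dtype=float)
    a = float(np.dot(d, d))
    if a < 1e-18:
        raise ValueError("in-profile direction component must be non-zero")
    b = 2.0 * float(np.dot(o, d))
    c = float(np.dot(o, o)) - radius**2
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    for t in (t1, t2):
        if t > tol:
            return t
    return None


def _boundary_hit(profile: RidgeProfile, pos: np.ndarray, direction: np.ndarray,
                  max_dist: float, tol: float = 1e-9):
    """Nearest boundary crossing within ``max_dist`` along a 3-D step.

    Checks every arc whose cell the in-profile segment can reach and keeps
    the smallest valid parameter (hit inside that arc's own cell).  Returns
    ``(t, point, arc_index)`` or None.
    """
    o2 = np.array([pos[0], pos[2]])
    d2 = np.array([direction[0], direction[2]])
    if np.dot(d2, d2) < 1e-18:
        return None
    x_lo = min(pos[0], pos[0] + direction[0] * max_dist) - profile.radius
    x_hi = max(pos[0], pos[0] + direction[0] * max_dist) + profile.radius
    i_lo = int(math.floor(x_lo / profile.separation + 0.5))
    i_hi = int(math.floor(x_hi / profile.separation + 0.5))
    best = None
    for idx in range(i_lo, i_hi + 1):
        center = profile.circle_center(idx)
        o = o2 - center
        a = float(np.dot(d2, d2))
        b = 2.0 * float(np.dot(o, d2))
        c = float(np.dot(o, o)) - profile.radius**2
        disc = b * b - 4.0 * a * c
        if disc < 0:
            continue
        sq = math.sqrt(disc)
        for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            if not (tol < t <= max_dist):
                continue
            hx = pos[0] + direction[0] * t
            hz = pos[2] + direction[2] * t
            # hit must lie within this arc's own half-separation cell
            if abs(hx - center[0]) > profile.separation / 2.0 + 1e-12:
                continue
            # and on the boundary half of the circle: upper arc of ridges,
            # lower arc of valleys (the other halves are interior)
            if profile.is_ridge(idx):
                if hz < center[1] - 1e-12:
                    continue
            elif hz > center[1] + 1e-12:
                continue
            if best is None or t < best[0]:
                hit = pos + direction * t
                best = (t, hit, idx)
    return best


def trace_photon(config: SimConfig, profile: RidgeProfile,
                 rng: np.random.Generator) -> PhotonPathRecord:
    """Trace one photon from vertical entry at the inflection point."""
    entry = profile.entry_point()
    idx0 = profile.arc_index(entry[0] - 1e-9)
    n_out = profile.outward_normal(entry[0], entry[2], idx0)
    direction, tir = refract_direction(
        np.array([0.0, 0.0, -1.0]), n_out, config.n_outside, config.n_inside
    )
    assert not tir  # entering the denser medium cannot totally reflect
    pos = entry.copy()
    vertices = [pos.copy()]
    n_events = 0

    remaining = sample_free_path(config.alpha, rng, config.path_offset)
    while True:
        hit = _boundary_hit(profile, pos, direction, remaining)
        if hit is not None:
            t, hpos, idx = hit
            n_hat = profile.outward_normal(hpos[0], hpos[2], idx)
            cos_i = float(np.dot(direction, n_hat))
            if cos_i <= 0:
                # re-entering geometry numerically; nudge inward and continue
                pos = hpos - 1e-9 * n_hat
                remaining -= t
                if remaining <= 0:
                    remaining = sample_free_path(
                        config.alpha, rng, config.path_offset)
                continue
            refracted, tir = refract_direction(
                direction, -n_hat, config.n_inside, config.n_outside
            )
            reflect = tir or rng.random() < schlick_reflectance(
                cos_i, config.n_inside, config.n_outside
            )
            if not reflect:
                vertices.append(hpos.copy())
                return PhotonPathRecord(
                    vertices=np.array(vertices),
                    fate="exited",
                    exit_position=hpos,
                    exit_direction=refracted,
                    n_events=n_events,
                )
            direction = direction - 2.0 * cos_i * n_hat
            pos = hpos - 1e-9 * n_hat
            remaining -= t
            if remaining <= 1e-12:
                remaining = sample_free_path(config.alpha, rng,
                                             config.path_offset)
            continue

        # free path completes inside the medium: subsurface event
        pos = pos + direction * remaining
        vertices.append(pos.copy())
        n_events += 1
        if rng.random() < 1.0 - config.albedo:
            return PhotonPathRecord(np.array(vertices), "absorbed",
                                    n_events=n_events)
        if n_events >= config.max_events:
            return PhotonPathRecord(np.array(vertices), "capped",
                                    n_events=n_events)
        direction = sample_scatter_direction(rng, config.phase_g, direction)
        remaining = sample_free_path(config.alpha, rng, config.path_offset)


def run_beam(config: SimConfig, profile: RidgeProfile | None = None,
             keep_records: bool = True) -> BeamSummary:
    """Trace ``n_photons`` with independent substreams of one seeded generator."""
    if config.n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    profile = profile or RidgeProfile()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_photons)
    entry = profile.entry_point()
    counts = {"exited": 0, "absorbed": 0, "capped": 0}
    lateral = []
    records = []
    for ss in streams:
        rec = trace_photon(config, profile, np.random.default_rng(ss))
        counts[rec.fate] += 1
        if rec.fate == "exited":
            dx = rec.exit_position[0] - entry[0]
            dy = rec.exit_position[1] - entry[1]
            lateral.append(math.hypot(dx, dy))
        if keep_records:
            records.append(rec)
    n = config.n_photons
    return BeamSummary(
        n_photons=n,
        exit_fraction=counts["exited"] / n,
        absorbed_fraction=counts["absorbed"] / n,
        capped_fraction=counts["capped"] / n,
        mean_lateral_displacement=float(np.mean(lateral)) if lateral else 0.0,
        records=records,
    )


def write_paths_table(summary: BeamSummary, path) -> None:
    """Tabular text: photon id, event index, x, y, z, fate."""
    import pandas as pd

    rows = []
    for pid, rec in enumerate(summary.records):
        for ev, v in enumerate(rec.vertices):
            rows.append((pid, ev, v[0], v[1], v[2], rec.fate))
    pd.DataFrame(
        rows, columns=["photon", "event", "x", "y", "z", "fate"]
    ).to_csv(path, index=False)


def write_summary_table(summary: BeamSummary, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "n_photons": summary.n_photons,
                "exit_fraction": summary.exit_fraction,
                "absorbed_fraction": summary.absorbed_fraction,
                "capped_fraction": summary.capped_fraction,
                "mean_lateral_displacement": summary.mean_lateral_displacement,
            }
        ]
    ).to_csv(path, index=False)
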