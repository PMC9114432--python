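"""Parametric synthetic ankle anatomy.

Generates watertight bone-surface meshes (distal tibia with fibular
incisura and medial malleolus, distal fibula with lateral malleolar fossa,
talus) with named anatomical landmarks, in a canonical *right*-ankle frame:

* +x lateral, +y anterior, +z proximal (along the tibial shaft), units mm,
  distal tibial plafond at ``plafond_z``;
* left ankles are handled by mirroring about the sagittal plane at load
  time (:func:`mirror_specimen`, :func:`canonicalize`).

All shapes are constructive: the tibia is a capped cylinder whose lateral
aspect carries a cosine-profile incisura groove (the groove is cut from the
tangent chord, so the chord-to-floor sagitta equals ``incisura_depth``
exactly) and whose medial rim prolongs into the medial malleolus; the
fibula is a shaft of revolution about its medullary canal that widens into
an off-axis circular lateral malleolus carrying a posteromedial fossa
depression.  The fossa's medial cortical wall -- the structure whose
projection defines point B of the ratio-alpha measurement -- is the medial
half-depth flank of the depression; its azimuth is solved so that at the
neutral pose, in the default 15-degree mortise view, the wall projects at
``fossa_medial_offset_frac`` of the malleolar width.  That single constant
is the only quantity calibrated against the reported normal range; the
behaviour at rotated poses is emergent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .meshes import (TriMesh, make_uv_sphere, mesh_from_rings, read_obj, read_stl,
                     write_obj, write_stl)

__all__ = [
    "AnatomyParams",
    "AnkleSpecimen",
    "Population",
    "ParameterError",
    "ScreeningRoster",
    "generate_specimen",
    "generate_cohort",
    "generate_roster",
    "mirror_specimen",
    "canonicalize",
    "save_specimen",
    "load_specimen",
]

DEFAULT_MORTISE_DEG = 15.0


class ParameterError(ValueError):
    """An anatomy parameter violates its stated constraints."""


@dataclass(frozen=True)
class AnatomyParams:
    """Generator parameters for one synthetic ankle (lengths in mm)."""

    fibula_shaft_radius: float = 4.5
    fibula_length: float = 85.0          # malleolar tip to proximal cut
    malleolus_width: float = 14.0        # mediolateral width of the lateral malleolus
    fossa_medial_offset_frac: float = 0.49  # neutral-view wall position / malleolar width
    fossa_depth: float = 3.0             # maximal depth of the fossa depression
    incisura_depth: float = 4.5          # chord-to-floor sagitta of the incisura
    incisura_chord: float = 22.0         # tangent-chord length of the incisura
    plafond_z: float = 0.0
    tibia_radius: float = 18.0
    sex: str = "female"
    seed: int = 0
    # secondary shape parameters (population-stable defaults)
    malleolus_offset: float = 2.5        # lateral offset of malleolar centre from the canal
    fossa_span_deg: float = 60.0         # full angular width of the fossa depression
    fossa_halfheight: float = 4.0        # vertical half-extent of the depression
    neutral_clearance: float = 0.2       # tibiofibular gap at the neutral pose
    malleolus_tip_drop: float = 20.0     # lateral malleolar tip below the plafond
    medial_malleolus_drop: float = 12.0  # medial malleolar tip below the plafond
    medial_malleolus_radius: float = 6.0
    tibia_shaft_height: float = 60.0
    side: str = "right"
    medial_malleolus_tip: tuple | None = None  # derived when None

    def resolved_tip(self) -> np.ndarray:
        if self.medial_malleolus_tip is not None:
            return np.asarray(self.medial_malleolus_tip, float)
        lobe_x = -(self.tibia_radius - self.medial_malleolus_radius)
        return np.array([lobe_x, 0.0, self.plafond_z - self.medial_malleolus_drop])

    def validate(self) -> None:
        positive = [
            "fibula_shaft_radius", "fibula_length", "malleolus_width", "fossa_depth",
            "incisura_chord", "tibia_radius", "malleolus_offset", "fossa_span_deg",
            "fossa_halfheight", "malleolus_tip_drop", "medial_malleolus_drop",
            "medial_malleolus_radius", "tibia_shaft_height",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.incisura_depth < 0:
            raise ParameterError(f"incisura_depth must be >= 0, got {self.incisura_depth!r}")
        if not 0.0 < self.fossa_medial_offset_frac < 1.0:
            raise ParameterError(
                f"fossa_medial_offset_frac must lie strictly in (0, 1), "
                f"got {self.fossa_medial_offset_frac!r}")
        if self.incisura_chord >= 2.0 * self.tibia_radius:
            raise ParameterError("incisura_chord must be smaller than the tibial diameter")
        if self.incisura_chord < self.malleolus_width + 1.0:
            raise ParameterError(
                "incisura_chord must exceed malleolus_width (+1 mm) so the "
                "fibula can nest in the incisura")
        if self.malleolus_offset >= self.malleolus_width / 2.0 - 0.5:
            raise ParameterError("malleolus_offset must keep the canal inside the malleolus")
        if self.fossa_depth >= self.malleolus_width / 2.0:
            raise ParameterError("fossa_depth must be smaller than the malleolar half-width")
        if self.sex not in ("male", "female"):
            raise ParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        tip = self.resolved_tip()
        if tip[0] >= 0.0:
            raise ParameterError("medial_malleolus_tip must lie medial to the tibial axis")
        if tip[2] >= self.plafond_z:
            raise ParameterError("medial_malleolus_tip must lie distal to the plafond")


@dataclass
class AnkleSpecimen:
    """Bone meshes + named 3D landmarks in the canonical ankle frame."""

    tibia_mesh: TriMesh
    fibula_mesh: TriMesh
    talus_mesh: TriMesh
    landmarks: dict[str, np.ndarray]
    params: AnatomyParams
    specimen_id: str = "specimen"

    @property
    def side(self) -> str:
        return self.params.side

    def bones(self) -> dict[str, TriMesh]:
        return {"tibia": self.tibia_mesh, "fibula": self.fibula_mesh, "talus": self.talus_mesh}


# ---------------------------------------------------------------------------
# tibia


def _incisura_contour(params: AnatomyParams, n_phi: int) -> np.ndarray:
    """Closed 2D cross-section of the tibial shaft (grooved circle), CCW."""
    rt = params.tibia_radius
    half = params.incisura_chord / 2.0
    delta = np.arcsin(half / rt)           # rim half-angle; rims at azimuth +/-delta
    phis = np.linspace(-np.pi, np.pi, n_phi, endpoint=False)
    x = rt * np.cos(phis)
    y = rt * np.sin(phis)
    in_groove = np.abs(phis) < delta
    pg = phis[in_groove]
    # chord is the vertical line x = rt*cos(delta); ray at azimuth phi meets it at:
    cx = rt * np.cos(delta)
    cy = cx * np.tan(pg)
    t = cy / (rt * np.sin(delta))          # chord parameter in [-1, 1]
    bump = np.cos(np.pi * t / 2.0) ** 2    # 1 at the centre, 0 at the rims
    x[in_groove] = cx - params.incisura_depth * bump
    y[in_groove] = cy
    return np.stack([x, y], axis=1)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _build_tibia(params: AnatomyParams, n_phi: int) -> TriMesh:
    p = params
    z0 = p.plafond_z
    contour = _incisura_contour(p, n_phi)
    rl = p.medial_malleolus_radius
    lobe_center = np.array([-(p.tibia_radius - rl), 0.0])
    phis = np.linspace(-np.pi, np.pi, n_phi, endpoint=False)
    lobe = lobe_center + rl * np.stack([np.cos(phis), np.sin(phis)], axis=1)

    def ring_at(xy: np.ndarray, z: float) -> np.ndarray:
        return np.concatenate([xy, np.full((len(xy), 1), z)], axis=1)

    rings = []
    # fine rings: facet size must stay below the tibiofibular clearance scale
    # or collision broad-phases degenerate
    shaft_zs = np.arange(z0 + p.tibia_shaft_height, z0 + 1.0, -1.5)
    for z in [*shaft_zs, z0]:
        rings.append(ring_at(contour, z))
    # plafond-to-malleolus transition: full section shrinks onto the medial
    # lobe; finely ringed so facets stay small near the tibiofibular contact
    for z in np.arange(z0 - 0.1, z0 - 2.0 - 1e-9, -0.1):
        w = _smoothstep((z0 - z) / 2.0)
        rings.append(ring_at((1 - w) * contour + w * lobe, z))
    # medial malleolus: lobe tapers to its distal tip
    tip = p.resolved_tip()
    drop = p.medial_malleolus_drop
    for z in np.arange(z0 - 2.5, tip[2] + 0.25, -0.5):
        tau = (z0 - 2.0 - z) / (drop - 2.0)
        shrink = np.sqrt(max(1.0 - tau * tau, 1e-4))
        rings.append(ring_at(lobe_center + shrink * (lobe - lobe_center), z))
    top_point = np.array([0.0, 0.0, z0 + p.tibia_shaft_height])
    return mesh_from_rings(rings, cap_top_point=top_point, cap_bottom_point=tip, name="tibia")


# ---------------------------------------------------------------------------
# fibula


def _malleolus_radius(phi, R: float, d: float):
    """Polar radius (about the canal axis) of the off-axis malleolar circle."""
    phi = np.asarray(phi, float)
    return d * np.cos(phi) + np.sqrt(R * R - (d * np.sin(phi)) ** 2)


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _solve_wall_azimuth(params: AnatomyParams, view_deg: float = DEFAULT_MORTISE_DEG) -> float:
    """Azimuth (about the canal) where the fossa wall must sit so that the
    neutral-pose mortise-view projection lands at ``fossa_medial_offset_frac``
    of the malleolar width."""
    p = params
    R = p.malleolus_width / 2.0
    d = p.malleolus_offset
    v = np.radians(view_deg)

    def wall_u(phi: float) -> float:
        rho = _malleolus_radius(phi, R, d) - p.fossa_depth / 2.0
        return rho * np.cos(phi + v)

    # target u relative to the canal axis
    target = d * np.cos(v) - R + p.fossa_medial_offset_frac * 2.0 * R
    lo, hi = np.radians(-175.0) - v, np.radians(-5.0) - v
    f_lo, f_hi = wall_u(lo) - target, wall_u(hi) - target
    if f_lo * f_hi > 0:
        raise ParameterError(
            "fossa_medial_offset_frac is not realisable for this malleolar geometry")
    return float(brentq(lambda a: wall_u(a) - target, lo, hi, xtol=1e-12))


def _fossa_depth_field(phi, z, params: AnatomyParams, phi_fossa: float, z_fossa: float):
    """Pocket depth (mm) removed radially at azimuth/height (phi, z)."""
    p = params
    half_span = np.radians(p.fossa_span_deg) / 2.0
    s = np.sqrt((_wrap_angle(np.asarray(phi) - phi_fossa) / half_span) ** 2
                + ((np.asarray(z) - z_fossa) / p.fossa_halfheight) ** 2)
    depth = np.where(s < 1.0, p.fossa_depth * np.cos(np.pi * np.minimum(s, 1.0) / 2.0) ** 2, 0.0)
    return depth


def _fibula_profile(phi: np.ndarray, z: float, params: AnatomyParams,
                    phi_fossa: float, z_fossa: float) -> np.ndarray:
    """Polar radius about the canal axis at height z (canonical, neutral pose)."""
    p = params
    R = p.malleolus_width / 2.0
    d = p.malleolus_offset
    z0 = p.plafond_z
    tip_z = z0 - p.malleolus_tip_drop
    z_mal_top = z0 + 2.0
    z_morph_top = z0 + 12.0
    taper_z = tip_z + 3.5
    r_mal = _malleolus_radius(phi, R, d)
    if z >= z_morph_top:
        r = np.full_like(phi, p.fibula_shaft_radius)
    elif z >= z_mal_top:
        w = _smoothstep((z_morph_top - z) / (z_morph_top - z_mal_top))
        r = (1 - w) * p.fibula_shaft_radius + w * r_mal
    elif z >= taper_z:
        r = r_mal.copy()
    else:
        tau = (taper_z - z) / (taper_z - tip_z)
        r = r_mal * np.sqrt(np.clip(1.0 - tau * tau, 0.01, 1.0))
    return r - _fossa_depth_field(phi, z, params, phi_fossa, z_fossa)


def _place_fibula(params: AnatomyParams, n_contour: int = 720) -> float:
    """Solve the canal x-position so the neutral tibiofibular gap equals
    ``neutral_clearance`` (2D, against the medial envelope of the fibula:
    the malleolar circle *and* the shaft circle, whichever reaches further
    medially for the drawn anatomy)."""
    p = params
    R = p.malleolus_width / 2.0
    contour = _incisura_contour(params, n_contour)
    seg_a = contour
    seg_b = np.roll(contour, -1, axis=0)

    def dist_to_contour(c: np.ndarray) -> float:
        ab = seg_b - seg_a
        t = np.clip(np.einsum("ij,ij->i", c - seg_a, ab)
                    / np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12), 0.0, 1.0)
        closest = seg_a + t[:, None] * ab
        return float(np.min(np.linalg.norm(closest - c, axis=1)))

    def gap(fx: float) -> float:
        gap_mal = dist_to_contour(np.array([fx + p.malleolus_offset, 0.0])) - R
        gap_shaft = dist_to_contour(np.array([fx, 0.0])) - p.fibula_shaft_radius
        return min(gap_mal, gap_shaft)

    # bracket: canal placed so the malleolar centre sits at the groove floor
    # (deep interpenetration) up to far lateral of the tibia
    delta = np.arcsin(p.incisura_chord / 2.0 / p.tibia_radius)
    floor_x = p.tibia_radius * np.cos(delta) - p.incisura_depth
    lo = floor_x - p.malleolus_offset
    hi = p.tibia_radius + 3.0 * R
    return float(brentq(lambda fx: gap(fx) - p.neutral_clearance, lo, hi, xtol=1e-10))


def _build_fibula(params: AnatomyParams, n_phi: int) -> tuple[TriMesh, dict]:
    p = params
    z0 = p.plafond_z
    tip_z = z0 - p.malleolus_tip_drop
    top_z = tip_z + p.fibula_length
    z_fossa = z0 - p.medial_malleolus_drop     # fossa centred at the reference-line level
    phi_wall = _solve_wall_azimuth(p)
    half_span = np.radians(p.fossa_span_deg) / 2.0
    phi_fossa = phi_wall + half_span / 2.0     # wall = medial half-depth flank
    fx = _place_fibula(p)

    phis = np.linspace(-np.pi, np.pi, n_phi, endpoint=False)
    zs: list[float] = list(np.arange(top_z, z0 + 16.0, -1.5))
    zs += list(np.arange(z0 + 16.0, z0 + 2.0 - 1e-9, -1.0))
    zs += list(np.arange(z0 + 1.0, z0 - 7.0 - 1e-9, -1.0))
    zs += list(np.arange(z0 - 7.5, z0 - 16.5 - 1e-9, -0.5))   # fossa belt, finer
    zs += list(np.arange(z0 - 17.0, tip_z + 0.75, -0.75))
    rings = []
    for z in zs:
        r = _fibula_profile(phis, z, p, phi_fossa, z_fossa)
        ring = np.stack([fx + r * np.cos(phis), r * np.sin(phis), np.full(n_phi, z)], axis=1)
        rings.append(ring)
    mesh = mesh_from_rings(
        rings,
        cap_top_point=np.array([fx, 0.0, top_z]),
        cap_bottom_point=np.array([fx, 0.0, tip_z]),
        name="fibula",
    )
    aux = {"canal_x": fx, "phi_wall": phi_wall, "phi_fossa": phi_fossa,
           "z_fossa": z_fossa, "half_span": half_span}
    return mesh, aux


def _fossa_wall_ring(params: AnatomyParams, aux: dict, n_points: int = 96) -> np.ndarray:
    """Half-depth iso-contour of the fossa depression, on the carved surface.

    A closed loop around the depression; its medial branch is the fossa's
    medial cortical wall whose tangential-ray shadow defines point B.
    """
    p = params
    taus = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    dphi = aux["half_span"] * 0.5 * np.cos(taus)
    dz = p.fossa_halfheight * 0.5 * np.sin(taus)
    phi = aux["phi_fossa"] + dphi
    z = aux["z_fossa"] + dz
    R = p.malleolus_width / 2.0
    r = _malleolus_radius(phi, R, p.malleolus_offset) - p.fossa_depth / 2.0
    return np.stack([aux["canal_x"] + r * np.cos(phi), r * np.sin(phi), z], axis=1)


# ---------------------------------------------------------------------------
# specimen assembly


def generate_specimen(params: AnatomyParams | None = None, *,
                      specimen_id: str = "specimen",
                      n_phi_fibula: int = 96, n_phi_tibia: int = 120,
                      n_phi_talus: int = 48) -> AnkleSpecimen:
    """Build one synthetic ankle; deterministic for fixed params."""
    p = params if params is not None else AnatomyParams()
    p.validate()
    tibia = _build_tibia(p, n_phi_tibia)
    fibula, aux = _build_fibula(p, n_phi_fibula)
    z0 = p.plafond_z
    # the talus fills the mortise: its lateral half-width adapts to the drawn
    # fibular position so the lateral joint space stays ~1 mm at neutral
    fib_medial_x = min(aux["canal_x"] - p.fibula_shaft_radius,
                       aux["canal_x"] + p.malleolus_offset - p.malleolus_width / 2.0)
    talus_cx = 1.5
    talus_sx = float(np.clip(fib_medial_x - talus_cx - 1.0, 4.0, 7.0))
    talus = make_uv_sphere(center=(talus_cx, 0.0, z0 - 8.0),
                           radii=(talus_sx, 11.0, 6.5),
                           n_theta=max(n_phi_talus // 2, 8), n_phi=n_phi_talus,
                           name="talus")
    rt = p.tibia_radius
    delta = np.arcsin(p.incisura_chord / 2.0 / rt)
    ring = _fossa_wall_ring(p, aux)
    rim_phi = aux["phi_fossa"] + aux["half_span"]
    rim_r = _malleolus_radius(rim_phi, p.malleolus_width / 2.0, p.malleolus_offset)
    landmarks = {
        "medial_malleolus_tip": p.resolved_tip(),
        "plafond_medial": np.array([-rt, 0.0, z0]),
        "plafond_lateral": np.array([rt * np.cos(delta), rt * np.sin(delta), z0]),
        "fossa_wall_ring": ring,
        "fossa_rim_anterior": np.array([
            aux["canal_x"] + rim_r * np.cos(rim_phi), rim_r * np.sin(rim_phi),
            aux["z_fossa"]]),
        "fibula_canal_distal": np.array([aux["canal_x"], 0.0, z0 - 5.0]),
        "fibula_canal_proximal": np.array([aux["canal_x"], 0.0, z0 + 45.0]),
    }
    spec = AnkleSpecimen(tibia, fibula, talus, landmarks, p, specimen_id)
    if p.side == "left":
        spec = mirror_specimen(replace_side(spec, "right"), rename=False)
    return spec


def replace_side(spec: AnkleSpecimen, side: str) -> AnkleSpecimen:
    return dataclasses.replace(spec, params=replace(spec.params, side=side))


def mirror_specimen(spec: AnkleSpecimen, rename: bool = True) -> AnkleSpecimen:
    """Reflect about the sagittal plane (x -> -x); toggles the recorded side."""
    lm = {}
    for k, v in spec.landmarks.items():
        v = np.array(v, float, copy=True)
        v[..., 0] = -v[..., 0]
        lm[k] = v
    new_side = "left" if spec.side == "right" else "right"
    tip = spec.params.resolved_tip().copy()
    tip[0] = -tip[0]
    params = replace(spec.params, side=new_side, medial_malleolus_tip=tuple(tip))
    sid = spec.specimen_id + "_mirrored" if rename else spec.specimen_id
    return AnkleSpecimen(
        spec.tibia_mesh.mirrored(0), spec.fibula_mesh.mirrored(0),
        spec.talus_mesh.mirrored(0), lm, params, sid)


def canonicalize(spec: AnkleSpecimen) -> AnkleSpecimen:
    """Return the specimen in the canonical right-ankle frame (mirror lefts)."""
    if spec.side == "right":
        return spec
    return mirror_specimen(spec, rename=False)


# ---------------------------------------------------------------------------
# population / cohort


@dataclass(frozen=True)
class Population:
    """Distribution of :class:`AnatomyParams` over the synthetic cohort.

    Incisura depth is bimodal about the 4 mm concave/shallow threshold: the
    type is drawn first (``p_concave``), then the depth from the matching
    normal component truncated at the threshold, so the realised concave
    fraction matches ``p_concave`` in expectation.
    """

    p_male: float = 45.0 / 96.0
    p_concave: float = 0.583
    shallow_depth_mean: float = 3.0
    shallow_depth_sd: float = 0.5
    concave_depth_mean: float = 4.8
    concave_depth_sd: float = 0.6
    offset_frac_mean: float = 0.49
    offset_frac_sd: float = 0.05
    malleolus_width_mean: dict = field(default_factory=lambda: {"male": 14.8, "female": 13.4})
    malleolus_width_sd: float = 0.9
    fossa_depth_mean: float = 3.0
    fossa_depth_sd: float = 0.35
    tibia_radius_mean: dict = field(default_factory=lambda: {"male": 18.5, "female": 17.5})
    tibia_radius_sd: float = 0.8
    incisura_chord_mean: float = 22.0
    incisura_chord_sd: float = 1.2
    shaft_radius_mean: float = 4.5
    shaft_radius_sd: float = 0.25
    malleolus_offset_mean: float = 2.5
    malleolus_offset_sd: float = 0.25
    age_mean: float = 38.4
    age_sd: float = 13.6

    def validate(self) -> None:
        for name in ("p_male", "p_concave"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("shallow_depth_sd", "concave_depth_sd", "offset_frac_sd",
                     "malleolus_width_sd", "fossa_depth_sd", "tibia_radius_sd",
                     "incisura_chord_sd", "shaft_radius_sd", "malleolus_offset_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def sample_incisura_depth(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Bimodal incisura depths (mm); P(depth >= 4) == p_concave exactly."""
        concave = rng.random(size) < self.p_concave
        out = np.empty(size)
        m, s = self.concave_depth_mean, self.concave_depth_sd
        n_c = int(concave.sum())
        if n_c:
            out[concave] = truncnorm.rvs((4.0 - m) / s, (9.0 - m) / s, loc=m, scale=s,
                                         size=n_c, random_state=rng)
        m, s = self.shallow_depth_mean, self.shallow_depth_sd
        n_s = size - n_c
        if n_s:
            out[~concave] = truncnorm.rvs((0.5 - m) / s, (4.0 - m) / s, loc=m, scale=s,
                                          size=n_s, random_state=rng)
        return out

    def sample_params(self, rng: np.random.Generator) -> AnatomyParams:
        sex = "male" if rng.random() < self.p_male else "female"
        width = float(np.clip(rng.normal(self.malleolus_width_mean[sex],
                                         self.malleolus_width_sd), 11.0, 16.5))
        fossa_depth = float(np.clip(rng.normal(self.fossa_depth_mean, self.fossa_depth_sd),
                                    2.0, 4.2))
        frac = float(np.clip(rng.normal(self.offset_frac_mean, self.offset_frac_sd),
                             0.28, 0.70))
        tibia_r = float(np.clip(rng.normal(self.tibia_radius_mean[sex],
                                           self.tibia_radius_sd), 15.0, 21.0))
        chord = float(np.clip(rng.normal(self.incisura_chord_mean, self.incisura_chord_sd),
                              max(18.0, width + 1.5), 2.0 * tibia_r - 3.0))
        shaft = float(np.clip(rng.normal(self.shaft_radius_mean, self.shaft_radius_sd),
                              3.5, 5.5))
        offset = float(np.clip(rng.normal(self.malleolus_offset_mean,
                                          self.malleolus_offset_sd),
                               1.5, width / 2.0 - 1.0))
        depth = float(self.sample_incisura_depth(rng, 1)[0])
        return AnatomyParams(
            fibula_shaft_radius=shaft, malleolus_width=width,
            fossa_medial_offset_frac=frac, fossa_depth=fossa_depth,
            incisura_depth=depth, incisura_chord=chord, tibia_radius=tibia_r,
            malleolus_offset=offset, sex=sex,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def generate_cohort(n: int, population: Population | None = None, seed: int = 0, *,
                    n_phi_fibula: int = 96, n_phi_tibia: int = 120) -> list[AnkleSpecimen]:
    """Draw ``n`` specimens from the population distribution (reproducible)."""
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    pop = population if population is not None else Population()
    pop.validate()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        params = pop.sample_params(rng)
        cohort.append(generate_specimen(
            params, specimen_id=f"S{i + 1:03d}",
            n_phi_fibula=n_phi_fibula, n_phi_tibia=n_phi_tibia))
    return cohort


# ---------------------------------------------------------------------------
# screening roster


@dataclass
class ScreeningRoster:
    """Screening records with mutually exclusive exclusion flags."""

    records: pd.DataFrame  # record_id, age, prior_fracture, under_18, poor_image_quality

    FLAGS = ("prior_fracture", "under_18", "poor_image_quality")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScreeningRoster":
        return cls(pd.read_csv(path))


def generate_roster(n_total: int, n_prior_fracture: int, n_under18: int,
                    n_poor_quality: int, seed: int = 0,
                    population: Population | None = None) -> ScreeningRoster:
    """Screening roster with exactly the requested per-cause exclusion counts."""
    counts = (n_prior_fracture, n_under18, n_poor_quality)
    if any(c < 0 for c in counts) or n_total < 0:
        raise ParameterError("roster counts must be non-negative")
    if sum(counts) > n_total:
        raise ParameterError(
            f"exclusion counts {counts} exceed the roster size {n_total}")
    pop = population if population is not None else Population()
    rng = np.random.default_rng(seed)
    ages = np.clip(rng.normal(pop.age_mean, pop.age_sd, n_total), 18.0, 75.0).round(1)
    flags = np.zeros((n_total, 3), dtype=int)
    order = rng.permutation(n_total)
    pos = 0
    for j, c in enumerate(counts):
        flags[order[pos:pos + c], j] = 1
        pos += c
    under = flags[:, 1] == 1
    ages[under] = rng.uniform(8.0, 17.9, int(under.sum())).round(1)
    df = pd.DataFrame({
        "record_id": [f"P{i + 1:03d}" for i in range(n_total)],
        "age": ages,
        "prior_fracture": flags[:, 0],
        "under_18": flags[:, 1],
        "poor_image_quality": flags[:, 2],
    })
    return ScreeningRoster(df)


# ---------------------------------------------------------------------------
# IO: meshes + landmark sidecar


def save_specimen(spec: AnkleSpecimen, directory, fmt: str = "stl") -> None:
    """Write bone meshes (binary STL or OBJ) and a JSON landmark sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mesh in spec.bones().items():
        if fmt == "stl":
            write_stl(mesh, directory / f"{spec.specimen_id}_{name}.stl")
        elif fmt == "obj":
            write_obj(mesh, directory / f"{spec.specimen_id}_{name}.obj")
        else:
            raise ValueError(f"unsupported mesh format {fmt!r}")
    sidecar = {
        "specimen_id": spec.specimen_id,
        "side": spec.side,
        "units": "mm",
        "frame": "canonical ankle frame: +x lateral (right), +y anterior, +z proximal",
        "landmarks": {k: np.asarray(v).tolist() for k, v in spec.landmarks.items()},
        "params": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in dataclasses.asdict(spec.params).items()},
    }
    with open(directory / f"{spec.specimen_id}_landmarks.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_specimen(directory, specimen_id: str, fmt: str = "stl",
                  mirror_left: bool = True) -> AnkleSpecimen:
    """Load a specimen written by :func:`save_specimen` (real-data entry point).

    Left-sided specimens are mirrored into the canonical right frame when
    ``mirror_left`` is set (the default), as the pipeline assumes.
    """
    directory = Path(directory)
    with open(directory / f"{specimen_id}_landmarks.json") as fh:
        sidecar = json.load(fh)
    reader = read_stl if fmt == "stl" else read_obj
    bones = {name: reader(directory / f"{specimen_id}_{name}.{fmt}", name)
             for name in ("tibia", "fibula", "talus")}
    lm = {k: np.asarray(v, float) for k, v in sidecar["landmarks"].items()}
    pkw = sidecar.get("params", {})
    if pkw.get("medial_malleolus_tip") is not None:
        pkw["medial_malleolus_tip"] = tuple(pkw["medial_malleolus_tip"])
    params = AnatomyParams(**pkw) if pkw else AnatomyParams(side=sidecar.get("side", "right"))
    spec = AnkleSpecimen(bones["tibia"], bones["fibula"], bones["talus"], lm,
                         params, sidecar["specimen_id"])
    if mirror_left and spec.side == "left":
        spec = mirror_specimen(spec, rename=False)
    return spec
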