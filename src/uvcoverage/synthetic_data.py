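"""Synthetic UV-photograph and study-population generators with known truth.

The generators emulate the data a UV-photography coverage study produces:

* per-participant image pairs in which applied product darkens covered
  skin multiplicatively, ``a(mass) = exp(-kappa * mass)``, over a
  per-participant skin-tone baseline with Gaussian sensor noise;
* application failures as contiguous blobs placed preferentially around
  the eyelids and medial canthi (people repeatedly miss the same
  anatomical areas, not random salt-and-pepper pixels);
* a study population table of paired percent-missed draws per region,
  with the crossover structure, subgroup shifts and counterbalanced
  order assignment of an 84-participant two-formulation trial.

Every output is a pure function of its spec and seed, so downstream
segmentation and statistics can be validated against exact ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from uvcoverage.coverage import UVImage, write_mask_png
from uvcoverage.facial_regions import (
    LandmarkSet,
    RegionParams,
    RegionSet,
    regions_from_landmarks,
    write_landmarks_pts,
)

__all__ = [
    "GenerationError",
    "ParticipantSpec",
    "PopulationSpec",
    "SyntheticParticipantBundle",
    "generate_landmark_template",
    "generate_participant",
    "generate_population",
    "write_fixture_set",
    "attenuation",
    "SKIN_TYPE_BASE_INTENSITY",
    "DEFAULT_KAPPA",
]

# Baseline grey level by Fitzpatrick skin type: darker types reflect less UV.
SKIN_TYPE_BASE_INTENSITY = {"I": 200.0, "II": 180.0, "III": 150.0, "IV": 120.0}

# exp(-kappa * 100) = 0.6: a 100 mg-equivalent application attenuates the
# covered-skin intensity by ~40%.
DEFAULT_KAPPA = -math.log(0.6) / 100.0


class GenerationError(ValueError):
    """A synthetic-data request is infeasible (e.g. region pixel budget)."""


def attenuation(mass: float, kappa: float = DEFAULT_KAPPA) -> float:
    """Multiplicative intensity attenuation of covered skin at a given mass."""
    return math.exp(-kappa * mass)


@dataclass(frozen=True)
class ParticipantSpec:
    """Ground-truth description of one synthetic participant-condition.

    ``true_missed_fraction`` maps region names (``face``, ``eyelid``,
    ``non_eyelid``, ``canthus_left``, ``canthus_right``) to the uncovered
    fraction in [0, 1]; ``face`` acts as the default for the eyelid /
    non-eyelid partition when those are not given explicitly.
    """

    participant_id: str
    skin_type: str = "II"
    sex: str = "female"
    age: float = 30.0
    base_intensity: float | None = None
    true_missed_fraction: dict[str, float] = field(default_factory=dict)
    applied_mass: float = 100.0
    noise_sd: float = 2.0
    image_dims: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.skin_type not in SKIN_TYPE_BASE_INTENSITY:
            raise GenerationError(f"unknown skin type {self.skin_type!r}")
        if self.base_intensity is None:
            object.__setattr__(
                self, "base_intensity", SKIN_TYPE_BASE_INTENSITY[self.skin_type]
            )
        if not 0 < self.base_intensity <= 255:
            raise GenerationError("base_intensity must lie in (0, 255]")
        for name, f in self.true_missed_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise GenerationError(
                    f"true_missed_fraction[{name!r}] = {f} outside [0, 1]"
                )
        if min(self.image_dims) < 64:
            raise GenerationError("image_dims must be at least 64x64")
        if self.applied_mass < 0:
            raise GenerationError("applied_mass must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic study population.

    ``region_params`` maps region -> formulation -> (mean, sd) of percent
    missed.  Defaults reflect an 84-participant crossover comparison in
    which the moisturiser is applied less completely than the sunscreen
    in every region, with within-participant correlation ``rho`` between
    the two formulation visits.  ``sex_effect`` (males) and
    ``skin_type_effect`` (types III+IV) are additive percentage-point
    shifts, applied mean-centred so the marginal means are preserved.
    """

    n_participants: int = 84
    region_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "face": {"sunscreen": (11.1, 5.0), "moisturiser": (16.6, 6.4)},
            "eyelid": {"sunscreen": (14.0, 8.3), "moisturiser": (20.9, 8.2)},
            "non_eyelid": {"sunscreen": (9.5, 5.5), "moisturiser": (13.6, 6.9)},
        }
    )
    rho: float = 0.5
    sex_effect: float = -5.0
    skin_type_effect: float = -6.0
    male_fraction: float = 22.0 / 84.0
    skin_type_probs: tuple[float, ...] = (0.30, 0.45, 0.15, 0.10)
    age_range: tuple[float, float] = (18.0, 57.0)
    # (sunscreen-first, moisturiser-first) counts; None = the 60:24 ratio
    # of the default 84-participant design, scaled to n_participants
    order_assignment: tuple[int, int] | None = None
    canthus_missed_rate: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise GenerationError("n_participants must be >= 2")
        if not -1.0 <= self.rho <= 1.0:
            raise GenerationError("rho must lie in [-1, 1]")
        for region, by_form in self.region_params.items():
            for form, (_, sd) in by_form.items():
                if sd <= 0:
                    raise GenerationError(
                        f"SD for {region}/{form} must be positive"
                    )
        if self.order_assignment is None:
            n_first = int(round(self.n_participants * 60 / 84))
            n_first = min(max(n_first, 1), self.n_participants - 1)
            object.__setattr__(self, "order_assignment",
                               (n_first, self.n_participants - n_first))
        if sum(self.order_assignment) != self.n_participants:
            raise GenerationError(
                "order_assignment counts must sum to n_participants"
            )


@dataclass
class SyntheticParticipantBundle:
    """Images, landmarks and exact truth masks for one participant."""

    baseline_image: UVImage
    applied_images: dict[str, UVImage]
    landmarks: LandmarkSet
    truth_masks: dict[str, np.ndarray]  # True = covered
    regions: RegionSet
    spec: ParticipantSpec


# ---------------------------------------------------------------------------
# 68-point landmark template

def _unit_template() -> np.ndarray:
    """Canonical frontal 68-point template, bilaterally symmetric about x=0.

    Unit coordinates: x in [-1, 1] across the jaw, y downward with the
    chin at y=1.  Ordering follows the standard scheme (jaw, brows, nose,
    eyes, mouth).
    """
    pts = np.zeros((68, 2))
    # jaw 1-17: open ellipse from image-left ear to chin to image-right ear
    t = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = -np.cos(t)
    pts[0:17, 1] = -0.1 + 1.1 * np.sin(t)
    # brows 18-27 (outer->inner on the left, inner->outer on the right)
    bx = np.linspace(-0.72, -0.22, 5)
    arch = 0.06 * np.sin(np.linspace(0, np.pi, 5))
    pts[17:22] = np.column_stack([bx, -0.64 - arch])
    pts[22:27] = np.column_stack([-bx[::-1], (-0.64 - arch)[::-1]])
    # nose bridge 28-31 and base 32-36
    pts[27:31] = np.column_stack([np.zeros(4), np.linspace(-0.50, 0.0, 4)])
    pts[31:36] = np.column_stack(
        [np.array([-0.16, -0.08, 0.0, 0.08, 0.16]),
         np.array([0.12, 0.15, 0.17, 0.15, 0.12])]
    )
    # eyes 37-48: six points each, corners at cx +/- w
    def eye(cx: float, mirror: bool) -> np.ndarray:
        w, h, cy = 0.20, 0.08, -0.38
        p = np.array([
            [cx - w, cy], [cx - w / 3, cy - h], [cx + w / 3, cy - h],
            [cx + w, cy], [cx + w / 3, cy + h], [cx - w / 3, cy + h],
        ])
        return p

    pts[36:42] = eye(-0.42, False)          # left eye: 37 outer, 40 inner
    pts[42:48] = eye(0.42, True)            # right eye: 43 inner, 46 outer
    # mouth 49-68: outer 12 + inner 8 elliptical rings centred at (0, 0.55)
    for start, n, rx, ry in ((48, 12, 0.30, 0.12), (60, 8, 0.20, 0.05)):
        a = np.pi + 2 * np.pi * np.arange(n) / n
        pts[start:start + n] = np.column_stack(
            [rx * np.cos(a), 0.55 - ry * np.sin(a)]
        )
    return pts


def generate_landmark_template(image_dims: tuple[int, int] = (128, 128),
                               scale: float = 0.8, jitter_sd: float = 0.0,
                               seed: int = 0) -> LandmarkSet:
    """Place the canonical 68-point template into an image frame.

    ``scale`` is the jaw width as a fraction of image width.  Gaussian
    jitter of SD ``jitter_sd`` pixels is added independently per
    coordinate; points are clipped to image bounds afterwards.
    """
    h, w = image_dims
    if h < 64 or w < 64:
        raise GenerationError(f"image_dims {image_dims} too small (min 64x64)")
    if not 0 < scale <= 1:
        raise GenerationError("scale must lie in (0, 1]")
    unit = _unit_template()
    sx = scale * (w - 1) / 2.0
    sy = scale * (h - 1) / 2.0 / 1.05
    cx, cy = (w - 1) / 2.0, (h - 1) * 0.55
    pts = np.column_stack([cx + unit[:, 0] * sx, cy + unit[:, 1] * sy])
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return LandmarkSet(pts, (h, w))


# ---------------------------------------------------------------------------
# Participant image generation

_STABLE_RADII: np.ndarray | None = None


def _stable_radii() -> np.ndarray:
    """Disc radii whose rasterization survives closing(disk(1)) unchanged.

    A few narrow radius bands rasterize with single-pixel tips or square
    corners that morphological closing fills; blobs avoid those bands so
    the segmentation's cleanup step cannot eat into ground truth.
    """
    global _STABLE_RADII
    if _STABLE_RADII is None:
        from skimage import morphology
        good = []
        for r in np.arange(2.0, 14.01, 0.1):
            n = int(np.ceil(r)) + 2
            yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
            hole = (yy * yy + xx * xx) <= r * r
            closed = morphology.closing(~hole, morphology.disk(1))
            if not (closed & hole).any():
                good.append((r, int(hole.sum())))
        _STABLE_RADII = (np.array([g[0] for g in good]),
                         np.array([g[1] for g in good]))
    return _STABLE_RADII


def _place_blobs(region: np.ndarray, target: int, rng: np.random.Generator,
                 weight: np.ndarray | None = None,
                 forbidden: np.ndarray | None = None) -> np.ndarray:
    """Mark exactly ``target`` region pixels as uncovered, in compact blobs.

    Blobs are built to be invariant under the segmentation's default
    morphological cleanup (closing with a radius-1 disc), so the recorded
    ground truth is exactly what an ideal noise-free segmentation would
    measure: whole rasterized discs of closing-stable radii are stamped
    with a one-pixel gap from other blobs, and the exact-count remainder
    accretes pixel by pixel under a local closing-stability constraint.
    Centres are sampled with probability proportional to ``weight``;
    pixels in ``forbidden`` are never used.
    """
    available = region if forbidden is None else (region & ~forbidden)
    n_avail = int(available.sum())
    if target > n_avail:
        raise GenerationError(
            f"requested {target} uncovered pixels but only {n_avail} available"
        )
    uncovered = np.zeros_like(region)
    if target == 0:
        return uncovered
    radii, areas = _stable_radii()
    r_hi = max(5.0, 0.20 * math.sqrt(n_avail))
    placed = 0
    while placed < target:
        remaining = target - placed
        room = available & ~uncovered
        # stamp whole discs while one of at least radius 2 fits inside the
        # remaining room with a one-pixel gap from other blobs and the
        # region border (the gap prevents thin tangency necks that the
        # closing step would fill)
        dt = ndimage.distance_transform_edt(room)
        r_fit = dt - 2.0
        # min radius 3.2: in smaller blobs a single noise-flipped pixel
        # can destabilize the whole shape against the closing step,
        # while larger discs self-heal (the flip is removed as a small
        # covered component)
        r_min = 3.2
        min_area = int(areas[radii >= r_min][0])
        eligible = (r_fit >= r_min) & room
        if remaining >= min_area and eligible.any():
            ys, xs = np.nonzero(eligible)
            w_px = (np.ones(len(ys)) if weight is None
                    else np.maximum(weight[ys, xs].astype(float), 1e-9))
            c = rng.choice(len(ys), p=w_px / w_px.sum())
            cy, cx = int(ys[c]), int(xs[c])
            r_cap = min(float(r_fit[cy, cx]), r_hi)
            r_draw = rng.uniform(r_min, max(r_min, r_cap))
            ok = (radii >= r_min) & (radii <= r_draw) & (areas <= remaining)
            if not ok.any():
                ok = (radii >= r_min) & (areas <= remaining)
            r = float(radii[np.nonzero(ok)[0][-1]])
            y0, y1 = int(cy - r), int(cy + r) + 1
            x0, x1 = int(cx - r), int(cx + r) + 1
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disc = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
            uncovered[y0:y1, x0:x1] |= disc
            placed += int(disc.sum())
        else:
            uncovered = _grow_tail(uncovered, room, remaining, rng, weight)
            placed = target
    return uncovered


# plus-shaped structuring element of the default closing step
_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _closing_stable_candidates(u: np.ndarray) -> np.ndarray:
    """Pixels p for which u | {p} keeps p stable under closing(disk(1)).

    A pixel survives the closing iff some translate of the plus-shaped
    structuring element contains it and lies entirely in the uncovered
    set.  Survival is monotone in the set, so accreting only such pixels
    keeps every previously placed pixel stable as well.  ``u`` must carry
    a 2-pixel False border (guaranteed by the caller's padding).
    """
    def s(dy: int, dx: int) -> np.ndarray:
        return u[2 + dy:u.shape[0] - 2 + dy, 2 + dx:u.shape[1] - 2 + dx]

    centre = s(-1, 0) & s(1, 0) & s(0, -1) & s(0, 1)
    up = s(-1, 0) & s(-2, 0) & s(-1, -1) & s(-1, 1)
    down = s(1, 0) & s(2, 0) & s(1, -1) & s(1, 1)
    left = s(0, -1) & s(0, -2) & s(-1, -1) & s(1, -1)
    right = s(0, 1) & s(0, 2) & s(-1, 1) & s(1, 1)
    out = np.zeros_like(u)
    out[2:-2, 2:-2] = centre | up | down | left | right
    return out


def _grow_tail(uncovered: np.ndarray, room: np.ndarray, remaining: int,
               rng: np.random.Generator,
               weight: np.ndarray | None) -> np.ndarray:
    """Add exactly ``remaining`` pixels, preserving closing stability.

    Growth accretes one pixel at a time at boundary positions that stay
    stable under the segmentation's closing step, preferring positions
    with many uncovered neighbours (notches first, so outlines stay
    compact).  When no stable accretion site exists, a 5-pixel plus is
    seeded where it fits; as a last resort (fewer than 5 pixels left and
    nowhere stable) plain boundary pixels are added — the only point at
    which ground truth and ideal segmentation may differ, by < 5 pixels.
    """
    out = np.pad(uncovered, 2)
    rm = np.pad(room, 2)
    plus_ok_needed = True
    while remaining > 0:
        cand = rm & ~out
        if not cand.any():
            raise GenerationError("ran out of room while placing blobs")
        stable = cand & _closing_stable_candidates(out)
        if stable.any():
            # neighbour count for smoothness preference
            ncount = (np.pad(out[1:, :], ((0, 1), (0, 0))).astype(int)
                      + np.pad(out[:-1, :], ((1, 0), (0, 0))).astype(int)
                      + np.pad(out[:, 1:], ((0, 0), (0, 1))).astype(int)
                      + np.pad(out[:, :-1], ((0, 0), (1, 0))).astype(int))
            scores = np.where(stable, ncount, -1)
            best = scores.max()
            ys, xs = np.nonzero(scores == best)
            c = int(rng.integers(len(ys)))
            out[ys[c], xs[c]] = True
            remaining -= 1
            continue
        if remaining >= 5:
            # seed a plus-shaped nucleus where one fits with a 1-px gap
            fits = ndimage.binary_erosion(
                ndimage.binary_erosion(cand, _PLUS), _PLUS
            )
            if not fits.any():
                fits = ndimage.binary_erosion(cand, _PLUS)
            if fits.any():
                ys, xs = np.nonzero(fits)
                if weight is not None:
                    wpad = np.pad(weight, 2)
                    w_px = np.maximum(wpad[ys, xs].astype(float), 1e-9)
                else:
                    w_px = np.ones(len(ys))
                c = rng.choice(len(ys), p=w_px / w_px.sum())
                cy, cx = int(ys[c]), int(xs[c])
                out[cy - 1:cy + 2, cx - 1:cx + 2] |= _PLUS
                remaining -= 5
                continue
        # last resort: plain pixels at the fullest boundary positions
        ncount = (np.pad(out[1:, :], ((0, 1), (0, 0))).astype(int)
                  + np.pad(out[:-1, :], ((1, 0), (0, 0))).astype(int)
                  + np.pad(out[:, 1:], ((0, 0), (0, 1))).astype(int)
                  + np.pad(out[:, :-1], ((0, 0), (1, 0))).astype(int))
        scores = np.where(cand, ncount, -1)
        ys, xs = np.nonzero(scores == scores.max())
        c = int(rng.integers(len(ys)))
        out[ys[c], xs[c]] = True
        remaining -= 1
    return out[2:-2, 2:-2]


def _resolve_targets(tmf: dict[str, float], regions: RegionSet
                     ) -> tuple[dict[str, int], dict[str, float]]:
    """Map requested missed fractions onto the eyelid/non-eyelid partition."""
    face_f = tmf.get("face")
    fracs = {
        "eyelid": tmf.get("eyelid", face_f if face_f is not None else 0.0),
        "non_eyelid": tmf.get("non_eyelid", face_f if face_f is not None else 0.0),
    }
    for side in ("left", "right"):
        key = f"canthus_{side}"
        if key in tmf:
            fracs[key] = tmf[key]
    counts = {name: int(round(f * regions.area(name)))
              for name, f in fracs.items()}
    return counts, fracs


def generate_participant(spec: ParticipantSpec, seed: int = 0,
                         region_params: RegionParams | None = None,
                         conditions: dict[str, dict] | None = None,
                         landmark_jitter_sd: float = 1.0,
                         rgb: bool = False,
                         kappa: float = DEFAULT_KAPPA
                         ) -> SyntheticParticipantBundle:
    """Generate a baseline/applied image bundle with exact truth masks.

    The baseline is the participant's skin tone plus Gaussian sensor
    noise.  Each applied image darkens covered pixels by
    ``exp(-kappa * mass)`` and leaves uncovered pixels at skin tone;
    uncovered pixels form contiguous blobs whose per-region counts hit
    the requested missed fractions exactly (to one pixel), with eyelid
    blobs seeded preferentially near the medial canthi.

    ``conditions`` maps condition names to overrides of
    ``true_missed_fraction`` and/or ``applied_mass``; by default a single
    ``"applied"`` condition uses the spec's own fields.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_dims
    lm = generate_landmark_template(
        (h, w), jitter_sd=landmark_jitter_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    regions = regions_from_landmarks(lm, region_params, (h, w))

    def to_image(grey: np.ndarray, condition: str) -> UVImage:
        grey = np.clip(grey, 0, 255)
        if rgb:
            px = np.stack([grey, grey * 0.98, grey * 0.95], axis=-1)
        else:
            px = grey
        return UVImage(np.round(px).astype(np.uint8),
                       participant=spec.participant_id, condition=condition)

    base = float(spec.base_intensity)
    baseline = to_image(
        base + rng.normal(0.0, spec.noise_sd, size=(h, w)), "baseline"
    )

    if conditions is None:
        conditions = {"applied": {}}
    # canthus-weighted seeding inside the eyelid region
    weight = np.ones((h, w))
    weight[regions["canthus_left"] | regions["canthus_right"]] = 3.0

    applied_images: dict[str, UVImage] = {}
    truth_masks: dict[str, np.ndarray] = {}
    for name, override in conditions.items():
        cspec = replace(
            spec,
            true_missed_fraction=override.get(
                "true_missed_fraction", spec.true_missed_fraction),
            applied_mass=override.get("applied_mass", spec.applied_mass),
        )
        counts, fracs = _resolve_targets(cspec.true_missed_fraction, regions)
        uncovered = np.zeros((h, w), dtype=bool)
        # canthus boxes with an explicit target of zero are kept pristine:
        # no general eyelid/non-eyelid blob may intrude there
        protected = np.zeros((h, w), dtype=bool)
        for side in ("left", "right"):
            key = f"canthus_{side}"
            if key not in counts:
                continue
            if counts[key] == 0:
                protected |= regions[key]
            else:
                uncovered |= _place_blobs(
                    regions[key], counts[key], rng, weight=None
                )
        for part in ("eyelid", "non_eyelid"):
            already = int((uncovered & regions[part]).sum())
            need = counts[part] - already
            if need < 0:
                # explicit canthus targets already exceed this region's
                # budget; accept the overshoot, the truth mask stays exact
                log_frac = already / max(regions.area(part), 1)
                warnings.warn(
                    f"{part} missed fraction raised to {log_frac:.3f} by "
                    f"canthus targets", stacklevel=2,
                )
                need = 0
            uncovered |= _place_blobs(
                regions[part], need, rng,
                weight=weight if part == "eyelid" else None,
                forbidden=uncovered | protected,
            )
        a = attenuation(cspec.applied_mass, kappa)
        clean = np.where(uncovered, base, base * a)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=(h, w))
        applied_images[name] = to_image(noisy, name)
        truth_masks[name] = ~uncovered

    return SyntheticParticipantBundle(
        baseline_image=baseline, applied_images=applied_images,
        landmarks=lm, truth_masks=truth_masks, regions=regions, spec=spec,
    )


# ---------------------------------------------------------------------------
# Population generation

def generate_population(pop: PopulationSpec) -> pd.DataFrame:
    """Draw a long-format study table of true percent-missed values.

    Each participant receives one bivariate-normal draw per region —
    sunscreen and moisturiser components correlated at ``rho`` — plus
    mean-centred additive subgroup shifts, truncated to [0, 100].
    Participants are assigned sex, skin type I-IV (with the derived
    collapsed ``skin_group``), age, counterbalanced first-formulation
    order and per-visit binary medial-canthus outcomes.
    """
    rng = np.random.default_rng(pop.seed)
    n = pop.n_participants
    male = rng.random(n) < pop.male_fraction
    skin_levels = np.array(["I", "II", "III", "IV"])
    probs = np.asarray(pop.skin_type_probs, dtype=float)
    skin = skin_levels[rng.choice(4, size=n, p=probs / probs.sum())]
    dark = np.isin(skin, ["III", "IV"])
    age = rng.uniform(*pop.age_range, size=n)
    order = np.array(
        ["sunscreen_first"] * pop.order_assignment[0]
        + ["moisturiser_first"] * pop.order_assignment[1]
    )
    rng.shuffle(order)

    shift = (pop.sex_effect * (male - male.mean())
             + pop.skin_type_effect * (dark - dark.mean()))

    records = []
    canthus = {
        form: rng.random(n) < pop.canthus_missed_rate
        for form in ("sunscreen", "moisturiser")
    }
    for region, by_form in pop.region_params.items():
        forms = list(by_form)
        mus = np.array([by_form[f][0] for f in forms])
        sds = np.array([by_form[f][1] for f in forms])
        cov = np.array([
            [sds[0] ** 2, pop.rho * sds[0] * sds[1]],
            [pop.rho * sds[0] * sds[1], sds[1] ** 2],
        ])
        draws = rng.multivariate_normal(mus, cov, size=n)
        draws = np.clip(draws + shift[:, None], 0.0, 100.0)
        for j, form in enumerate(forms):
            for i in range(n):
                records.append({
                    "participant": f"P{i + 1:03d}",
                    "formulation": form,
                    "region": region,
                    "percent_missed": draws[i, j],
                    "sex": "male" if male[i] else "female",
                    "skin_type": skin[i],
                    "skin_group": "III+IV" if dark[i] else "I+II",
                    "age": age[i],
                    "order": order[i],
                    "canthus_left": "missed" if canthus[form][i] else "covered",
                    "canthus_right": "missed" if canthus[form][i] else "covered",
                })
    df = pd.DataFrame.from_records(records)
    return df.sort_values(
        ["participant", "formulation", "region"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixture output

def write_fixture_set(bundles: list[SyntheticParticipantBundle],
                      directory: str | Path) -> pd.DataFrame:
    """Write bundles to disk as PNG images, PTS landmarks and a CSV manifest.

    Layout per participant: ``<id>_baseline.png``, ``<id>_<condition>.png``,
    ``<id>_<condition>_truth.png`` (0/255 covered mask) and ``<id>.pts``.
    Returns the manifest, also written as ``manifest.csv``, with one row
    per (participant, condition).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    def save(img: UVImage, path: Path) -> None:
        Image.fromarray(img.pixels).save(path)

    rows = []
    for b in bundles:
        pid = b.spec.participant_id
        base_path = directory / f"{pid}_baseline.png"
        lm_path = directory / f"{pid}.pts"
        save(b.baseline_image, base_path)
        write_landmarks_pts(b.landmarks, lm_path)
        for cond, img in b.applied_images.items():
            app_path = directory / f"{pid}_{cond}.png"
            truth_path = directory / f"{pid}_{cond}_truth.png"
            save(img, app_path)
            write_mask_png(b.truth_masks[cond], truth_path)
            rows.append({
                "participant": pid,
                "condition": cond,
                "baseline": base_path.name,
                "applied": app_path.name,
                "truth": truth_path.name,
                "landmarks": lm_path.name,
                "skin_type": b.spec.skin_type,
                "sex": b.spec.sex,
                "age": b.spec.age,
                "base_intensity": b.spec.base_intensity,
                "noise_sd": b.spec.noise_sd,
                "applied_mass": b.spec.applied_mass,
                "height": b.spec.image_dims[0],
                "width": b.spec.image_dims[1],
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
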