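"""Synthetic implantation geometry: shafts, masks, and SOZ designation.

Anatomy is deliberately abstract: straight shafts enter a 1 mm isotropic
synthetic volume along outward directions (deep tip near their target), the
gray-matter probability volume is a smooth random field, and the resection is
a sphere whose volume follows the cohort distribution (17.08 +/- 4.19 cm^3).
Downstream analysis consumes only zone membership (SOZ / in-resection /
outside) and inter-channel distances, so the generator guarantees those:
every SOZ channel lies inside the resection, each zone contains gray-matter
channels, and every directed edge class needed by the feature taxonomy has at
least one admissible (different-shaft, >= 10 mm, gray recording) edge.  The
first two shafts sample the resection interior; the rest spread over the
surrounding volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import localization as loc
from .config import CohortConfig
from .errors import InvalidConfigError
from .localization import Contact, VolumeMask
from .preprocess import MIN_STIM_DISTANCE_MM
from .schema import CATEGORY_CLASSES

_MARGIN_MM = 3.0
_FEATURE_CLASSES = sorted({c for v in CATEGORY_CLASSES.values() for c in v})


@dataclass
class Geometry:
    """One patient's implantation: contacts, masks, SOZ ids, channel labels."""

    patient_id: str
    contacts: list
    gm: VolumeMask
    resection: VolumeMask
    soz_channel_ids: list
    channels: list = field(default_factory=list)
    labels: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def contact_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    patient_id=c.patient_id,
                    shaft=c.shaft_id,
                    contact_index=c.index_on_shaft,
                    x_mm=c.position[0],
                    y_mm=c.position[1],
                    z_mm=c.position[2],
                )
                for c in self.contacts
            ]
        )


def _smooth_field(rng: np.random.Generator, shape, coarse: int = 24) -> np.ndarray:
    """Unit-variance smooth random field via spline upsampling of coarse noise."""
    noise = rng.standard_normal((coarse,) * 3)
    zoom = [s / coarse for s in shape]
    f = ndimage.zoom(noise, zoom, order=1, mode="nearest", grid_mode=True)
    f = f[: shape[0], : shape[1], : shape[2]]
    return f / max(f.std(), 1e-9)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (d2 <= radius**2).astype(np.uint8)


def _fits(pos: np.ndarray, shape) -> bool:
    lo = np.full(3, _MARGIN_MM)
    hi = np.asarray(shape, float) - 1 - _MARGIN_MM
    return bool(np.all(pos >= lo) and np.all(pos <= hi))


def _force_gray_ball(gm_values: np.ndarray, center_mm: np.ndarray, radius: float = 2.5):
    c = np.floor(center_mm + 0.5).astype(int)
    r = int(np.ceil(radius))
    sl = tuple(slice(max(ci - r, 0), min(ci + r + 1, s)) for ci, s in zip(c, gm_values.shape))
    gm_values[sl] = 1.0


def sample_shaft_count(config: CohortConfig, rng: np.random.Generator) -> int:
    """Per-patient shaft count: rounded normal, clipped to the allowed range."""
    return int(
        np.clip(
            np.round(rng.normal(config.shafts_mean, config.shafts_sd)),
            config.shafts_range[0],
            config.shafts_range[1],
        )
    )


def _random_perp(rng, u):
    v = rng.standard_normal(3)
    v -= v @ u * u
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([u[1], -u[0], 0.0])


def _graze_shaft(res_center, radius, direction, n_inside, pitch):
    """A shaft whose deepest ``n_inside`` channel midpoints lie just inside
    the sphere (1.2 mm margin each side), the rest outside, tip-first along
    ``direction`` away from the resection centre."""
    t0 = radius - 2.0 - pitch * (n_inside - 1) - pitch / 2.0
    if t0 <= 0:
        return None
    return res_center + t0 * direction, direction


def _place_cohort_shafts(rng, config: CohortConfig, shape, res_center, radius, n_shafts):
    """Contact positions per shaft.

    Shaft 0 grazes the resection with exactly ``n_soz_channels`` midpoints
    inside (the SOZ), shaft 1 with ``n_ir_channels`` inside on roughly the
    opposite side; all remaining shafts stay entirely outside the sphere.
    Keeping the in-resection channel count this small keeps resection-crossing
    edges a small fraction of the pool (see module docstring).
    """
    pitch = config.contact_pitch_mm
    center = np.asarray(shape, float) / 2.0
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    shafts = []
    for s in range(n_shafts):
        n_c = int(rng.integers(config.contacts_range[0], config.contacts_range[1] + 1))
        placed = False
        for _ in range(80):
            if s == 0:
                d = -u + 0.1 * rng.standard_normal(3)
                d /= np.linalg.norm(d)
                got = _graze_shaft(res_center, radius, d, config.n_soz_channels, pitch)
            elif s == 1:
                d = u + 0.3 * _random_perp(rng, u) + 0.1 * rng.standard_normal(3)
                d /= np.linalg.norm(d)
                got = _graze_shaft(res_center, radius, d, config.n_ir_channels, pitch)
            else:
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                q = rng.uniform(radius + 6.0, radius + 26.0)
                tip = res_center + q * d
                axis = d + 0.4 * rng.standard_normal(3)
                axis /= np.linalg.norm(axis)
                got = (tip, axis)
            if got is None:
                return None
            tip, axis = got
            pos = tip[None, :] + np.arange(n_c)[:, None] * pitch * axis[None, :]
            if not _fits(pos, shape):
                continue
            if s >= 2:
                mids = 0.5 * (pos[:-1] + pos[1:])
                if np.linalg.norm(mids - res_center, axis=1).min() < radius + 1.2:
                    continue  # outside shafts must stay clear of the resection
            shafts.append(dict(dir=axis, pos=pos))
            placed = True
            break
        if not placed:
            return None
    return shafts


def _edge_class_feasible(midpoints, shaft_ids, zones, stim_zone, rec_zone):
    """Indices (s, r) of one admissible edge for the class, ignoring gray."""
    for s in range(len(zones)):
        if zones[s] != stim_zone:
            continue
        for r in range(len(zones)):
            if r == s or zones[r] != rec_zone or shaft_ids[r] == shaft_ids[s]:
                continue
            if np.linalg.norm(midpoints[r] - midpoints[s]) >= MIN_STIM_DISTANCE_MM:
                return s, r
    return None


def generate_geometry(config: CohortConfig, patient_seed: int, group: str = "SF") -> Geometry:
    """Generate one patient's geometry, masks and SOZ labels (deterministic)."""
    config.validate()
    rng = np.random.default_rng(int(patient_seed))
    shape = tuple(config.volume_shape)
    center = np.asarray(shape, float) / 2.0

    vol_cm3 = float(
        np.clip(
            rng.normal(config.resection_volume_mean_cm3, config.resection_volume_sd_cm3),
            6.0,
            32.0,
        )
    )
    radius = (3.0 * vol_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    last_err = "no attempt"
    for _attempt in range(40):
        res_center = center + rng.uniform(-6.0, 6.0, size=3)
        n_shafts = sample_shaft_count(config, rng)
        shafts = _place_cohort_shafts(rng, config, shape, res_center, radius, n_shafts)
        if shafts is None:
            last_err = "shaft placement failed"
            continue

        patient_id = f"P{int(patient_seed) % 10**8:08d}"
        contacts: list[Contact] = []
        for s, sh in enumerate(shafts):
            shaft_id = chr(ord("A") + s) if s < 26 else f"S{s}"
            contacts.extend(
                Contact(patient_id, shaft_id, k + 1, tuple(sh["pos"][k]))
                for k in range(len(sh["pos"]))
            )
        channels = loc.make_bipolar_channels(contacts)
        midpoints = np.array([ch.midpoint for ch in channels])
        shaft_ids = [ch.shaft_id for ch in channels]
        # nearest-voxel membership, exactly as label_resection evaluates it
        in_res = np.linalg.norm(np.floor(midpoints + 0.5) - res_center, axis=1) <= radius

        # SOZ = shaft A's in-resection channels; shaft B supplies the
        # in-resection non-SOZ channels; other shafts must stay outside
        a_in = [i for i in range(len(channels)) if shaft_ids[i] == "A" and in_res[i]]
        b_in = [i for i in range(len(channels)) if shaft_ids[i] == "B" and in_res[i]]
        other_in = [
            i for i in range(len(channels))
            if in_res[i] and shaft_ids[i] not in ("A", "B")
        ]
        if len(a_in) != config.n_soz_channels or len(b_in) != config.n_ir_channels:
            last_err = (
                f"in-resection channel counts off target (A={len(a_in)}, B={len(b_in)})"
            )
            continue
        if other_in:
            last_err = "an outside shaft crossed the resection"
            continue
        soz_idx = a_in
        zones = [
            "soz" if i in soz_idx else ("ir" if in_res[i] else "or")
            for i in range(len(channels))
        ]

        feasible = {}
        for cls_ in _FEATURE_CLASSES:
            pair = _edge_class_feasible(midpoints, shaft_ids, zones, *cls_)
            if pair is None:
                break
            feasible[cls_] = pair
        else:
            break  # all six classes admissible
        last_err = f"no admissible edge for class {cls_}"
    else:
        raise InvalidConfigError(
            f"could not realize a feasible geometry in 40 attempts ({last_err})"
        )

    res_values = _sphere_mask(shape, res_center, radius)
    n_vox = int(res_values.sum())
    target_vox = vol_cm3 * 1000.0 / config.voxel_mm**3
    if abs(n_vox - target_vox) > 0.2 * target_vox:
        raise InvalidConfigError("resection voxelization missed the target volume by >20%")

    f = _smooth_field(rng, shape)
    gm_values = np.clip(0.35 + 0.35 * f, 0.0, 1.0)
    # gray-matter guarantees: SOZ channels and one admissible recording partner
    # per feature class, plus one per zone
    for i in soz_idx:
        _force_gray_ball(gm_values, midpoints[i])
    for s, r in feasible.values():
        _force_gray_ball(gm_values, midpoints[r])
    for zone in ("ir", "or"):
        cand = [i for i, z in enumerate(zones) if z == zone]
        _force_gray_ball(gm_values, midpoints[cand[int(rng.integers(len(cand)))]])

    gm = VolumeMask(gm_values, np.eye(4))
    resection = VolumeMask(res_values, np.eye(4))
    soz_ids = [channels[i].channel_id for i in soz_idx]
    labels = loc.label_channels(channels, gm, resection, soz_ids)

    return Geometry(
        patient_id=patient_id,
        contacts=contacts,
        gm=gm,
        resection=resection,
        soz_channel_ids=soz_ids,
        channels=channels,
        labels=labels,
        meta=dict(
            group=group,
            n_shafts=n_shafts,
            resection_volume_cm3=vol_cm3,
            resection_voxels=n_vox,
            resection_radius_mm=float(radius),
            seed=int(patient_seed),
        ),
    )
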