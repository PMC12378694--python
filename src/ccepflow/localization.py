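"""Bipolar channel derivation and anatomical labelling.

Depth-electrode contacts are paired along each shaft; the midpoint between
adjacent contacts is the bipolar channel's position.  A channel counts as gray
matter when the 3x3x3 voxel cube centred on its midpoint voxel contains at
least 24 voxels whose gray-matter probability exceeds 0.1, as resection-side
when its midpoint voxel lies inside the binary resection mask, and as SOZ when
clinically designated (SOZ channels must lie inside the resection).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidInputError, OutOfBoundsError

logger = logging.getLogger(__name__)

GM_PROB_THRESHOLD = 0.1
GM_CUBE_MIN_VOXELS = 24


@dataclass
class VolumeMask:
    """A 3-D probability or binary volume with a voxel->mm affine."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 3:
            raise InvalidInputError("volume must be 3-D with dims >= 3")
        if self.values.min() < 0 or self.values.max() > 1:
            raise InvalidInputError("volume values must lie in [0, 1]")

    @property
    def is_binary(self) -> bool:
        v = self.values
        return bool(np.all((v == 0) | (v == 1)))

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel index for mm coordinates (half-up rounding)."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        vox = (inv[:3, :3] @ xyz.T).T + inv[:3, 3]
        return np.floor(vox + 0.5).astype(int)  # half-up, not banker's

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class Contact:
    patient_id: str
    shaft_id: str
    index_on_shaft: int
    position: tuple  # (x, y, z) mm


@dataclass
class BipolarChannel:
    contact_lo: Contact
    contact_hi: Contact
    midpoint: np.ndarray
    is_gray: bool = False
    in_resection: bool = False
    is_soz: bool = False

    @property
    def channel_id(self) -> str:
        return f"{self.contact_lo.shaft_id}{self.contact_lo.index_on_shaft}-{self.contact_hi.index_on_shaft}"

    @property
    def shaft_id(self) -> str:
        return self.contact_lo.shaft_id


def make_bipolar_channels(contacts: Sequence[Contact]) -> list[BipolarChannel]:
    """One channel per adjacent same-shaft contact pair (k contacts -> k-1)."""
    by_shaft: dict[str, list[Contact]] = {}
    for c in contacts:
        by_shaft.setdefault(c.shaft_id, []).append(c)
    channels: list[BipolarChannel] = []
    for shaft_id in sorted(by_shaft):
        shaft = sorted(by_shaft[shaft_id], key=lambda c: c.index_on_shaft)
        if len(shaft) < 2:
            warnings.warn(f"shaft {shaft_id} has <2 contacts, skipped", stacklevel=2)
            continue
        for lo, hi in zip(shaft[:-1], shaft[1:]):
            mid = 0.5 * (np.asarray(lo.position) + np.asarray(hi.position))
            channels.append(BipolarChannel(contact_lo=lo, contact_hi=hi, midpoint=mid))
    return channels


def classify_gray_matter(
    channel: BipolarChannel, gm: VolumeMask, threshold: float = GM_PROB_THRESHOLD
) -> bool:
    """Cube rule: >=24 of the 27 voxels around the midpoint voxel are gray."""
    ijk = gm.mm_to_voxel(channel.midpoint)[0]
    shape = np.asarray(gm.values.shape)
    if np.any(ijk < 1) or np.any(ijk > shape - 2):
        raise OutOfBoundsError(
            f"midpoint voxel {tuple(ijk)} lacks a 1-voxel margin in volume {tuple(shape)}"
        )
    cube = gm.values[ijk[0] - 1 : ijk[0] + 2, ijk[1] - 1 : ijk[1] + 2, ijk[2] - 1 : ijk[2] + 2]
    return int(np.count_nonzero(cube > threshold)) >= GM_CUBE_MIN_VOXELS


def label_resection(channel: BipolarChannel, resection: VolumeMask) -> bool:
    """True iff the midpoint's nearest voxel lies inside the binary mask."""
    if not resection.is_binary:
        raise InvalidInputError("resection mask must be binary")
    ijk = resection.mm_to_voxel(channel.midpoint)[0]
    shape = np.asarray(resection.values.shape)
    if np.any(ijk < 0) or np.any(ijk >= shape):
        raise OutOfBoundsError(f"midpoint voxel {tuple(ijk)} outside volume {tuple(shape)}")
    return bool(resection.values[tuple(ijk)])


def dice_coefficient(a: VolumeMask, b: VolumeMask) -> float:
    """2|A n B| / (|A| + |B|); defined as 1.0 when both masks are empty."""
    if a.values.shape != b.values.shape:
        raise InvalidInputError("mask shapes differ")
    if not (a.is_binary and b.is_binary):
        raise InvalidInputError("dice requires binary masks")
    na, nb = int(a.values.sum()), int(b.values.sum())
    if na + nb == 0:
        logger.info("dice of two empty masks: returning 1.0 by convention")
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def label_channels(
    channels: Sequence[BipolarChannel],
    gm: VolumeMask,
    resection: VolumeMask,
    soz_channel_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Label every channel and return the per-channel table.

    SOZ designation must be consistent with resection membership.
    """
    if not resection.is_binary:
        raise InvalidInputError("resection mask must be binary")
    soz_set = set(soz_channel_ids)
    rows = []
    for i, ch in enumerate(channels):
        ch.is_gray = classify_gray_matter(ch, gm)
        ijk = resection.mm_to_voxel(ch.midpoint)[0]
        ch.in_resection = bool(resection.values[tuple(ijk)])
        ch.is_soz = ch.channel_id in soz_set
        if ch.is_soz and not ch.in_resection:
            raise ConsistencyError(f"SOZ channel {ch.channel_id} lies outside the resection")
        rows.append(
            dict(
                channel_index=i,
                channel_id=ch.channel_id,
                shaft_id=ch.shaft_id,
                x_mm=ch.midpoint[0],
                y_mm=ch.midpoint[1],
                z_mm=ch.midpoint[2],
                is_gray=ch.is_gray,
                in_resection=ch.in_resection,
                is_soz=ch.is_soz,
            )
        )
    return pd.DataFrame(rows)


def channel_zone(row) -> str:
    """Zone of a labelled channel: soz, ir (in-resection non-SOZ), or or."""
    if row["is_soz"]:
        return "soz"
    return "ir" if row["in_resection"] else "or"


def soz_distance_profile(labels: pd.DataFrame) -> pd.DataFrame:
    """Minimum distance from each non-SOZ gray channel to any SOZ channel.

    Returns a frame with columns channel_id, distance_mm, in_resection.
    """
    soz = labels[labels["is_soz"]]
    if len(soz) == 0:
        raise InvalidInputError("no SOZ channels")
    others = labels[(~labels["is_soz"]) & labels["is_gray"]]
    soz_xyz = soz[["x_mm", "y_mm", "z_mm"]].to_numpy()
    oth_xyz = others[["x_mm", "y_mm", "z_mm"]].to_numpy()
    d = np.linalg.norm(oth_xyz[:, None, :] - soz_xyz[None, :, :], axis=2).min(axis=1)
    return pd.DataFrame(
        {
            "channel_id": others["channel_id"].to_numpy(),
            "distance_mm": d,
            "in_resection": others["in_resection"].to_numpy(),
        }
    )
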