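"""Heatable body regions of the neonatal phantom.

The phantom surface is divided into 13 individually controllable heating
regions: two on the head, three on the torso and an upper/lower segment on
each of the four limbs.
"""

from __future__ import annotations

from enum import Enum


class RegionId(str, Enum):
    """One of the 13 heatable regions."""

    HEAD_FRONT = "head_front"
    HEAD_BACK = "head_back"
    TORSO_UPPER = "torso_upper"
    TORSO_MID = "torso_mid"
    TORSO_LOWER = "torso_lower"
    LEFT_ARM_UPPER = "left_arm_upper"
    LEFT_ARM_LOWER = "left_arm_lower"
    RIGHT_ARM_UPPER = "right_arm_upper"
    RIGHT_ARM_LOWER = "right_arm_lower"
    LEFT_LEG_UPPER = "left_leg_upper"
    LEFT_LEG_LOWER = "left_leg_lower"
    RIGHT_LEG_UPPER = "right_leg_upper"
    RIGHT_LEG_LOWER = "right_leg_lower"

    @property
    def group(self) -> str:
        """Body-part group: ``head``, ``torso`` or ``limb``."""
        if self in (RegionId.HEAD_FRONT, RegionId.HEAD_BACK):
            return "head"
        if self in (RegionId.TORSO_UPPER, RegionId.TORSO_MID, RegionId.TORSO_LOWER):
            return "torso"
        return "limb"


HEAD_REGIONS = (RegionId.HEAD_FRONT, RegionId.HEAD_BACK)
TORSO_REGIONS = (RegionId.TORSO_UPPER, RegionId.TORSO_MID, RegionId.TORSO_LOWER)
LIMB_REGIONS = tuple(r for r in RegionId if r.group == "limb")
LIMB_LOWER_REGIONS = tuple(r for r in LIMB_REGIONS if r.value.endswith("_lower"))
ALL_REGIONS = tuple(RegionId)
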