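"""In-memory container for a registered multi-channel 2-D image."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel roles, in the order synthetic scenes are written.
CHANNEL_ROLES = ("hoechst", "gal9", "sc35", "pdna")


@dataclass
class ChannelStack:
    """A registered multi-channel 2-D fluorescence image.

    Parameters
    ----------
    planes
        List of 2-D intensity arrays, all of the same shape.  Intensities
        are kept in their native dtype; no rescaling is applied anywhere.
    roles
        Map from semantic role (``hoechst``, ``gal9``, ``sc35``, ``pdna``)
        to plane index.  ``hoechst`` is required for segmentation; the
        others are optional.
    pixel_size_um
        Lateral pixel size in micrometres per pixel (> 0).
    source_id
        Identifier for the originating file or synthetic scene; used to
        order and join result tables.
    """

    planes: list[np.ndarray]
    roles: dict[str, int]
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ChannelStack needs at least one plane")
        shape = self.planes[0].shape
        for i, p in enumerate(self.planes):
            if p.ndim != 2:
                raise ValueError(f"plane {i} is not 2-D")
            if p.shape != shape:
                raise ValueError(
                    f"plane {i} shape {p.shape} differs from {shape}"
                )
        for role, idx in self.roles.items():
            if not 0 <= idx < len(self.planes):
                raise ValueError(
                    f"role {role!r} maps to plane {idx}, but the stack has "
                    f"{len(self.planes)} plane(s)"
                )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    def plane(self, role: str) -> np.ndarray:
        """Return the plane bound to `role`."""
        if role not in self.roles:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.planes[self.roles[role]]

    def has_role(self, role: str) -> bool:
        return role in self.roles
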