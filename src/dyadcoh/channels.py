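"""Channel geometry and the default dual-cap montage.

Long-separation channels (LSCs) sample cortical plus extracerebral
haemodynamics; short-separation channels (SSCs, ~10 mm) sample only the
superficial scalp layer.  LSCs are grouped into four regions of interest:
left/right prefrontal cortex and left/right temporoparietal junction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

ROIS = ("lPFC", "rPFC", "lTPJ", "rTPJ")

#: Separation (mm) at or below which a channel counts as short-separation.
SHORT_SEPARATION_MM = 15.0

#: Default LSC separations by participant role (mm).
LSC_SEPARATION_MM = {"child": 25.0, "mother": 30.0}
SSC_SEPARATION_MM = 10.0


@dataclass(frozen=True)
class ChannelInfo:
    """One source-detector pair.

    ``kind`` is ``"short"`` iff ``separation <= 15 mm``; every long channel
    belongs to a region of interest, short channels carry the ROI they are
    placed over (left PFC and right TPJ in the default montage) but are never
    analysed as cortical units.
    """

    id: str
    source: int
    detector: int
    separation: float
    kind: str  # {"long", "short"}
    roi: str  # {"lPFC", "rPFC", "lTPJ", "rTPJ", "none"}
    valid: bool = True

    def __post_init__(self) -> None:
        expected = "short" if self.separation <= SHORT_SEPARATION_MM else "long"
        if self.kind != expected:
            raise ValueError(
                f"channel {self.id}: kind {self.kind!r} inconsistent with "
                f"separation {self.separation} mm"
            )

    def invalidated(self) -> "ChannelInfo":
        return replace(self, valid=False)


def default_montage(role: str, n_lsc: int = 16, n_ssc: int = 2) -> list[ChannelInfo]:
    """Build the default cap: ``n_lsc`` long channels spread evenly over the
    four ROIs plus ``n_ssc`` short channels (left PFC then right TPJ).

    Source/detector indices are dedicated per channel; optode sharing is a
    cap-geometry detail outside this package's scope.
    """
    if role not in LSC_SEPARATION_MM:
        raise ValueError(f"unknown role {role!r}")
    if n_lsc < 1 or n_ssc < 0:
        raise ValueError("need >=1 long channel and >=0 short channels")
    sep = LSC_SEPARATION_MM[role]
    chans: list[ChannelInfo] = []
    for i in range(n_lsc):
        roi = ROIS[(i * len(ROIS)) // n_lsc]
        chans.append(
            ChannelInfo(
                id=f"{role[0].upper()}{i + 1:02d}",
                source=i + 1,
                detector=i + 1,
                separation=sep,
                kind="long",
                roi=roi,
            )
        )
    ssc_rois = ("lPFC", "rTPJ")
    for j in range(n_ssc):
        chans.append(
            ChannelInfo(
                id=f"{role[0].upper()}S{j + 1}",
                source=n_lsc + j + 1,
                detector=n_lsc + j + 1,
                separation=SSC_SEPARATION_MM,
                kind="short",
                roi=ssc_rois[j % len(ssc_rois)],
            )
        )
    return chans


def long_channels(channels: list[ChannelInfo], valid_only: bool = False) -> list[ChannelInfo]:
    out = [c for c in channels if c.kind == "long"]
    return [c for c in out if c.valid] if valid_only else out


def short_channels(channels: list[ChannelInfo], valid_only: bool = False) -> list[ChannelInfo]:
    out = [c for c in channels if c.kind == "short"]
    return [c for c in out if c.valid] if valid_only else out
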