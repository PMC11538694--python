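"""Electrode montages: channel labels and their cortical region assignment.

Analysis operates on four scalp regions -- frontal, parietal, temporal and
occipital.  Both partners of a dyad wear 16-electrode caps with the same
region vocabulary; individual channels can be flagged as excluded from
analysis (e.g. temporal channels on the dog-role montage, which are not
usable in practice) while still being generated and stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = ("frontal", "parietal", "temporal", "occipital")


@dataclass(frozen=True)
class Montage:
    """Mapping of channel labels to scalp regions.

    Parameters
    ----------
    channel_names:
        Ordered channel labels; the order matches rows of a Recording.
    region_of:
        Label -> region; every channel maps to exactly one region.
    excluded:
        Channels generated/recorded but excluded from analysis.
    """

    channel_names: tuple[str, ...]
    region_of: dict[str, str]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for ch in self.channel_names:
            if ch not in self.region_of:
                raise ValueError(f"channel {ch!r} has no region assignment")
            if self.region_of[ch] not in REGIONS:
                raise ValueError(
                    f"channel {ch!r} assigned to unknown region "
                    f"{self.region_of[ch]!r}; expected one of {REGIONS}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(r for r in REGIONS if any(self.region_of[c] == r for c in self.channel_names))

    def channels_in(self, region: str, usable_only: bool = True) -> list[str]:
        chans = [c for c in self.channel_names if self.region_of[c] == region]
        if usable_only:
            chans = [c for c in chans if c not in self.excluded]
        return chans

    def indices_in(self, region: str, usable_only: bool = True) -> list[int]:
        names = self.channels_in(region, usable_only=usable_only)
        return [self.channel_names.index(c) for c in names]

    # ------------------------------------------------------------------ #

    @classmethod
    def standard(cls, channels_per_region: int = 4, exclude_regions: tuple[str, ...] = ()) -> "Montage":
        """A symmetric montage with ``channels_per_region`` channels per region.

        The default (4 per region) gives the 16-channel layout used
        throughout; ``channels_per_region=1`` gives a minimal 4-channel
        montage handy for large simulation sweeps.
        """
        if channels_per_region < 1:
            raise ValueError("channels_per_region must be >= 1")
        prefix = {"frontal": "F", "parietal": "P", "temporal": "T", "occipital": "O"}
        names: list[str] = []
        region_of: dict[str, str] = {}
        for region in REGIONS:
            for i in range(1, channels_per_region + 1):
                name = f"{prefix[region]}{i}"
                names.append(name)
                region_of[name] = region
        excluded = frozenset(n for n in names if region_of[n] in exclude_regions)
        return cls(tuple(names), region_of, excluded)

    @classmethod
    def human_16(cls) -> "Montage":
        return cls.standard(4)

    @classmethod
    def dog_16(cls) -> "Montage":
        # Dog temporal channels are recorded but not analyzable.
        return cls.standard(4, exclude_regions=("temporal",))
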