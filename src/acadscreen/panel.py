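"""Analyte panel model for a dried-blood-spot tandem-MS screening assay.

The default panel mirrors a non-derivatized expanded newborn-screening kit:
43 channels comprising 11 amino acids, 30 acylcarnitines, free carnitine
(C0) and succinylacetone (SA).  Isobaric acylcarnitine species that the
assay cannot resolve are reported as compound channels whose names join the
two species with ``+`` (e.g. ``C5DC+C6-OH``); ``/`` is reserved for ratio
feature names and never appears in a channel identifier.

Channel order is fixed and versioned: downstream ratio-feature indices and
canonical ratio orientation both depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import yaml

KINDS = ("amino-acid", "acylcarnitine", "free-carnitine", "succinylacetone")

#: Panel layout version; bump whenever channel identity or order changes.
PANEL_VERSION = "1.0"


@dataclass(frozen=True)
class Channel:
    """A single measured channel: identifier, analyte class and unit."""

    name: str
    kind: str
    unit: str = "nmol/L"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r} for {self.name!r}")
        if "/" in self.name:
            raise ValueError(f"channel name {self.name!r} may not contain '/'")


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered, immutable catalogue of measured channels.

    Parameters
    ----------
    channels : tuple of Channel
        Measurement channels in their fixed, versioned order.
    version : str
        Layout version tag carried into provenance records.
    """

    channels: tuple[Channel, ...]
    version: str = PANEL_VERSION
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self) -> Iterator[Channel]:
        return iter(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in panel") from None

    def kind_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in KINDS}
        for c in self.channels:
            counts[c.kind] += 1
        return counts

    def to_yaml(self, path) -> None:
        doc = {
            "version": self.version,
            "channels": [
                {"name": c.name, "kind": c.kind, "unit": c.unit} for c in self.channels
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalytePanel":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        channels = tuple(
            Channel(d["name"], d["kind"], d.get("unit", "nmol/L"))
            for d in doc["channels"]
        )
        return cls(channels=channels, version=str(doc.get("version", PANEL_VERSION)))

    @classmethod
    def from_names(cls, names: Iterable[str], kind: str = "acylcarnitine",
                   unit: str = "nmol/L") -> "AnalytePanel":
        """Build an ad-hoc panel (mainly for tests and small examples)."""
        return cls(tuple(Channel(n, kind, unit) for n in names), version="adhoc")


# 11 amino acids quantified by the non-derivatized DBS assay.
_AMINO_ACIDS = (
    "Ala", "Arg", "Cit", "Gly", "Leu", "Met", "Orn", "Phe", "Pro", "Tyr", "Val",
)

# 30 acylcarnitines in carbon-number order; compound names are isobaric
# species the assay reports as a single summed channel.
_ACYLCARNITINES = (
    "C2", "C3", "C3DC+C4-OH", "C4", "C4DC+C5-OH", "C5", "C5:1", "C5DC+C6-OH",
    "C6", "C6DC", "C8", "C8:1", "C10", "C10:1", "C10:2", "C12", "C12:1",
    "C14", "C14:1", "C14:2", "C14-OH", "C16", "C16:1", "C16:1-OH", "C16-OH",
    "C18", "C18:1", "C18:1-OH", "C18:2", "C18-OH",
)

# Channels every screening rule or selected ratio in this package may rely on.
REQUIRED_CHANNELS = (
    "C2", "C4", "C6", "C8", "C8:1", "C14:1", "C16", "C16-OH",
    "C4DC+C5-OH", "C5DC+C6-OH",
)


def default_panel() -> AnalytePanel:
    """The versioned 43-channel default panel.

    11 amino acids + 30 acylcarnitines + free carnitine (C0) +
    succinylacetone (SA).  Amino acids come first, then acylcarnitines in
    carbon order, then C0 and SA; ratio-feature indices depend on this order.
    """
    channels = (
        tuple(Channel(n, "amino-acid", "µmol/L") for n in _AMINO_ACIDS)
        + tuple(Channel(n, "acylcarnitine") for n in _ACYLCARNITINES)
        + (Channel("C0", "free-carnitine"), Channel("SA", "succinylacetone"))
    )
    panel = AnalytePanel(channels)
    assert len(panel) == 43
    return panel
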