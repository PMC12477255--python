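"""Panel and barcode-scheme definitions.

A *panel* maps marker short names to metal channels and assigns each channel a
role (phenotype, signaling, barcode, bead, time).  The default panel is a
synthetic stand-in for a 40+ antibody mass-cytometry panel: 14 phenotyping
markers sufficient for the default gate tree, 15 phospho/total signaling
markers, 6 palladium barcode channels and 5 dedicated bead channels whose
metals do not collide with any antibody channel.

A *barcode scheme* maps sample identifiers to k-of-n binary palladium codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

ROLES = ("phenotype", "signaling", "barcode", "bead", "time")

TIME_CHANNEL = "Time"


@dataclass(frozen=True)
class Channel:
    name: str
    metal: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class Panel:
    """Ordered channel list with role-based accessors."""

    channels: list[Channel]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in panel")

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return [c.name for c in self.channels]
        return [c.name for c in self.channels if c.role == role]

    @property
    def phenotype_channels(self) -> list[str]:
        return self.names("phenotype")

    @property
    def signaling_channels(self) -> list[str]:
        return self.names("signaling")

    @property
    def barcode_channels(self) -> list[str]:
        return self.names("barcode")

    @property
    def bead_channels(self) -> list[str]:
        return self.names("bead")

    @property
    def measurement_channels(self) -> list[str]:
        """All non-time channels, in panel order."""
        return [c.name for c in self.channels if c.role != "time"]

    def metal(self, name: str) -> str:
        for c in self.channels:
            if c.name == name:
                return c.metal
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "channels": [
                {"name": c.name, "metal": c.metal, "role": c.role}
                for c in self.channels
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        return cls([Channel(**c) for c in d["channels"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: default phenotyping markers and (synthetic) metal assignments
_PHENOTYPE = [
    ("CD45", "Y89Di"),
    ("CD66", "Gd158Di"),
    ("CD3", "Gd157Di"),
    ("CD4", "Gd156Di"),
    ("CD8", "Gd155Di"),
    ("CD20", "Dy161Di"),
    ("IgM", "Yb174Di"),
    ("CD56", "Lu175Di"),
    ("CD16", "Tb159Di"),
    ("CD14", "Nd144Di"),
    ("CD11b", "Eu153Di"),
    ("CD11c", "Er167Di"),
    ("CD123", "Nd148Di"),
    ("HLA-DR", "Yb176Di"),
    ("Ki67", "Er168Di"),
]

#: 15 intracellular signaling markers
_SIGNALING = [
    ("pSTAT1", "Eu151Di"),
    ("pSTAT3", "Sm147Di"),
    ("pSTAT4", "Nd145Di"),
    ("pSTAT5", "Nd150Di"),
    ("pSTAT6", "Sm149Di"),
    ("pErk1/2", "Er166Di"),
    ("pMAPKAP2", "Ho165Di"),
    ("pCREB", "Yb171Di"),
    ("IkBa", "Dy164Di"),
    ("pTBK1", "Dy162Di"),
    ("pS6", "Yb172Di"),
    ("pZap70/Syk", "Dy160Di"),
    ("p4EBP1", "Yb173Di"),
    ("pPLCg2", "Sm152Di"),
    ("pP38", "Dy163Di"),
]

_BARCODE = [(f"BC{i+1}", m) for i, m in enumerate(
    ["Pd102Di", "Pd104Di", "Pd105Di", "Pd106Di", "Pd108Di", "Pd110Di"])]

# bead metals chosen disjoint from every antibody channel above
_BEAD = [(f"Bead{i+1}", m) for i, m in enumerate(
    ["Ce140Di", "In113Di", "In115Di", "Tm169Di", "Lu176Di"])]


def default_panel() -> Panel:
    chans = (
        [Channel(n, m, "phenotype") for n, m in _PHENOTYPE]
        + [Channel(n, m, "signaling") for n, m in _SIGNALING]
        + [Channel(n, m, "barcode") for n, m in _BARCODE]
        + [Channel(n, m, "bead") for n, m in _BEAD]
        + [Channel(TIME_CHANNEL, "Time", "time")]
    )
    return Panel(chans)


@dataclass
class BarcodeScheme:
    """k-of-n binary barcoding: sample id -> tuple of 0/1 over n channels."""

    codes: dict[str, tuple[int, ...]]
    k: int = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("empty barcode scheme")
        lengths = {len(c) for c in self.codes.values()}
        if len(lengths) != 1:
            raise ValueError("codes of unequal length")
        self.n = lengths.pop()
        ks = {int(sum(c)) for c in self.codes.values()}
        if len(ks) != 1:
            raise ValueError("codes with differing numbers of set bits")
        self.k = ks.pop()
        if self.k >= self.n:
            raise ValueError(f"k={self.k} must be < n={self.n}")
        if len(set(self.codes.values())) != len(self.codes):
            raise ValueError("duplicate codes in scheme")

    def lookup(self, code: tuple[int, ...]) -> str | None:
        for sid, c in self.codes.items():
            if c == code:
                return sid
        return None

    @property
    def code_matrix(self) -> np.ndarray:
        return np.array(list(self.codes.values()), dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.keys())

    def to_dict(self) -> dict:
        return {"codes": {s: list(c) for s, c in self.codes.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeScheme":
        return cls({s: tuple(int(b) for b in c) for s, c in d["codes"].items()})


def default_scheme(sample_ids: list[str], n: int = 6, k: int = 3) -> BarcodeScheme:
    """Assign the first len(sample_ids) k-of-n codes in lexicographic order.

    The 6-choose-3 palladium scheme yields 20 codes; batches of 16 samples
    use the first 16.
    """
    all_codes = []
    for ones in itertools.combinations(range(n), k):
        code = [0] * n
        for i in ones:
            code[i] = 1
        all_codes.append(tuple(code))
    if len(sample_ids) > len(all_codes):
        raise ValueError(
            f"{len(sample_ids)} samples exceed {len(all_codes)} available "
            f"{k}-of-{n} codes")
    return BarcodeScheme(dict(zip(sample_ids, all_codes)))
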