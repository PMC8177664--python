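"""PI analyte panel definition and MRM transition arithmetic.

Analytes are diacyl-phosphatidylinositol (PI) species, named either by sum
composition ("PI 36:2") or with resolved acyl chains ("PI(18:0|18:2)").
Transitions are computed for negative-mode MRM: the precursor is the
[M-H]- ion of the neutral diacyl-PI and the product is the fatty-acyl
carboxylate anion [RCOO]- of one chain.

The elemental formula of a diacyl-PI with total acyl carbon count C and
total double bonds D is C(9+C) H(15+2C-2D) O13 P (glycerol + inositol +
phosphate + two fatty acids, minus four waters of condensation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

from .constants import MASS_C, MASS_ELECTRON, MASS_H, MASS_O, MASS_P, MASS_PROTON


@dataclass(frozen=True)
class AcylChain:
    """One fatty-acyl chain: carbon count and number of C=C double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"chain double bonds must be >= 0, got {self.double_bonds}")

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        c, _, d = text.strip().partition(":")
        return cls(int(c), int(d))

    @property
    def carboxylate_mz(self) -> float:
        """Monoisotopic m/z of the [RCOO]- carboxylate anion of this chain."""
        n, d = self.carbons, self.double_bonds
        return n * MASS_C + (2 * n - 2 * d - 1) * MASS_H + 2 * MASS_O + MASS_ELECTRON


@dataclass(frozen=True)
class PiSpecies:
    """A diacyl-PI analyte, optionally with resolved sn1/sn2 chains."""

    name: str
    total_carbons: int
    total_double_bonds: int
    sn1: Optional[AcylChain] = None
    sn2: Optional[AcylChain] = None
    is_surrogate: bool = False
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.total_carbons < 2:
            raise ValueError("total_carbons must be >= 2")
        if self.total_double_bonds < 0:
            raise ValueError("total_double_bonds must be >= 0")
        if (self.sn1 is None) != (self.sn2 is None):
            raise ValueError("sn1 and sn2 must be specified together")
        if self.sn1 is not None and self.sn2 is not None:
            if self.sn1.carbons + self.sn2.carbons != self.total_carbons:
                raise ValueError(
                    f"{self.name}: sn1+sn2 carbons "
                    f"({self.sn1.carbons}+{self.sn2.carbons}) != {self.total_carbons}"
                )
            if self.sn1.double_bonds + self.sn2.double_bonds != self.total_double_bonds:
                raise ValueError(
                    f"{self.name}: sn1+sn2 double bonds != {self.total_double_bonds}"
                )

    @property
    def role(self) -> str:
        if self.is_internal_standard:
            return "IS"
        if self.is_surrogate:
            return "SA"
        return "endogenous"

    @classmethod
    def from_chains(
        cls,
        sn1: str | AcylChain,
        sn2: str | AcylChain,
        *,
        is_surrogate: bool = False,
        is_internal_standard: bool = False,
    ) -> "PiSpecies":
        c1 = sn1 if isinstance(sn1, AcylChain) else AcylChain.parse(sn1)
        c2 = sn2 if isinstance(sn2, AcylChain) else AcylChain.parse(sn2)
        return cls(
            name=f"PI({c1}|{c2})",
            total_carbons=c1.carbons + c2.carbons,
            total_double_bonds=c1.double_bonds + c2.double_bonds,
            sn1=c1,
            sn2=c2,
            is_surrogate=is_surrogate,
            is_internal_standard=is_internal_standard,
        )

    @classmethod
    def from_sum(cls, total_carbons: int, total_double_bonds: int) -> "PiSpecies":
        return cls(
            name=f"PI {total_carbons}:{total_double_bonds}",
            total_carbons=total_carbons,
            total_double_bonds=total_double_bonds,
        )


@dataclass(frozen=True)
class MrmTransition:
    """A negative-mode MRM transition: [M-H]- precursor -> [RCOO]- product."""

    precursor_mz: float
    product_mz: float
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.product_mz >= self.precursor_mz:
            raise ValueError("product m/z must be below precursor m/z")


def neutral_pi_mass(total_carbons: int, total_double_bonds: int) -> float:
    """Monoisotopic mass of the neutral diacyl-PI C(9+C) H(15+2C-2D) O13 P."""
    n_c = 9 + total_carbons
    n_h = 15 + 2 * total_carbons - 2 * total_double_bonds
    if n_h <= 0:
        raise ValueError("unsaturation too high for carbon count")
    return n_c * MASS_C + n_h * MASS_H + 13 * MASS_O + MASS_P


def precursor_mz(species: PiSpecies) -> float:
    """[M-H]- m/z of a diacyl-PI species (neutral mass minus one proton)."""
    return neutral_pi_mass(species.total_carbons, species.total_double_bonds) - MASS_PROTON


def compute_transition(species: PiSpecies, product_chain: str | AcylChain) -> MrmTransition:
    """MRM transition for one species and one product acyl chain.

    Parameters
    ----------
    species
        The PI analyte; chains need not be resolved unless ``product_chain``
        is given as ``"sn1"``/``"sn2"``.
    product_chain
        ``"sn1"``, ``"sn2"``, a chain spec string such as ``"18:1"``, or an
        :class:`AcylChain`. The product ion is that chain's carboxylate anion.
    """
    if isinstance(product_chain, AcylChain):
        chain = product_chain
    elif product_chain in ("sn1", "sn2"):
        chain = getattr(species, product_chain)
        if chain is None:
            raise ValueError(
                f"species {species.name!r} has no resolved {product_chain} chain"
            )
    else:
        try:
            chain = AcylChain.parse(product_chain)
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"unknown product_chain spec {product_chain!r}") from exc
    if chain.carbons >= species.total_carbons:
        raise ValueError(
            f"product chain {chain} does not fit within {species.name}"
        )
    return MrmTransition(
        precursor_mz=round(precursor_mz(species), 4),
        product_mz=round(chain.carboxylate_mz, 4),
    )


def enumerate_pi_species(c_min: int, c_max: int, db_max: int) -> list[PiSpecies]:
    """Enumerate sum-composition PI species over a carbon/unsaturation grid.

    Returns one species per (total carbons, double bonds) pair with carbons
    in [c_min, c_max] and double bonds in [0, db_max], sorted by (C, DB).
    This reproduces the transition-list prediction step used to screen for
    detectable plasma PI (total chain length 30-40, unsaturation up to 6
    covers the abundant diacyl species).
    """
    if c_min > c_max:
        raise ValueError(f"c_min ({c_min}) must be <= c_max ({c_max})")
    if c_min < 2:
        raise ValueError("c_min must be >= 2")
    if db_max < 0:
        raise ValueError(f"db_max must be >= 0, got {db_max}")
    return [
        PiSpecies.from_sum(c, d)
        for c in range(c_min, c_max + 1)
        for d in range(0, db_max + 1)
    ]


# The 31-member endogenous panel. The true monitored species list is not
# public; this panel is a synthetic stand-in of plausible abundant plasma
# diacyl-PI species (all within chain length 30-40, unsaturation <= 6) and
# always contains PI(16:0|16:0), PI(16:0|18:1) and PI(18:0|18:2), which the
# downstream analyses refer to by name.
_ENDOGENOUS_CHAIN_PAIRS: tuple[tuple[str, str], ...] = (
    ("14:0", "16:0"),
    ("14:0", "16:1"),
    ("16:0", "16:0"),
    ("16:0", "16:1"),
    ("16:1", "16:1"),
    ("16:0", "18:0"),
    ("16:0", "18:1"),
    ("16:0", "18:2"),
    ("16:1", "18:2"),
    ("18:0", "18:0"),
    ("18:0", "18:1"),
    ("18:0", "18:2"),
    ("18:1", "18:1"),
    ("18:1", "18:2"),
    ("18:2", "18:2"),
    ("16:0", "20:3"),
    ("16:0", "20:4"),
    ("16:0", "20:5"),
    ("16:1", "20:4"),
    ("18:0", "20:1"),
    ("18:0", "20:2"),
    ("18:0", "20:3"),
    ("18:0", "20:4"),
    ("18:1", "20:4"),
    ("16:0", "22:5"),
    ("16:0", "22:6"),
    ("18:0", "22:2"),
    ("18:0", "22:3"),
    ("18:0", "22:4"),
    ("18:0", "22:5"),
    ("18:0", "22:6"),
)

INTERNAL_STANDARD = PiSpecies.from_chains("12:0", "13:0", is_internal_standard=True)
SURROGATE_ANALYTES = (
    PiSpecies.from_chains("17:0", "14:1", is_surrogate=True),
    PiSpecies.from_chains("21:0", "22:6", is_surrogate=True),
)


def default_panel(include_is: bool = True, include_sa: bool = True) -> list[PiSpecies]:
    """The default acquisition panel: 31 endogenous PI plus IS and SA.

    Endogenous species come first (sorted by total carbons then
    unsaturation), then the internal standard PI(12:0|13:0) and the two
    odd-chain surrogate analytes PI(17:0|14:1) and PI(21:0|22:6).
    """
    panel = [PiSpecies.from_chains(a, b) for a, b in _ENDOGENOUS_CHAIN_PAIRS]
    panel.sort(key=lambda s: (s.total_carbons, s.total_double_bonds, s.name))
    if include_is:
        panel.append(INTERNAL_STANDARD)
    if include_sa:
        panel.extend(SURROGATE_ANALYTES)
    return panel


def endogenous_names(panel: Iterable[PiSpecies] | None = None) -> list[str]:
    """Names of the endogenous (non-IS, non-SA) species of a panel."""
    panel = default_panel() if panel is None else list(panel)
    return [s.name for s in panel if s.role == "endogenous"]


PANEL_CSV_COLUMNS = (
    "name",
    "total_carbons",
    "total_db",
    "sn1",
    "sn2",
    "precursor_mz",
    "product_mz",
    "role",
)


def write_panel_csv(panel: Iterable[PiSpecies], path: str) -> None:
    """Export a panel, with computed transitions, to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PANEL_CSV_COLUMNS)
        for sp in panel:
            if sp.sn2 is not None:
                trans = compute_transition(sp, "sn2")
                prec, prod = trans.precursor_mz, trans.product_mz
                sn1, sn2 = str(sp.sn1), str(sp.sn2)
            else:
                prec, prod = round(precursor_mz(sp), 4), ""
                sn1 = sn2 = ""
            writer.writerow(
                [sp.name, sp.total_carbons, sp.total_double_bonds, sn1, sn2, prec, prod, sp.role]
            )


def read_panel_csv(path: str) -> list[PiSpecies]:
    """Read a panel CSV written by :func:`write_panel_csv`."""
    panel: list[PiSpecies] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(("name", "total_carbons", "total_db", "role")) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        for row in reader:
            sn1 = AcylChain.parse(row["sn1"]) if row.get("sn1") else None
            sn2 = AcylChain.parse(row["sn2"]) if row.get("sn2") else None
            panel.append(
                PiSpecies(
                    name=row["name"],
                    total_carbons=int(row["total_carbons"]),
                    total_double_bonds=int(row["total_db"]),
                    sn1=sn1,
                    sn2=sn2,
                    is_surrogate=row["role"] == "SA",
                    is_internal_standard=row["role"] == "IS",
                )
            )
    return panel
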