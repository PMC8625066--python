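"""Plate layouts and the default 284-substrate catalog.

Four 96-well phenotype-microarray plates (PM3B for general nitrogen
sources; PM6, PM7, PM8 for peptide nitrogen sources) together carry 270
dipeptides and 14 tripeptides, with one negative-control well and one
L-glutamine positive-control well per plate.  The vendor's true well maps
are proprietary and not reproduced here; :func:`build_default_catalog`
generates a deterministic stand-in honoring those counts, which doubles as
the default substrate universe for the simulators.  Real well maps can be
supplied as a catalog TSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peptides import AA_ORDER, Peptide, Residue, parse_peptide_name, peptide

PLATE_IDS = ("PM3B", "PM6", "PM7", "PM8")

ROLE_SUBSTRATE = "substrate"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"

#: Conventional control positions used by the default catalog.
NEGATIVE_WELL = "A1"
POSITIVE_WELL = "A2"

# Internal seed for the filler-dipeptide draw; fixed so the default
# catalog is identical across runs and machines.
_CATALOG_SEED = 963


def well_names() -> list[str]:
    """All 96 well coordinates of an 8x12 plate, row-major (A1..H12)."""
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


@dataclass(frozen=True)
class WellContent:
    role: str
    substrate: Peptide | None = None


@dataclass
class PlateLayout:
    """One plate: a map from well coordinate to its content."""

    plate_id: str
    wells: dict[str, WellContent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = [w.role for w in self.wells.values()]
        if roles.count(ROLE_NEGATIVE) != 1 or roles.count(ROLE_POSITIVE) != 1:
            raise ValidationError(
                f"plate {self.plate_id}: exactly one negative and one "
                "positive control well required"
            )
        seen: set[Peptide] = set()
        for well, content in self.wells.items():
            if content.role == ROLE_SUBSTRATE:
                if content.substrate is None:
                    raise ValidationError(f"{self.plate_id}:{well} has no substrate")
                if content.substrate in seen:
                    raise ValidationError(
                        f"{self.plate_id}: duplicate substrate "
                        f"{content.substrate.display_name}"
                    )
                seen.add(content.substrate)

    @property
    def negative_well(self) -> str:
        return next(w for w, c in self.wells.items() if c.role == ROLE_NEGATIVE)

    @property
    def positive_well(self) -> str:
        return next(w for w, c in self.wells.items() if c.role == ROLE_POSITIVE)

    def substrates(self) -> list[tuple[str, Peptide]]:
        """(well, peptide) pairs in row-major well order."""
        order = {w: i for i, w in enumerate(well_names())}
        items = [
            (w, c.substrate)
            for w, c in self.wells.items()
            if c.role == ROLE_SUBSTRATE and c.substrate is not None
        ]
        items.sort(key=lambda t: order.get(t[0], 10**6))
        return items


# ---------------------------------------------------------------------------
# Default catalog construction

# Dipeptides named in consumption-profile work; pinned into the default
# universe so analyses can refer to them by name.
NAMED_DIPEPTIDES = (
    "His–Pro", "Thr–Ser", "Gly–Leu", "Lys–Trp", "Trp–Tyr",
    "Phe–Glu", "Phe–Asp", "Phe–Gly", "Cys–Gly", "Arg–Trp",
    "Arg–Lys", "Arg–Tyr", "Pro–Arg", "Met–Arg", "Trp–Arg",
)

#: Modified (D-/β-/γ-) dipeptides present in the default universe.
MODIFIED_DIPEPTIDES = (
    "γ-Glu–Gly", "γ-Glu–Ala", "β-Ala–His", "β-Ala–Ala", "β-Ala–Gly",
    "D-Ala–Gly", "D-Ala–Ala", "D-Ala–Leu", "D-Leu–Tyr", "D-Leu–Gly",
    "D-Val–Ala", "D-Ser–Gly",
)

#: The 14 tripeptides of the default universe (two with N-terminal Gly).
TRIPEPTIDES = (
    "Gly–Gly–Gly", "Gly–Gly–Leu", "Ala–Ala–Ala", "Ala–Gly–Gly",
    "Leu–Leu–Leu", "Leu–Gly–Gly", "Val–Tyr–Val", "Tyr–Gly–Gly",
    "Met–Leu–Phe", "Phe–Gly–Gly", "Ser–Ser–Ser", "Pro–Gly–Gly",
    "His–Gly–Gly", "Leu–Trp–Met",
)

_N_DIPEPTIDES = 270
_N_TRIPEPTIDES = 14


def default_peptides() -> list[Peptide]:
    """The deterministic 284-member default substrate universe.

    270 dipeptides (258 unmodified + 12 modified) followed by 14
    tripeptides.  Unmodified dipeptides pin the named peptides and all 20
    Gly-X pairs; the remainder is a fixed seeded draw from the other
    residue pairs, sorted into N→C alphabet order.
    """
    pinned = {parse_peptide_name(n) for n in NAMED_DIPEPTIDES}
    pinned |= {Peptide((Residue("G"), Residue(c))) for c in AA_ORDER}
    others = [
        Peptide((Residue(a), Residue(b)))
        for a in AA_ORDER
        for b in AA_ORDER
        if Peptide((Residue(a), Residue(b))) not in pinned
    ]
    n_fill = _N_DIPEPTIDES - len(MODIFIED_DIPEPTIDES) - len(pinned)
    rng = np.random.default_rng(_CATALOG_SEED)
    fill_idx = rng.choice(len(others), size=n_fill, replace=False)
    plain = sorted(
        pinned | {others[i] for i in sorted(fill_idx)},
        key=lambda p: tuple(AA_ORDER.index(r.code) for r in p.residues),
    )
    modified = [parse_peptide_name(n) for n in MODIFIED_DIPEPTIDES]
    tri = [parse_peptide_name(n) for n in TRIPEPTIDES]
    return plain + modified + tri


def build_default_catalog() -> list[PlateLayout]:
    """Four plates holding the default universe plus per-plate controls.

    PM6/PM7/PM8 take 94 substrates each; the remaining 2 land on PM3B.
    Wells A1/A2 of every plate are the negative and L-glutamine controls.
    """
    peptides = default_peptides()
    assert len(peptides) == _N_DIPEPTIDES + _N_TRIPEPTIDES
    substrate_wells = [w for w in well_names() if w not in (NEGATIVE_WELL, POSITIVE_WELL)]
    chunks = {
        "PM6": peptides[0:94],
        "PM7": peptides[94:188],
        "PM8": peptides[188:282],
        "PM3B": peptides[282:284],
    }
    plates = []
    for plate_id in PLATE_IDS:
        wells = {
            NEGATIVE_WELL: WellContent(ROLE_NEGATIVE),
            POSITIVE_WELL: WellContent(ROLE_POSITIVE),
        }
        for well, pep in zip(substrate_wells, chunks[plate_id]):
            wells[well] = WellContent(ROLE_SUBSTRATE, pep)
        plates.append(PlateLayout(plate_id, wells))
    return plates


def universe(catalog: Iterable[PlateLayout]) -> list[Peptide]:
    """Ordered, duplicate-free list of all substrates across *catalog*.

    Order is plate order as given, then row-major well order.
    """
    out: list[Peptide] = []
    seen: set[Peptide] = set()
    for plate in catalog:
        for _, pep in plate.substrates():
            if pep not in seen:
                seen.add(pep)
                out.append(pep)
    return out


def substrate_lookup(catalog: Iterable[PlateLayout]) -> dict[tuple[str, str], Peptide]:
    """(plate_id, well) → peptide for every substrate well."""
    return {
        (plate.plate_id, well): pep
        for plate in catalog
        for well, pep in plate.substrates()
    }


# ---------------------------------------------------------------------------
# Catalog TSV round-trip

def write_catalog(catalog: Iterable[PlateLayout], path: str) -> None:
    rows = []
    order = {w: i for i, w in enumerate(well_names())}
    for plate in catalog:
        for well in sorted(plate.wells, key=lambda w: order.get(w, 10**6)):
            content = plate.wells[well]
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": well,
                    "substrate_name": (
                        content.substrate.display_name if content.substrate else ""
                    ),
                    "role": content.role,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> list[PlateLayout]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"plate_id", "well", "substrate_name", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"catalog file {path!r} missing columns {sorted(required - set(df.columns))}"
        )
    plates = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        wells: dict[str, WellContent] = {}
        for _, row in grp.iterrows():
            role = row["role"]
            if role == ROLE_SUBSTRATE:
                wells[row["well"]] = WellContent(role, parse_peptide_name(row["substrate_name"]))
            elif role in (ROLE_NEGATIVE, ROLE_POSITIVE):
                wells[row["well"]] = WellContent(role)
            else:
                raise ValidationError(f"unknown well role {role!r} in {path!r}")
        plates.append(PlateLayout(str(plate_id), wells))
    return plates
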