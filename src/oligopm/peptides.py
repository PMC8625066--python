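"""Di-/tripeptide substrates and amino-acid classification.

Oligopeptides on Biolog peptide-nitrogen plates are di- and tripeptides
written in three-letter code, e.g. ``His–Pro`` or ``γ-Glu–Gly``.  A residue
may carry a stereochemical/linkage modifier (D-enantiomer, β- or γ-linked),
which matters biologically: modified peptides are generally not imported by
the transporters under study.  Classification of the 20 canonical residues
into hydrophobic / polar-uncharged / charged groups drives the positional
specificity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, PeptideParseError, ValidationError

#: Canonical one-letter amino-acid alphabet in a fixed, stable order.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

ONE_TO_THREE: Mapping[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}
THREE_TO_ONE: Mapping[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

MODIFIERS = ("none", "D", "beta", "gamma")

_MOD_RENDER = {"D": "D-", "beta": "β-", "gamma": "γ-"}
# Accepted spellings of modifier prefixes in input names.
_MOD_TOKENS = {
    "D": "D", "d": "D",
    "β": "beta", "b": "beta", "beta": "beta", "Beta": "beta",
    "γ": "gamma", "g": "gamma", "gamma": "gamma", "Gamma": "gamma",
}

# en-dash / em-dash are normalized to plain hyphen before tokenizing
_DASHES = {"–": "-", "—": "-", "−": "-"}


@dataclass(frozen=True)
class Residue:
    """One amino-acid position of a peptide.

    Parameters
    ----------
    code:
        One-letter symbol, one of the 20 canonical amino acids.
    modifier:
        ``"none"`` (default), ``"D"`` (D-enantiomer), ``"beta"`` or
        ``"gamma"`` (β-/γ-linked residue).
    """

    code: str
    modifier: str = "none"

    def __post_init__(self) -> None:
        if self.code not in ONE_TO_THREE:
            raise ValidationError(f"unknown amino-acid code {self.code!r}")
        if self.modifier not in MODIFIERS:
            raise ValidationError(f"unknown residue modifier {self.modifier!r}")

    def render(self) -> str:
        return _MOD_RENDER.get(self.modifier, "") + ONE_TO_THREE[self.code]


@dataclass(frozen=True)
class Peptide:
    """An ordered di- or tripeptide, N-terminus first."""

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) not in (2, 3):
            raise ValidationError(
                f"peptide length must be 2 or 3, got {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_terminal(self) -> Residue:
        return self.residues[0]

    @property
    def c_terminal(self) -> Residue:
        return self.residues[-1]

    @property
    def is_modified(self) -> bool:
        """True if any residue carries a D-/β-/γ- modifier."""
        return any(r.modifier != "none" for r in self.residues)

    @property
    def display_name(self) -> str:
        return render_peptide(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display_name


def peptide(spec: str | Sequence[str]) -> Peptide:
    """Convenience constructor: ``peptide("His–Pro")`` or ``peptide("HP")``."""
    if isinstance(spec, str) and "-" not in spec and "–" not in spec:
        return Peptide(tuple(Residue(c) for c in spec))
    return parse_peptide_name(spec)  # type: ignore[arg-type]


def render_peptide(p: Peptide) -> str:
    """Canonical display name: residues in three-letter code joined by en-dash."""
    return "–".join(r.render() for r in p.residues)


def parse_peptide_name(name: str) -> Peptide:
    """Parse a printed peptide name such as ``"γ-Glu–Gly"`` into a :class:`Peptide`.

    Hyphen and en-/em-dash are interchangeable; modifier prefixes accept both
    Greek (``β-``, ``γ-``) and Latin (``b-``, ``g-``) spellings plus ``D-``.

    Raises
    ------
    PeptideParseError
        On an unrecognized residue or dangling modifier token.
    ValidationError
        If the parsed length is outside 2–3 residues.
    """
    s = name.strip()
    for dash, repl in _DASHES.items():
        s = s.replace(dash, repl)
    tokens = [t for t in s.split("-") if t != ""]
    residues: list[Residue] = []
    pending: str | None = None
    for tok in tokens:
        if pending is None and tok in _MOD_TOKENS:
            pending = _MOD_TOKENS[tok]
            continue
        key = tok.capitalize()
        if key not in THREE_TO_ONE:
            raise PeptideParseError(
                f"unknown residue token {tok!r} in peptide name {name!r}"
            )
        residues.append(Residue(THREE_TO_ONE[key], pending or "none"))
        pending = None
    if pending is not None:
        raise PeptideParseError(f"dangling modifier prefix in {name!r}")
    if len(residues) not in (2, 3):
        raise ValidationError(
            f"peptide {name!r} has {len(residues)} residues; expected 2 or 3"
        )
    return Peptide(tuple(residues))


@dataclass(frozen=True)
class AminoAcidClass:
    """A named group of one-letter codes used for N-/C-terminal classification."""

    name: str
    members: frozenset[str]


#: Default scheme: three classes partitioning the canonical alphabet.
#: Gly, Pro and Trp sit with the hydrophobic panel, matching how peptide
#: preference panels group Gly-X / Pro-X / Trp-X substrates; users may
#: override via a YAML scheme file.
DEFAULT_SCHEME: tuple[AminoAcidClass, ...] = (
    AminoAcidClass("hydrophobic", frozenset("AVLIMFWGP")),
    AminoAcidClass("polar_uncharged", frozenset("STCYNQ")),
    AminoAcidClass("charged", frozenset("DEKRH")),
)


def validate_scheme(scheme: Iterable[AminoAcidClass]) -> tuple[AminoAcidClass, ...]:
    """Check that *scheme* partitions the 20 canonical symbols."""
    scheme = tuple(scheme)
    seen: dict[str, str] = {}
    for cls in scheme:
        for code in cls.members:
            if code not in ONE_TO_THREE:
                raise ConfigurationError(
                    f"class {cls.name!r} contains unknown code {code!r}"
                )
            if code in seen:
                raise ConfigurationError(
                    f"code {code!r} appears in both {seen[code]!r} and {cls.name!r}"
                )
            seen[code] = cls.name
    missing = set(AA_ORDER) - set(seen)
    if missing:
        raise ConfigurationError(f"scheme does not cover {sorted(missing)}")
    return scheme


def classify_residue(
    r: Residue, scheme: Iterable[AminoAcidClass] = DEFAULT_SCHEME
) -> AminoAcidClass:
    """Return the class containing ``r.code``; the modifier is ignored."""
    for cls in scheme:
        if r.code in cls.members:
            return cls
    raise ConfigurationError(f"code {r.code!r} absent from classification scheme")


def load_scheme(path: str) -> tuple[AminoAcidClass, ...]:
    """Read a YAML mapping of class name → list of one-letter codes."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"scheme file {path!r} must be a mapping")
    scheme = tuple(
        AminoAcidClass(str(name), frozenset(str(c) for c in codes))
        for name, codes in raw.items()
    )
    return validate_scheme(scheme)


def save_scheme(scheme: Iterable[AminoAcidClass], path: str) -> None:
    data = {cls.name: sorted(cls.members) for cls in scheme}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)
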