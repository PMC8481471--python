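"""Parsing, validation and formatting of shotgun-lipidomics annotation strings.

Lipid annotations follow the shorthand grammar

    <class token> <carbons>:<double bonds>;<hydroxyls>

at *species* level (sums over all hydrocarbon moieties), e.g. ``PI 34:1;0``
or ``SM 34:1;2``.  *Subspecies* annotations resolve the individual chains,
separated by ``_`` when the sn-position is not resolved and ``/`` when it is,
e.g. ``PI 18:1;0_16:0;0`` or ``PC O- 18:1;0/16:0;0``.  For ether classes
(token ending in ``O-``) the first chain is alkyl (ether-bound).  Sterol
("ST") carries no numeric block at all.

The class vocabulary is a closed registry: unknown tokens raise
:class:`LipidNameError` rather than passing through silently, which prevents
typos from being aggregated as new lipid classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Tuple

__all__ = [
    "Chain",
    "LipidSpecies",
    "LipidNameError",
    "ClassInfo",
    "ClassRegistry",
    "DEFAULT_REGISTRY",
    "parse_species",
    "format_species",
    "to_species_level",
    "fatty_acids_of",
]


class LipidNameError(ValueError):
    """Raised when an annotation string cannot be interpreted."""


class Level(str, Enum):
    SPECIES = "species"
    SUBSPECIES = "subspecies"


@dataclass(frozen=True)
class Chain:
    """One hydrocarbon moiety: acyl/alkyl chain or sphingoid base."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    ether: bool = False

    @property
    def label(self) -> str:
        """Compact descriptor used in fatty-acid profiles, e.g. ``O-18:1``."""
        s = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            s += f";{self.hydroxyls}"
        if self.ether:
            s = "O-" + s
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ClassInfo:
    """Registry entry for one lipid class."""

    token: str
    ether: bool = False
    sphingoid: bool = False
    n_chains: int = 2
    has_numeric_block: bool = True


# The 24 lipid classes quantified by the platform: glycerophospholipids and
# their lyso- and ether forms, neutral storage lipids, sterol, sphingolipids.
_DEFAULT_CLASSES = [
    ClassInfo("PC"),
    ClassInfo("PC O-", ether=True),
    ClassInfo("LPC", n_chains=1),
    ClassInfo("LPC O-", ether=True, n_chains=1),
    ClassInfo("PE"),
    ClassInfo("PE O-", ether=True),
    ClassInfo("LPE", n_chains=1),
    ClassInfo("LPE O-", ether=True, n_chains=1),
    ClassInfo("PA"),
    ClassInfo("LPA", n_chains=1),
    ClassInfo("PG"),
    ClassInfo("LPG", n_chains=1),
    ClassInfo("PI"),
    ClassInfo("LPI", n_chains=1),
    ClassInfo("PS"),
    ClassInfo("LPS", n_chains=1),
    ClassInfo("CL", n_chains=4),
    ClassInfo("DAG"),
    ClassInfo("TAG", n_chains=3),
    ClassInfo("CE", n_chains=1),
    ClassInfo("ST", has_numeric_block=False, n_chains=0),
    ClassInfo("Cer", sphingoid=True),
    ClassInfo("HexCer", sphingoid=True),
    ClassInfo("SM", sphingoid=True),
]


class ClassRegistry:
    """Closed vocabulary of lipid class tokens.

    Tokens may contain spaces (``PC O-``); lookup at parse time is
    longest-match-first so that ``PC O-`` wins over ``PC``.
    """

    def __init__(self, classes: Iterable[ClassInfo] = _DEFAULT_CLASSES):
        self._classes: dict[str, ClassInfo] = {}
        for c in classes:
            self.register(c)

    def register(self, info: ClassInfo) -> None:
        self._classes[info.token] = info

    def __contains__(self, token: str) -> bool:
        return token in self._classes

    def __getitem__(self, token: str) -> ClassInfo:
        return self._classes[token]

    @property
    def tokens(self) -> list[str]:
        return list(self._classes)

    def match(self, text: str) -> Optional[ClassInfo]:
        """Return the registered class whose token prefixes *text* (longest first)."""
        best = None
        for token, info in self._classes.items():
            if text == token or text.startswith(token + " "):
                if best is None or len(token) > len(best.token):
                    best = info
        return best


DEFAULT_REGISTRY = ClassRegistry()


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation.

    Totals are sums over all hydrocarbon moieties.  ``chains`` is present
    only for subspecies-level annotations; ``sn_resolved`` is True when the
    chains were separated by ``/``.
    """

    class_token: str
    total_carbons: int
    total_double_bonds: int
    total_hydroxyls: int
    chains: Optional[Tuple[Chain, ...]] = None
    sn_resolved: bool = False
    level: Level = Level.SPECIES

    def __post_init__(self):
        if self.chains is not None:
            if (
                sum(c.carbons for c in self.chains) != self.total_carbons
                or sum(c.double_bonds for c in self.chains) != self.total_double_bonds
                or sum(c.hydroxyls for c in self.chains) != self.total_hydroxyls
            ):
                raise LipidNameError(
                    f"chain sums do not match totals for class {self.class_token}"
                )
        if self.sn_resolved and self.chains is None:
            raise LipidNameError("sn_resolved requires resolved chains")

    @property
    def lipid_class(self) -> str:
        return self.class_token

    def __str__(self) -> str:
        return format_species(self)


_MOIETY_RE = re.compile(r"^(\d+):(\d+);(\d+)$")


def _parse_moiety(text: str, offset: int) -> Tuple[int, int, int]:
    m = _MOIETY_RE.match(text)
    if m is None:
        raise LipidNameError(
            f"malformed numeric field {text!r} at position {offset} "
            "(expected <carbons>:<double bonds>;<hydroxyls>)"
        )
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def parse_species(
    annotation: str, registry: ClassRegistry = DEFAULT_REGISTRY
) -> LipidSpecies:
    """Parse an annotation string into a :class:`LipidSpecies`.

    Repeated internal spaces are tolerated; the canonical form uses exactly
    one space between class token and numeric block.

    Raises
    ------
    LipidNameError
        If the class token is not registered or a numeric field is malformed.
    """
    if not annotation or not annotation.strip():
        raise LipidNameError("empty annotation")
    text = re.sub(r"\s+", " ", annotation.strip())

    info = registry.match(text)
    if info is None:
        token_guess = re.split(r" \d", text, maxsplit=1)[0]
        raise LipidNameError(f"unknown lipid class token {token_guess!r}")

    rest = text[len(info.token):].strip()
    if not info.has_numeric_block:
        if rest:
            raise LipidNameError(
                f"class {info.token!r} takes no numeric block, got {rest!r}"
            )
        return LipidSpecies(info.token, 0, 0, 0)
    if not rest:
        raise LipidNameError(f"missing numeric block after class {info.token!r}")

    if "/" in rest and "_" in rest:
        raise LipidNameError(f"mixed chain separators in {annotation!r}")
    sn_resolved = "/" in rest
    sep = "/" if sn_resolved else "_"
    parts = rest.split(sep)

    offset = len(info.token) + 1
    if len(parts) == 1:
        c, db, oh = _parse_moiety(parts[0], offset)
        return LipidSpecies(info.token, c, db, oh)

    chains = []
    for i, part in enumerate(parts):
        c, db, oh = _parse_moiety(part, offset)
        chains.append(Chain(c, db, oh, ether=info.ether and i == 0))
        offset += len(part) + 1
    return LipidSpecies(
        info.token,
        sum(ch.carbons for ch in chains),
        sum(ch.double_bonds for ch in chains),
        sum(ch.hydroxyls for ch in chains),
        chains=tuple(chains),
        sn_resolved=sn_resolved,
        level=Level.SUBSPECIES,
    )


def format_species(
    sp: LipidSpecies, registry: ClassRegistry = DEFAULT_REGISTRY
) -> str:
    """Render the canonical annotation string (inverse of :func:`parse_species`)."""
    if sp.class_token in registry and not registry[sp.class_token].has_numeric_block:
        return sp.class_token
    if sp.chains is None:
        return (
            f"{sp.class_token} "
            f"{sp.total_carbons}:{sp.total_double_bonds};{sp.total_hydroxyls}"
        )
    sep = "/" if sp.sn_resolved else "_"
    body = sep.join(f"{c.carbons}:{c.double_bonds};{c.hydroxyls}" for c in sp.chains)
    return f"{sp.class_token} {body}"


def to_species_level(sub: LipidSpecies) -> LipidSpecies:
    """Collapse a subspecies annotation to species level (summed totals).

    Species-level input is returned unchanged; totals are conserved.
    """
    if sub.level is Level.SPECIES:
        return sub
    return replace(
        sub, chains=None, sn_resolved=False, level=Level.SPECIES
    )


def fatty_acids_of(sub: LipidSpecies) -> list[Chain]:
    """Return the individual hydrocarbon-chain descriptors of a subspecies.

    The sphingoid long-chain base is treated like any other chain (it carries
    the hydroxyl count); ether-bound chains are flagged via ``Chain.ether``.

    Raises
    ------
    LipidNameError
        For species-level input, where chains are not resolved.
    """
    if sub.chains is None:
        raise LipidNameError(
            f"no resolved chains for species-level annotation {format_species(sub)!r}"
        )
    return list(sub.chains)
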