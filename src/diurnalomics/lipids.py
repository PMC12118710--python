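"""Shorthand lipid nomenclature: parsing, formatting, class summaries.

Untargeted lipidomics reports species in the compact shorthand
``CLASS C:D`` — class token, total carbons, total double bonds — optionally
refined with individual acyl chains ("_" when the sn-position is undefined,
"/" when it is defined), an ether prefix (O-/P-, plasmanyl/plasmenyl), and
";"-separated modifiers such as hydroxylation (``2O``) or sulfation (``S``).
Examples covered: ``TG 58:9`` (sum composition only), ``PC 18:0_22:5``
(undefined positions), ``Cer 18:1;2O/23:0`` (defined positions with a
modified long-chain base), ``ST 28:1;O;S`` (sum composition with modifiers).

Modifiers are kept as opaque ordered tokens: they are printed and round-
tripped but never interpreted chemically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Chain",
    "LipidName",
    "LipidParseError",
    "parse_lipid_name",
    "canonical_format",
    "class_distribution",
]


class LipidParseError(ValueError):
    """Raised when a species name does not follow the shorthand grammar."""


_CLASS_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")
_CHAIN_RE = re.compile(r"^(\d+):(\d+)((?:;[A-Za-z0-9]+)*)$")
_MOD_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass(frozen=True)
class Chain:
    """One acyl/alkyl chain: carbon count, double bonds, modifier tokens."""

    carbons: int
    double_bonds: int
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("chain counts must be non-negative")
        for mod in self.modifiers:
            if not _MOD_RE.match(mod):
                raise ValueError(f"invalid modifier token {mod!r}")

    def format(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        for mod in self.modifiers:
            s += f";{mod}"
        return s


@dataclass(frozen=True)
class LipidName:
    """A parsed shorthand lipid species name.

    ``separator`` is ``"sum"`` when only the summed composition is known
    (``chains`` is then empty and modifiers, if any, live in
    ``total_modifiers``), ``"_"`` for undefined sn-positions and ``"/"`` for
    defined positions.
    """

    lipid_class: str
    chains: tuple[Chain, ...] = ()
    separator: str = "sum"
    ether_prefix: str | None = None  # "O-" or "P-"
    total_carbons: int = 0
    total_double_bonds: int = 0
    total_modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _CLASS_RE.match(self.lipid_class):
            raise ValueError(f"invalid lipid class token {self.lipid_class!r}")
        if self.separator not in ("sum", "_", "/"):
            raise ValueError(f"invalid separator kind {self.separator!r}")
        if self.ether_prefix not in (None, "O-", "P-"):
            raise ValueError(f"invalid ether prefix {self.ether_prefix!r}")
        if self.separator == "sum":
            if self.chains:
                raise ValueError("sum-only names carry no chain list")
        else:
            if not self.chains:
                raise ValueError("chain-separated names need at least one chain")
            if self.total_carbons != sum(c.carbons for c in self.chains):
                raise ValueError("total carbons inconsistent with chain sum")
            if self.total_double_bonds != sum(c.double_bonds for c in self.chains):
                raise ValueError("total double bonds inconsistent with chain sum")
            if self.total_modifiers:
                raise ValueError("chain-level names carry modifiers on chains")


def parse_lipid_name(name: str) -> LipidName:
    """Parse a shorthand species name.

    Raises :class:`LipidParseError` preserving the offending token.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError("empty lipid name")
    text = name.strip()
    parts = text.split(None, 1)
    if len(parts) != 2:
        raise LipidParseError(f"cannot split class and composition in {text!r}")
    cls, rest = parts
    if not _CLASS_RE.match(cls):
        raise LipidParseError(f"invalid class token {cls!r} in {text!r}")

    ether: str | None = None
    if rest.startswith(("O-", "P-")):
        ether, rest = rest[:2], rest[2:]

    if "_" in rest and "/" in rest:
        raise LipidParseError(f"mixed chain separators in {text!r}")
    sep = "_" if "_" in rest else ("/" if "/" in rest else "sum")
    tokens = [rest] if sep == "sum" else rest.split(sep)

    chains: list[Chain] = []
    for tok in tokens:
        match = _CHAIN_RE.match(tok)
        if not match:
            raise LipidParseError(f"invalid composition token {tok!r} in {text!r}")
        mods = tuple(m for m in match.group(3).split(";") if m)
        chains.append(Chain(int(match.group(1)), int(match.group(2)), mods))

    if sep == "sum":
        only = chains[0]
        return LipidName(
            lipid_class=cls,
            chains=(),
            separator="sum",
            ether_prefix=ether,
            total_carbons=only.carbons,
            total_double_bonds=only.double_bonds,
            total_modifiers=only.modifiers,
        )
    return LipidName(
        lipid_class=cls,
        chains=tuple(chains),
        separator=sep,
        ether_prefix=ether,
        total_carbons=sum(c.carbons for c in chains),
        total_double_bonds=sum(c.double_bonds for c in chains),
        total_modifiers=(),
    )


def canonical_format(lipid: LipidName) -> str:
    """Render a LipidName back to its canonical shorthand string."""
    prefix = lipid.ether_prefix or ""
    if lipid.separator == "sum":
        body = Chain(
            lipid.total_carbons, lipid.total_double_bonds, lipid.total_modifiers
        ).format()
    else:
        body = lipid.separator.join(c.format() for c in lipid.chains)
    return f"{lipid.lipid_class} {prefix}{body}"


def class_distribution(
    names: list[str], rhythmic: list[bool] | None = None
) -> pd.DataFrame:
    """Tabulate species per lipid class, optionally split by a rhythmic flag.

    Returns a DataFrame indexed by class with columns ``n_total`` and
    ``n_rhythmic``; the totals sum to ``len(names)``.  Parse errors propagate.
    """
    if rhythmic is None:
        rhythmic = [False] * len(names)
    if len(names) != len(rhythmic):
        raise ValueError("names and rhythmic flags must be aligned")
    rows: dict[str, list[int]] = {}
    for name, flag in zip(names, rhythmic):
        cls = parse_lipid_name(name).lipid_class
        entry = rows.setdefault(cls, [0, 0])
        entry[0] += 1
        entry[1] += int(bool(flag))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_total", "n_rhythmic"]
    )
    table.index.name = "lipid_class"
    return table.sort_index()
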