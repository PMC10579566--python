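"""Staining-panel, marker and phenotype definitions.

A *panel* is an ordered set of fluorescence channels, one marker per channel,
exactly one of which is the nuclear counterstain (DAPI) used for cell
detection. Phenotypes are boolean formulas over binary marker statuses
(e.g. the NK-cell rule ``CD8- AND [CD16+ AND/OR CD56+] AND [NKG2A+ AND/OR
GZMB+ AND/OR GNLY+]``), each with a *parent* formula that defines the
denominator population used when reporting phenotype fractions.

The grammar accepted for formulas: atoms are marker names with an optional
``+``/``-`` suffix (``CD8-`` is shorthand for ``NOT CD8``); operators are
prefix ``NOT`` and infix ``AND`` / ``OR`` (``AND/OR`` is accepted as a
synonym for ``OR`` so published rule text can be transcribed verbatim);
``( )`` and ``[ ]`` both group. ``OR`` binds loosest, then ``AND``, then
``NOT``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Union

import numpy as np
import yaml

LOCALIZATIONS = ("nuclear", "membranous", "cytoplasmic")

CASE_TYPES = ("tonsil", "NLPHL-pA", "NLPHL-pC", "NLPHL-pE", "THRLBCL", "LRcHL")

DEFAULT_PANEL_NAMES = ("lymphocyte", "cytotoxic_nk", "macrophage")


class PanelConfigError(ValueError):
    """Invalid panel/phenotype configuration."""


class ExpressionError(ValueError):
    """Malformed phenotype formula or evaluation over an incomplete vector."""


@dataclass(frozen=True)
class MarkerSpec:
    """One marker on one channel of a panel."""

    name: str
    channel_index: int
    localization: str
    is_counterstain: bool = False

    def __post_init__(self):
        if self.localization not in LOCALIZATIONS:
            raise PanelConfigError(
                f"marker {self.name!r}: localization must be one of "
                f"{LOCALIZATIONS}, got {self.localization!r}"
            )
        if self.is_counterstain and self.localization != "nuclear":
            raise PanelConfigError(
                f"counterstain {self.name!r} must have nuclear localization"
            )


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    markers: tuple[MarkerSpec, ...]

    def __post_init__(self):
        if len(self.markers) < 2:
            raise PanelConfigError(
                f"panel {self.name!r} needs at least 2 markers "
                f"(got {len(self.markers)})"
            )
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise PanelConfigError(f"panel {self.name!r}: duplicate marker names")
        chans = [m.channel_index for m in self.markers]
        if len(set(chans)) != len(chans):
            raise PanelConfigError(
                f"panel {self.name!r}: duplicate channel index among {chans}"
            )
        n_cs = sum(m.is_counterstain for m in self.markers)
        if n_cs != 1:
            raise PanelConfigError(
                f"panel {self.name!r}: exactly one counterstain required, got {n_cs}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.markers)

    @property
    def counterstain(self) -> MarkerSpec:
        return next(m for m in self.markers if m.is_counterstain)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    @property
    def phenotype_marker_names(self) -> tuple[str, ...]:
        """Marker names excluding the counterstain."""
        return tuple(m.name for m in self.markers if not m.is_counterstain)

    def __getitem__(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def channel_of(self, name: str) -> int:
        return self[name].channel_index


# --------------------------------------------------------------------------
# boolean formula parsing / evaluation
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(AND/OR|\(|\)|\[|\]|[A-Za-z_][A-Za-z0-9_]*[+\-]?)")
_KEYWORDS = {"AND", "OR", "NOT", "AND/OR"}

# AST nodes: ("marker", name, positive) | ("not", node) | ("and", l, r) | ("or", l, r)
Node = tuple


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(
                f"unexpected character {text[pos]!r} at position {pos} in {text!r}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise ExpressionError(
                f"trailing tokens {self.tokens[self.i:]} in {self.text!r}"
            )
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek() in ("OR", "AND/OR"):
            self.next()
            node = ("or", node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek() == "AND":
            self.next()
            node = ("and", node, self.unary())
        return node

    def unary(self) -> Node:
        tok = self.peek()
        if tok == "NOT":
            self.next()
            return ("not", self.unary())
        return self.atom()

    def atom(self) -> Node:
        tok = self.next()
        if tok is None:
            raise ExpressionError(f"unexpected end of formula in {self.text!r}")
        if tok in ("(", "["):
            node = self.expr()
            closing = self.next()
            if closing not in (")", "]"):
                raise ExpressionError(f"unbalanced brackets in {self.text!r}")
            return node
        if tok in _KEYWORDS or tok in (")", "]"):
            raise ExpressionError(f"unexpected token {tok!r} in {self.text!r}")
        positive = True
        if tok.endswith("+"):
            tok = tok[:-1]
        elif tok.endswith("-"):
            tok, positive = tok[:-1], False
        return ("marker", tok, positive)


def parse_expression(text: str) -> Node:
    """Parse a phenotype formula into an AST."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty formula")
    return _Parser(tokens, text).parse()


def expression_markers(node_or_text: Union[Node, str]) -> set[str]:
    """Set of marker names referenced by a formula."""
    node = (
        parse_expression(node_or_text)
        if isinstance(node_or_text, str)
        else node_or_text
    )
    out: set[str] = set()

    def walk(n):
        if n[0] == "marker":
            out.add(n[1])
        elif n[0] == "not":
            walk(n[1])
        else:
            walk(n[1])
            walk(n[2])

    walk(node)
    return out


def _eval(node: Node, lookup) -> np.ndarray:
    kind = node[0]
    if kind == "marker":
        val = lookup(node[1])
        return val if node[2] else np.logical_not(val)
    if kind == "not":
        return np.logical_not(_eval(node[1], lookup))
    left, right = _eval(node[1], lookup), _eval(node[2], lookup)
    return np.logical_and(left, right) if kind == "and" else np.logical_or(left, right)


def evaluate_phenotype(
    expression: Union[Node, str], marker_vector: Mapping[str, bool]
) -> bool:
    """Evaluate a boolean phenotype formula on one cell's binary marker vector.

    Deterministic and total: given a vector covering every referenced marker,
    the result is always defined. A missing marker raises ``ExpressionError``
    naming it.
    """
    node = (
        parse_expression(expression) if isinstance(expression, str) else expression
    )

    def lookup(name):
        if name not in marker_vector:
            raise ExpressionError(f"marker {name!r} missing from marker vector")
        return bool(marker_vector[name])

    return bool(_eval(node, lookup))


def evaluate_phenotype_frame(
    expression: Union[Node, str], frame
) -> np.ndarray:
    """Vectorised evaluation over a DataFrame of boolean marker columns."""
    node = (
        parse_expression(expression) if isinstance(expression, str) else expression
    )

    def lookup(name):
        if name not in frame.columns:
            raise ExpressionError(f"marker {name!r} missing from marker table")
        return frame[name].to_numpy(dtype=bool)

    return np.asarray(_eval(node, lookup), dtype=bool)


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named phenotype rule plus the parent population it is reported over.

    ``parent_expression`` empty means the parent is every segmented cell.
    """

    display_name: str
    expression: str
    parent_expression: str = ""

    def markers(self) -> set[str]:
        out = expression_markers(self.expression)
        if self.parent_expression:
            out |= expression_markers(self.parent_expression)
        return out

    def validate_against(self, panel: PanelDefinition) -> None:
        known = set(panel.marker_names)
        for name in sorted(self.markers()):
            if name not in known:
                raise PanelConfigError(
                    f"phenotype {self.display_name!r} references marker "
                    f"{name!r} which is not in panel {panel.name!r}"
                )


@dataclass
class CaseTypePreset:
    """Tissue-composition parameters for one case type.

    ``phenotype_proportions`` maps a phenotype (or lineage class) to its
    expected fraction of the relevant parent population; lineage classes
    ('CD4+', 'CD8+', 'NK-cell', 'Macrophage') are fractions of CD20-negative
    cells, activation phenotypes are fractions of their own parent
    population (NK subsets of NK cells, CD8 subsets of CD8+ cells, ...).
    ``b_cell_fraction`` is the fraction of all cells that are CD20+,
    ``lp_density`` is neoplastic LP cells per mm², ``nodularity`` in [0, 1]
    controls how strongly B cells cluster into nodules.
    """

    case_type: str
    phenotype_proportions: dict[str, float]
    b_cell_fraction: float
    lp_density: float
    nodularity: float

    def __post_init__(self):
        for key, p in self.phenotype_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise PanelConfigError(
                    f"preset {self.case_type!r}: proportion {key}={p} outside [0, 1]"
                )
        if not (0.0 <= self.b_cell_fraction <= 1.0):
            raise PanelConfigError("b_cell_fraction outside [0, 1]")
        if not (0.0 <= self.nodularity <= 1.0):
            raise PanelConfigError("nodularity outside [0, 1]")
        if self.lp_density < 0:
            raise PanelConfigError("lp_density must be >= 0")


# --------------------------------------------------------------------------
# config loading
# --------------------------------------------------------------------------

def load_panel_config(
    document: Union[str, Mapping],
) -> tuple[PanelDefinition, list[PhenotypeDefinition]]:
    """Parse a panel + phenotype config document (YAML text or mapping).

    Schema::

        panel:
          name: lymphocyte
          markers:
            - {name: CD20, channel: 0, localization: membranous}
            - {name: DAPI, channel: 5, localization: nuclear, counterstain: true}
        phenotypes:
          - {name: "CD4+FOXP3+", expression: "CD4+ AND FOXP3+", parent: "CD20-"}
    """
    if isinstance(document, str):
        try:
            doc = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise PanelConfigError(f"invalid config document: {exc}") from exc
    else:
        doc = dict(document)
    if not isinstance(doc, Mapping) or "panel" not in doc:
        raise PanelConfigError("config must contain a 'panel' section")
    pd_ = doc["panel"]
    raw_markers = pd_.get("markers") or []
    if not raw_markers:
        raise PanelConfigError(f"panel {pd_.get('name')!r}: empty marker list")
    markers = tuple(
        MarkerSpec(
            name=str(m["name"]),
            channel_index=int(m["channel"]),
            localization=str(m["localization"]),
            is_counterstain=bool(m.get("counterstain", False)),
        )
        for m in raw_markers
    )
    panel = PanelDefinition(name=str(pd_.get("name", "panel")), markers=markers)
    phenotypes = []
    for ph in doc.get("phenotypes") or []:
        defn = PhenotypeDefinition(
            display_name=str(ph["name"]),
            expression=str(ph["expression"]),
            parent_expression=str(ph.get("parent", "") or ""),
        )
        parse_expression(defn.expression)  # syntax check
        if defn.parent_expression:
            parse_expression(defn.parent_expression)
        defn.validate_against(panel)
        phenotypes.append(defn)
    names = [p.display_name for p in phenotypes]
    if len(set(names)) != len(names):
        raise PanelConfigError("duplicate phenotype names")
    return panel, phenotypes


def load_default_panel(
    name: str,
) -> tuple[PanelDefinition, list[PhenotypeDefinition]]:
    """Load one of the packaged panels: lymphocyte, cytotoxic_nk, macrophage."""
    if name not in DEFAULT_PANEL_NAMES:
        raise PanelConfigError(
            f"unknown packaged panel {name!r}; available: {DEFAULT_PANEL_NAMES}"
        )
    text = (
        resources.files("phenoplex").joinpath(f"data/{name}.yaml").read_text()
    )
    return load_panel_config(text)
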