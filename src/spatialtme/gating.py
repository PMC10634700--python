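"""Hierarchical cell phenotyping and T cell functionality barcoding.

Cells carry binary marker positivity. A declarative gating hierarchy assigns
every cell exactly one terminal state: siblings are evaluated in listed order
and the first matching predicate wins ("exclusive populations"), so the leaf
assignment is a partition of the input. Cells matching no explicit terminal
gate fall into a residual leaf, which guarantees exhaustiveness.

T cells additionally receive a 10-bit "functionality barcode": the binary
positivity pattern over a fixed ordered panel of 10 functional markers
(differentiation, exhaustion, and checkpoint biomarkers). Proliferation
(Ki-67) and cytotoxicity (granzyme B) are scored separately and are *not*
barcode bits.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import BARCODE_MARKERS, RESIDUAL_LEAF


class GatingError(ValueError):
    """Raised for invalid gating configurations or unsatisfiable inputs."""


# ---------------------------------------------------------------------------
# Barcode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Barcode:
    """Ordered 10-bit positivity pattern over :data:`BARCODE_MARKERS`."""

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(BARCODE_MARKERS):
            raise ValueError(
                f"barcode must have exactly {len(BARCODE_MARKERS)} bits, "
                f"got {len(self.bits)}"
            )

    @property
    def canonical_name(self) -> str:
        """Positive markers joined in fixed panel order, or ``NEG``."""
        name = "".join(
            f"{m}+" for m, b in zip(BARCODE_MARKERS, self.bits) if b
        )
        return name or "NEG"

    @classmethod
    def from_positivity(cls, positivity: dict[str, bool]) -> "Barcode":
        return cls(tuple(bool(positivity[m]) for m in BARCODE_MARKERS))

    @classmethod
    def from_name(cls, name: str) -> "Barcode":
        if name == "NEG":
            return cls((False,) * len(BARCODE_MARKERS))
        tokens = [t for t in name.split("+") if t]
        unknown = set(tokens) - set(BARCODE_MARKERS)
        if unknown:
            raise ValueError(f"unknown barcode markers: {sorted(unknown)}")
        return cls(tuple(m in tokens for m in BARCODE_MARKERS))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


def barcode_name_from_row(row: pd.Series | dict) -> str:
    return "".join(f"{m}+" for m in BARCODE_MARKERS if row[m]) or "NEG"


# ---------------------------------------------------------------------------
# Gating configuration
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    name: str
    parent: str | None
    require_positive: tuple[str, ...] = ()
    require_negative: tuple[str, ...] = ()
    require_any: tuple[tuple[str, ...], ...] = ()
    terminal: bool = False

    @property
    def markers(self) -> set[str]:
        out = set(self.require_positive) | set(self.require_negative)
        for group in self.require_any:
            out |= set(group)
        return out

    def predicate_key(self) -> tuple:
        return (
            tuple(sorted(self.require_positive)),
            tuple(sorted(self.require_negative)),
            tuple(sorted(tuple(sorted(g)) for g in self.require_any)),
        )


@dataclass
class GatingConfig:
    """Validated gating hierarchy with a residual leaf."""

    nodes: list[GateNode]
    panel: tuple[str, ...]
    residual_leaf: str = RESIDUAL_LEAF
    _by_name: dict[str, GateNode] = field(default_factory=dict, repr=False)
    _children: dict[str, list[GateNode]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for node in self.nodes:
            if node.name in self._by_name:
                raise GatingError(f"duplicate gate name {node.name!r}")
            if node.name == self.residual_leaf:
                raise GatingError(
                    f"gate name {node.name!r} collides with the residual leaf"
                )
            self._by_name[node.name] = node
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise GatingError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children = {n.name: [] for n in self.nodes}
        for node in self.nodes:
            if node.parent is not None:
                if node.parent not in self._by_name:
                    raise GatingError(
                        f"gate {node.name!r} has unknown parent {node.parent!r}"
                    )
                self._children[node.parent].append(node)
        self._check_acyclic()
        panel_set = set(self.panel)
        for node in self.nodes:
            missing = node.markers - panel_set
            if missing:
                raise GatingError(
                    f"gate {node.name!r} references markers not in the panel: "
                    f"{sorted(missing)}"
                )
        for parent, children in self._children.items():
            seen: dict[tuple, str] = {}
            for child in children:
                key = child.predicate_key()
                if key in seen:
                    raise GatingError(
                        f"siblings {seen[key]!r} and {child.name!r} under "
                        f"{parent!r} have identical predicates"
                    )
                seen[key] = child.name

    def _check_acyclic(self) -> None:
        for node in self.nodes:
            seen = set()
            cur: GateNode | None = node
            while cur is not None:
                if cur.name in seen:
                    raise GatingError(f"cyclic parent links at {node.name!r}")
                seen.add(cur.name)
                cur = self._by_name.get(cur.parent) if cur.parent else None

    def children(self, name: str) -> list[GateNode]:
        return self._children[name]

    # -- taxonomy ----------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        """Terminal leaf labels in document order, residual last."""
        out = [n.name for n in self.nodes if n.terminal]
        out.append(self.residual_leaf)
        return out

    def path_requirements(
        self, leaf: str
    ) -> tuple[set[str], set[str], list[tuple[str, ...]]]:
        """Accumulated (positive, negative, any-of) constraints root -> leaf."""
        if leaf == self.residual_leaf:
            # Residual cells are guaranteed by negativity for every marker
            # that appears in a require_positive anywhere at depth-1 branches.
            raise GatingError("residual leaf has no explicit predicate path")
        node = self._by_name.get(leaf)
        if node is None or not node.terminal:
            raise GatingError(f"{leaf!r} is not a terminal gate")
        pos: set[str] = set()
        neg: set[str] = set()
        anys: list[tuple[str, ...]] = []
        cur: GateNode | None = node
        while cur is not None:
            overlap = set(cur.require_positive) & neg
            overlap |= set(cur.require_negative) & pos
            if overlap:
                raise GatingError(
                    f"contradictory constraints on {sorted(overlap)} along "
                    f"path to {leaf!r}"
                )
            pos |= set(cur.require_positive)
            neg |= set(cur.require_negative)
            anys.extend(cur.require_any)
            cur = self._by_name.get(cur.parent) if cur.parent else None
        return pos, neg, anys

    def is_t_state(self, leaf: str) -> bool:
        """A leaf is a T state when its path requires CD3 positivity."""
        if leaf == self.residual_leaf:
            return False
        pos, _, _ = self.path_requirements(leaf)
        return "CD3" in pos

    def is_treg_state(self, leaf: str) -> bool:
        if leaf == self.residual_leaf:
            return False
        pos, _, _ = self.path_requirements(leaf)
        return "FOXP3" in pos

    def classify_one(self, positivity) -> str:
        """Classify a single positivity mapping (missing markers read False)."""

        def matches(node: GateNode) -> bool:
            if any(not positivity.get(m, False) for m in node.require_positive):
                return False
            if any(positivity.get(m, False) for m in node.require_negative):
                return False
            return all(
                any(positivity.get(m, False) for m in group)
                for group in node.require_any
            )

        node = self.root
        while True:
            for child in self.children(node.name):
                if matches(child):
                    if child.terminal:
                        return child.name
                    node = child
                    break
            else:
                return self.residual_leaf

    @property
    def t_state_leaves(self) -> list[str]:
        return [s for s in self.leaves if self.is_t_state(s)]

    @property
    def treg_state_leaves(self) -> list[str]:
        return [s for s in self.leaves if self.is_treg_state(s)]


def load_gating_config(path=None) -> GatingConfig:
    """Load a gating hierarchy from YAML (shipped default when *path* is None)."""
    if path is None:
        ref = importlib.resources.files("spatialtme").joinpath(
            "data/gating_default.yaml"
        )
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    nodes = [
        GateNode(
            name=str(d["name"]),
            parent=d.get("parent"),
            require_positive=tuple(d.get("require_positive", ())),
            require_negative=tuple(d.get("require_negative", ())),
            require_any=tuple(tuple(g) for g in d.get("require_any", ())),
            terminal=bool(d.get("terminal", False)),
        )
        for d in raw["nodes"]
    ]
    return GatingConfig(
        nodes=nodes,
        panel=tuple(raw["panel"]),
        residual_leaf=raw.get("residual_leaf", RESIDUAL_LEAF),
    )


def taxonomy_leaves(config: GatingConfig) -> list[str]:
    """Ordered taxonomy leaf labels (deterministic document order)."""
    return config.leaves


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _marker_arrays(cells: pd.DataFrame, config: GatingConfig) -> dict[str, np.ndarray]:
    arrays = {}
    needed = set()
    for node in config.nodes:
        needed |= node.markers
    for marker in sorted(needed):
        if marker not in cells.columns:
            gate = next(n.name for n in config.nodes if marker in n.markers)
            raise GatingError(
                f"marker {marker!r} required by gate {gate!r} is missing "
                "from the cell table"
            )
        arrays[marker] = cells[marker].to_numpy().astype(bool)
    return arrays

def _node_mask(node: GateNode, M: dict[str, np.ndarray], n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for m in node.require_positive:
        mask &= M[m]
    for m in node.require_negative:
        mask &= ~M[m]
    for group in node.require_any:
        any_mask = np.zeros(n, dtype=bool)
        for m in group:
            any_mask |= M[m]
        mask &= any_mask
    return mask


def assign_states(cells: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Assign each cell exactly one taxonomy leaf (first-match-wins).

    Returns a copy of *cells* with a ``state`` column. Cells failing every
    explicit terminal gate receive the residual leaf.
    """
    n = len(cells)
    M = _marker_arrays(cells, config)
    state = np.full(n, config.residual_leaf, dtype=object)

    def descend(node: GateNode, active: np.ndarray) -> None:
        for child in config.children(node.name):
            if not active.any():
                return
            matched = active & _node_mask(child, M, n)
            if child.terminal:
                state[matched] = child.name
            else:
                descend(child, matched)
            active = active & ~matched

    descend(config.root, np.ones(n, dtype=bool))
    out = cells.copy()
    out["state"] = state
    return out


def assign_barcodes(cells: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Assign every T-state cell its 10-bit functionality barcode name.

    Non-T cells get a missing barcode. Requires ``state`` to be assigned and
    all 10 barcode markers to be present as columns.
    """
    if "state" not in cells.columns:
        raise GatingError("states must be assigned before barcodes")
    missing = [m for m in BARCODE_MARKERS if m not in cells.columns]
    if missing:
        raise GatingError(f"barcode markers missing from cell table: {missing}")
    t_leaves = set(config.t_state_leaves)
    is_t = cells["state"].isin(t_leaves).to_numpy()
    bits = cells.loc[:, list(BARCODE_MARKERS)].to_numpy().astype(bool)
    names = np.full(len(cells), None, dtype=object)
    if is_t.any():
        markers = np.array(BARCODE_MARKERS, dtype=object)
        sub = bits[is_t]
        names[is_t] = [
            "".join(f"{m}+" for m in markers[row]) or "NEG" for row in sub
        ]
    out = cells.copy()
    out["barcode"] = names
    return out
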