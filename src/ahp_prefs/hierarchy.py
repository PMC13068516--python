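"""Two-level criterion hierarchies and global-weight composition.

The survey's decision structure has a goal, five first-level endpoints
(mortality, myocardial infarction, stroke, heart failure, adverse events)
and four second-level adverse events (pain, dyspnea, cough, edema) under
the aggregated adverse-events criterion.  A child's global weight is its
local weight times its parent's global weight; leaves' global weights sum
to one.  The types are generic over any depth-2 hierarchy.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .core import PriorityVector

__all__ = [
    "LEVEL1_CRITERIA",
    "LEVEL2_CRITERIA",
    "EndpointHierarchy",
    "WeightedHierarchy",
    "Violation",
    "default_hierarchy",
    "load_hierarchy",
    "compose_global_weights",
    "validate_hierarchy",
]

LEVEL1_CRITERIA = (
    "mortality",
    "myocardial_infarction",
    "stroke",
    "heart_failure",
    "adverse_events",
)
LEVEL2_CRITERIA = ("pain", "dyspnea", "cough", "edema")


@dataclass(frozen=True)
class EndpointHierarchy:
    """A goal, its first-level criteria and optional children per criterion."""

    goal: str
    criteria: tuple[str, ...]
    children: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(
            self,
            "children",
            {p: tuple(c) for p, c in dict(self.children).items()},
        )
        all_ids = list(self.criteria)
        for parent, kids in self.children.items():
            if parent not in self.criteria:
                raise ValueError(f"children listed for unknown criterion "
                                 f"{parent!r}")
            if not kids:
                raise ValueError(f"{parent!r} has an empty child list")
            all_ids.extend(kids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("criterion identifiers must be unique across "
                             "the tree")

    @property
    def leaves(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.criteria:
            out.extend(self.children.get(c, (c,)))
        return tuple(out)


def default_hierarchy() -> EndpointHierarchy:
    """The bundled hypertension endpoint hierarchy."""
    with resources.files("ahp_prefs.data").joinpath("hierarchy.yaml").open() as fh:
        return _from_config(yaml.safe_load(fh))


def _from_config(cfg: Mapping) -> EndpointHierarchy:
    return EndpointHierarchy(
        goal=str(cfg["goal"]),
        criteria=tuple(cfg["criteria"]),
        children={p: tuple(c) for p, c in (cfg.get("children") or {}).items()},
    )


def load_hierarchy(path) -> EndpointHierarchy:
    """Load a hierarchy description from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "goal" not in cfg or "criteria" not in cfg:
        raise ValueError("hierarchy config needs 'goal' and 'criteria' keys")
    return _from_config(cfg)


@dataclass(frozen=True)
class WeightedHierarchy:
    """A hierarchy together with local and composed global weights."""

    hierarchy: EndpointHierarchy
    local: Mapping[str, float]   # per node, relative to its parent
    global_: Mapping[str, float]  # per node, relative to the goal

    def leaf_globals(self) -> PriorityVector:
        leaves = self.hierarchy.leaves
        return PriorityVector.from_raw(
            leaves, [self.global_[leaf] for leaf in leaves]
        )


@dataclass(frozen=True)
class Violation:
    """One hierarchy-invariant violation; ``severity`` is 'warning' for
    deviations explainable by 3-dp printed rounding, else 'error'."""

    kind: str
    message: str
    magnitude: float
    severity: str


def compose_global_weights(
    level1: PriorityVector,
    subcriteria_local: PriorityVector | Mapping[str, PriorityVector],
    hierarchy: EndpointHierarchy | None = None,
) -> WeightedHierarchy:
    """Compose local weights into global weights down the hierarchy.

    ``level1`` must cover the hierarchy's first-level criteria.  For each
    parent with children, a local :class:`PriorityVector` over exactly those
    children must be supplied; a bare vector is accepted when a single parent
    has children (the default hierarchy's adverse-events criterion).
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    if tuple(level1.criteria) != hierarchy.criteria:
        raise ValueError(
            f"level-1 vector covers {level1.criteria}, hierarchy expects "
            f"{hierarchy.criteria}"
        )
    if isinstance(subcriteria_local, PriorityVector):
        if len(hierarchy.children) != 1:
            raise ValueError(
                "a bare sub-criteria vector is ambiguous: hierarchy has "
                f"{len(hierarchy.children)} parents with children"
            )
        parent = next(iter(hierarchy.children))
        locals_map = {parent: subcriteria_local}
    else:
        locals_map = dict(subcriteria_local)
    if set(locals_map) != set(hierarchy.children):
        raise ValueError(
            f"local vectors supplied for {sorted(locals_map)}, hierarchy "
            f"parents with children are {sorted(hierarchy.children)}"
        )

    local: dict[str, float] = level1.as_dict()
    global_: dict[str, float] = level1.as_dict()
    for parent, vector in locals_map.items():
        if tuple(vector.criteria) != hierarchy.children[parent]:
            raise ValueError(
                f"local vector for {parent!r} covers {vector.criteria}, "
                f"expected {hierarchy.children[parent]}"
            )
        for child, w in vector.as_dict().items():
            local[child] = w
            global_[child] = w * global_[parent]
    return WeightedHierarchy(hierarchy, local, global_)


def validate_hierarchy(
    weighted: WeightedHierarchy,
    tolerance: float = 1e-9,
    warn_tolerance: float = 1e-2,
) -> list[Violation]:
    """Check leaf-global conservation and child-below-parent monotonicity.

    Returns an empty list iff both invariants hold at ``tolerance``.
    Deviations below ``warn_tolerance`` are reported with severity
    'warning' (consistent with weights printed at 3 decimal places); larger
    ones with severity 'error'.
    """
    violations: list[Violation] = []

    def _sev(mag: float) -> str:
        return "warning" if mag < warn_tolerance else "error"

    leaf_sum = sum(
        weighted.global_[leaf] for leaf in weighted.hierarchy.leaves
    )
    dev = abs(leaf_sum - 1.0)
    if dev > tolerance:
        violations.append(Violation(
            "leaf_sum",
            f"leaf global weights sum to {leaf_sum:.6f}, expected 1",
            dev,
            _sev(dev),
        ))
    for parent, kids in weighted.hierarchy.children.items():
        for child in kids:
            excess = weighted.global_[child] - weighted.global_[parent]
            if excess > tolerance:
                violations.append(Violation(
                    "child_exceeds_parent",
                    f"global weight of {child!r} "
                    f"({weighted.global_[child]:.6f}) exceeds its parent "
                    f"{parent!r} ({weighted.global_[parent]:.6f})",
                    excess,
                    _sev(excess),
                ))
    return violations
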