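"""Shared domain types for the regulatory-sign pipeline.

States are encoded as integers: +1 (upregulated), -1 (downregulated),
0 (undetermined).  Evidence tiers order the strength of a node's anchor:
qRTPCR-confirmed and microarray-reported states are *known* (weight 2),
inferred states are *predicted* (weight 1), and unanchored nodes carry no
evidence (weight 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

UP = 1
DOWN = -1
UNDETERMINED = 0

STATE_NAMES = {UP: "up", DOWN: "down", UNDETERMINED: "undetermined"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


class Tier(str, Enum):
    """Evidence tier of a node's misregulation state."""

    QRT_CONFIRMED = "qrt_confirmed"
    ARRAY_REPORTED = "array_reported"
    PREDICTED = "predicted"
    UNANCHORED = "unanchored"

    @property
    def weight(self) -> int:
        if self in (Tier.QRT_CONFIRMED, Tier.ARRAY_REPORTED):
            return 2
        if self is Tier.PREDICTED:
            return 1
        return 0

    @property
    def anchored(self) -> bool:
        """Anchored states are observed and never change during inference."""
        return self in (Tier.QRT_CONFIRMED, Tier.ARRAY_REPORTED)


@dataclass(frozen=True)
class RegEdge:
    """One signed, directed, provenance-tagged regulatory interaction.

    ``sign`` is +1 for activation (arrowhead) and -1 for repression (bar).
    ``directness`` distinguishes direct regulation (e.g. protein binding a
    promoter) from indirect regulation mediated by other genes; it carries no
    weight in scoring and is provenance metadata only.
    """

    source: str
    target: str
    sign: int
    directness: str = "direct"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop not allowed: {self.source}")
        if self.sign not in (UP, DOWN):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if self.directness not in ("direct", "indirect"):
            raise ValueError(f"directness must be direct/indirect, got {self.directness!r}")


@dataclass(frozen=True)
class NodeState:
    """A gene's misregulation state plus the evidence tier behind it."""

    gene: str
    state: int
    tier: Tier

    def __post_init__(self) -> None:
        if self.state not in (UP, DOWN, UNDETERMINED):
            raise ValueError(f"state must be +1/-1/0, got {self.state!r}")
        if not isinstance(self.tier, Tier):
            object.__setattr__(self, "tier", Tier(self.tier))

    @property
    def weight(self) -> int:
        if self.state == UNDETERMINED:
            return 0
        return self.tier.weight


@dataclass
class PredictionScore:
    """Hypothesis scores for one node: evidence points for up vs down.

    ``decision`` is the argmax of the two scores; a tie leaves the node
    undetermined.  ``contributions`` lists (edge, hypothesis, points) triples
    for audit.
    """

    gene: str
    score_up: int
    score_down: int
    decision: int = field(init=False)
    contributions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score_up > self.score_down:
            self.decision = UP
        elif self.score_down > self.score_up:
            self.decision = DOWN
        else:
            self.decision = UNDETERMINED


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene (or per-probe) fold change with raw and adjusted p-values.

    Fold changes follow the signed microarray convention: |fc| >= 1, with the
    sign carrying the direction (a 2-fold decrease is -2.0, never 0.5).
    """

    gene: str
    source: str
    fold_change: float
    p_raw: float
    p_adj: float
    probe: str | None = None

    SOURCES = ("array_P0", "array_P4", "qrtpcr")

    def __post_init__(self) -> None:
        if self.source not in self.SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {self.SOURCES}")
        for name, p in (("p_raw", self.p_raw), ("p_adj", self.p_adj)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} out of [0,1] for {self.gene}: {p}")
        if abs(self.fold_change) < 1.0:
            raise ValueError(
                f"signed fold change must satisfy |fc| >= 1, got {self.fold_change} for {self.gene}"
            )


@dataclass(frozen=True)
class TargetEvidence:
    """One line of evidence that a gene is a direct microRNA target."""

    gene: str
    category: str
    citation: str = ""

    CATEGORIES = (
        "literature_confirmed",
        "luciferase_confirmed",
        "upregulated_with_seed_match",
        "predicted_and_expressed",
    )

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown evidence category {self.category!r}")
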