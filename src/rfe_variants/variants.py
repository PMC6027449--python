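"""Decision variants: pick the final subset from an elimination trace.

Three rules are supported:

* **HA** — the subset with the highest recorded accuracy; accuracy ties go to
  the smaller subset, since the whole point of selection is compactness.
* **pct-HA** (90% HA by default) — the *smallest* subset whose accuracy
  reaches a fraction (default 0.90) of the highest accuracy.  Trading a
  little accuracy for a much smaller subset is the rationale.
* **PreNum** — the subset of a preset size, i.e. the top-``prenum`` features
  of the ranking the elimination order induces.

Thresholds are compared at full precision; reported values are rounded
half-up to two decimals, matching how such tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._utils import round_half_up
from .rfe import EliminationTrace


class VariantKind(str, Enum):
    HA = "ha"
    PCT_HA = "pct-ha"
    PRENUM = "prenum"


@dataclass(frozen=True)
class VariantSpec:
    """Which decision rule to apply, with its parameter."""

    kind: VariantKind
    pct: float = 0.90
    prenum: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", VariantKind(self.kind))
        if not 0.0 < self.pct <= 1.0:
            raise ValueError("pct must lie in (0, 1]")
        if self.kind is VariantKind.PRENUM:
            if self.prenum is None or self.prenum < 1:
                raise ValueError("prenum must be a positive integer")

    def describe(self) -> str:
        if self.kind is VariantKind.HA:
            return "HA"
        if self.kind is VariantKind.PCT_HA:
            return f"{round_half_up(100 * self.pct, 0):.0f}% HA"
        return f"PreNum ({self.prenum})"


@dataclass(frozen=True)
class VariantDecision:
    """One selected subset, with the rule that produced it."""

    variant: VariantSpec
    subset: tuple[str, ...]
    achieved_accuracy: float
    trace_index: int
    threshold: float | None = None  # accuracy cutoff used by pct-HA

    @property
    def threshold_reported(self) -> float | None:
        return None if self.threshold is None else round_half_up(self.threshold)


def _require_nonempty(trace: EliminationTrace) -> None:
    if len(trace) == 0:
        raise ValueError("elimination trace is empty")


def select_ha(trace: EliminationTrace) -> VariantDecision:
    """Highest-accuracy step; ties resolved toward the smaller subset."""
    _require_nonempty(trace)
    best = max(range(len(trace)),
               key=lambda i: (trace[i].accuracy, -len(trace[i].subset)))
    return VariantDecision(
        variant=VariantSpec(kind=VariantKind.HA),
        subset=trace[best].subset,
        achieved_accuracy=trace[best].accuracy,
        trace_index=best,
    )


def select_pct_ha(trace: EliminationTrace, pct: float = 0.90) -> VariantDecision:
    """Smallest subset whose accuracy reaches ``pct`` of the trace maximum.

    A step exactly at the threshold qualifies (>=, not >).
    """
    _require_nonempty(trace)
    if not 0.0 < pct <= 1.0:
        raise ValueError("pct must lie in (0, 1]")
    threshold = pct * max(s.accuracy for s in trace)
    qualifying = [i for i in range(len(trace)) if trace[i].accuracy >= threshold]
    best = min(qualifying, key=lambda i: (len(trace[i].subset), -trace[i].accuracy))
    return VariantDecision(
        variant=VariantSpec(kind=VariantKind.PCT_HA, pct=pct),
        subset=trace[best].subset,
        achieved_accuracy=trace[best].accuracy,
        trace_index=best,
        threshold=threshold,
    )


def select_prenum(trace: EliminationTrace, prenum: int) -> VariantDecision:
    """The trace step whose subset has exactly ``prenum`` features."""
    _require_nonempty(trace)
    if prenum < 1:
        raise ValueError("prenum must be a positive integer")
    sizes = trace.subset_sizes
    for i, size in enumerate(sizes):
        if size == prenum:
            return VariantDecision(
                variant=VariantSpec(kind=VariantKind.PRENUM, prenum=prenum),
                subset=trace[i].subset,
                achieved_accuracy=trace[i].accuracy,
                trace_index=i,
            )
    raise ValueError(
        f"no trace step has {prenum} features; available sizes: {sorted(sizes)}")


def select(trace: EliminationTrace, spec: VariantSpec) -> VariantDecision:
    """Dispatch to the selector ``spec`` names."""
    if spec.kind is VariantKind.HA:
        return select_ha(trace)
    if spec.kind is VariantKind.PCT_HA:
        return select_pct_ha(trace, spec.pct)
    return select_prenum(trace, spec.prenum)
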