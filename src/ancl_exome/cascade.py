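"""Multi-stage rare-variant filtering cascade with attrition accounting.

The cascade mirrors the study design for a fully penetrant dominant trait in
a small pedigree: per-sample quality filtering, removal of known common
variants (zygosity-specific frequency thresholds), restriction to functional
classes, intersection across affected individuals, and subtraction of calls
carried by the unaffected control and by an external exome panel.

Removal thresholds are strict inequalities (frequency *greater than* the
cutoff removes); a call absent from every database is novel and always
survives the frequency filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .variant_io import SampleExome, VariantKey

logger = logging.getLogger(__name__)

DEFAULT_FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "coding-indel", "frameshift"}
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the filtering cascade.

    ``het_freq_max``/``hom_freq_max`` are the database-frequency cutoffs above
    which a known het/hom call is discarded (5% and 30%); ``min_depth`` and
    ``min_qual`` are the per-call floors of the quality stage.
    """

    het_freq_max: float = 0.05
    hom_freq_max: float = 0.30
    min_depth: int = 5
    min_qual: float = 30.0
    functional_classes: frozenset[str] = DEFAULT_FUNCTIONAL_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_freq_max <= self.hom_freq_max <= 1.0:
            raise ValueError(
                "require 0 <= het_freq_max <= hom_freq_max <= 1, got "
                f"{self.het_freq_max}, {self.hom_freq_max}"
            )
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")


@dataclass
class FilterTrace:
    """Ordered per-stage surviving counts; enforces cascade monotonicity."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, surviving: int) -> None:
        if surviving < 0:
            raise ValueError("surviving count cannot be negative")
        if self.stages and surviving > self.stages[-1][1]:
            raise ValueError(
                f"stage {name!r}: surviving count {surviving} exceeds previous "
                f"stage {self.stages[-1][0]!r} ({self.stages[-1][1]})"
            )
        self.stages.append((name, surviving))
        logger.info("cascade stage %-28s surviving=%d", name, surviving)

    def counts(self) -> list[int]:
        return [n for _, n in self.stages]

    def percent_remaining(self, denominator: Optional[int] = None) -> list[float]:
        denom = denominator if denominator is not None else (
            self.stages[0][1] if self.stages else 0
        )
        return attrition_table(self, denom)


def filter_quality(
    exome: SampleExome, cfg: CascadeConfig, trace: Optional[FilterTrace] = None
) -> SampleExome:
    """Keep calls with depth >= min_depth and qual >= min_qual.

    Calls with missing depth or quality are kept (the filter acts on available
    metrics only) and a warning is logged.
    """
    kept = []
    n_missing = 0
    for call in exome.calls:
        if call.depth is None or call.qual is None:
            n_missing += 1
            kept.append(call)
        elif call.depth >= cfg.min_depth and call.qual >= cfg.min_qual:
            kept.append(call)
    if n_missing:
        logger.warning(
            "%s: %d call(s) missing depth/qual kept unfiltered",
            exome.sample_id,
            n_missing,
        )
    out = exome.replaced(kept)
    if trace is not None:
        trace.add(f"quality[{exome.sample_id}]", len(out))
    return out


def filter_known_common(
    exome: SampleExome,
    db: Mapping[VariantKey, float],
    cfg: CascadeConfig,
    trace: Optional[FilterTrace] = None,
) -> SampleExome:
    """Remove calls known to the database at frequency > the zygosity cutoff.

    ``db`` maps variant keys to population frequency; calls absent from the
    database (novel) always survive.  Per-call ``db_flags`` frequencies are
    used when the key is not in ``db``.
    """
    kept = []
    for call in exome.calls:
        freq = db.get(call.key)
        if freq is None:
            freq = call.max_db_freq()
        if freq is None:
            kept.append(call)  # novel
            continue
        cutoff = cfg.hom_freq_max if call.zygosity == "hom" else cfg.het_freq_max
        if freq > cutoff:
            continue
        kept.append(call)
    out = exome.replaced(kept)
    if trace is not None:
        trace.add(f"known_common[{exome.sample_id}]", len(out))
    return out


def filter_functional(
    exome: SampleExome, cfg: CascadeConfig, trace: Optional[FilterTrace] = None
) -> SampleExome:
    """Keep only the configured functional classes (missense/nonsense/splice/indel)."""
    kept = [c for c in exome.calls if c.var_class in cfg.functional_classes]
    out = exome.replaced(kept)
    if trace is not None:
        trace.add(f"functional[{exome.sample_id}]", len(out))
    return out


def shared_in_affecteds(
    exomes: Sequence[SampleExome], trace: Optional[FilterTrace] = None
) -> set[VariantKey]:
    """Intersection of variant keys across all affected exomes.

    Variant identity is (chrom, pos, ref, alt); zygosity is ignored so that a
    het call in one sample matches a hom call in another.
    """
    if len(exomes) < 2:
        raise ValueError("need at least two affected exomes to intersect")
    shared = set(exomes[0].key_set())
    for ex in exomes[1:]:
        shared &= ex.key_set()
    if trace is not None:
        trace.add("shared_in_affecteds", len(shared))
    return shared


def subtract_samples(
    shared: set[VariantKey],
    controls: Iterable[SampleExome],
    trace: Optional[FilterTrace] = None,
    stage_name: str = "subtract_controls",
) -> set[VariantKey]:
    """Remove every key carried by any control/panel sample."""
    result = set(shared)
    for ctrl in controls:
        result -= ctrl.key_set()
    if trace is not None:
        trace.add(stage_name, len(result))
    return result


def attrition_table(trace: FilterTrace, denominator: int) -> list[float]:
    """Raw percent-remaining series: 100 * surviving / denominator per stage."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return [100.0 * n / denominator for _, n in trace.stages]


def format_percent(value: float) -> str:
    """Render a percent-remaining cell at the published mixed precision.

    Values of at least 1% are shown with one decimal (trailing ``.0``
    dropped, so the 100% row prints as ``100``); values below 1% with two
    decimals.  Note: one published cell (19/38,179 printed as 0.04) is not
    reproduced by this rule, which yields the standard rounding 0.05.
    """
    if value >= 1.0:
        text = f"{value:.1f}"
        return text[:-2] if text.endswith(".0") else text
    return f"{value:.2f}"


def validation_fdr(n_tested: int, n_failed: int) -> float:
    """Fraction of genotype-validated candidates that failed validation."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_failed <= n_tested:
        raise ValueError("require 0 <= n_failed <= n_tested")
    return n_failed / n_tested


def run_cascade(
    affecteds: Sequence[SampleExome],
    controls: Sequence[SampleExome],
    panel: Sequence[SampleExome],
    db: Mapping[VariantKey, float],
    cfg: Optional[CascadeConfig] = None,
) -> tuple[set[VariantKey], FilterTrace]:
    """Run the full cascade and return (surviving keys, per-stage trace).

    The trace records set-level counts: total affected-1 calls, then the
    survivors of each per-sample filter on the first affected (the published
    attrition table is per-sample up to the intersection), then the
    intersection and subtraction stages.
    """
    cfg = cfg or CascadeConfig()
    trace = FilterTrace()
    trace.add("total", len(affecteds[0]))

    filtered: list[SampleExome] = []
    for i, ex in enumerate(affecteds):
        t = trace if i == 0 else None
        ex = filter_quality(ex, cfg, t)
        ex = filter_known_common(ex, db, cfg, t)
        ex = filter_functional(ex, cfg, t)
        filtered.append(ex)
    shared = shared_in_affecteds(filtered, trace)
    shared = subtract_samples(shared, controls, trace, "subtract_control")
    shared = subtract_samples(shared, panel, trace, "subtract_panel")
    return shared, trace
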