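"""Hypergeometric gene-set over-representation test.

Given k genes drawn as a sample (e.g. genes elevated in high-NP
neurons) from a universe containing m population successes (e.g. genes
decreased in AD) and n failures, the upper-tail probability of the
observed overlap x is computed from the hypergeometric distribution in
log space, so universes of ~20,000 genes pose no overflow risk.

Two tail conventions are exposed: the default P(X >= x) counts results
as extreme as observed; P(X > x) reproduces an upper-tail CDF call
that excludes the quantile.  For any strongly enriched overlap the two
differ negligibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneList, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class OverlapTestInput:
    """x: overlap; m: population successes; n: population failures; k: sample size."""

    x: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        for name in ("x", "m", "n", "k"):
            value = getattr(self, name)
            if not float(value).is_integer() or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
            setattr(self, name, int(value))
        if self.x > min(self.m, self.k):
            raise ValidationError(f"overlap x={self.x} exceeds min(m={self.m}, k={self.k})")
        if self.k > self.m + self.n:
            raise ValidationError(f"sample size k={self.k} exceeds universe m+n={self.m + self.n}")


@dataclass
class OverlapTestResult:
    input: OverlapTestInput
    p_value: float
    expected_overlap: float
    fold_enrichment: float


def hypergeom_overlap_test(inp: OverlapTestInput, tail: str = "ge") -> OverlapTestResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``tail='ge'`` gives P(X >= x) (default), ``tail='gt'`` gives P(X > x).
    """
    dist = stats.hypergeom(inp.m + inp.n, inp.m, inp.k)
    if tail == "ge":
        log_p = dist.logsf(inp.x - 1)
    elif tail == "gt":
        log_p = dist.logsf(inp.x)
    else:
        raise ValidationError(f"tail must be 'ge' or 'gt', got {tail!r}")
    p = float(np.exp(log_p))
    p = min(1.0, max(0.0, p))
    expected = inp.k * inp.m / (inp.m + inp.n) if (inp.m + inp.n) else 0.0
    fold = inp.x / expected if expected > 0 else float("nan")
    logger.info("hypergeom_overlap_test: x=%d m=%d n=%d k=%d tail=%s p=%.3g",
                inp.x, inp.m, inp.n, inp.k, tail, p)
    return OverlapTestResult(inp, p, expected, fold)


def build_overlap_input(set_sample, set_population_success, universe) -> OverlapTestInput:
    """Assemble the x/m/n/k quadruple from gene-symbol collections.

    ``universe`` must contain both sets; members outside it are an
    error listing the offenders.
    """
    def _norm(collection):
        symbols = collection.symbols if isinstance(collection, GeneList) else collection
        return {normalize_symbol(s) for s in symbols}

    sample = _norm(set_sample)
    success = _norm(set_population_success)
    uni = _norm(universe)
    offenders = sorted((sample | success) - uni)
    if offenders:
        raise ValidationError(f"set members outside the universe: {offenders[:10]}")
    return OverlapTestInput(
        x=len(sample & success), m=len(success), n=len(uni) - len(success), k=len(sample)
    )
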