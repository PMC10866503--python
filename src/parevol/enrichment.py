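"""Permutation tests of gene-set overlap enrichment.

The null model: draw two gene sets of the observed sizes uniformly without
replacement from the background universe, independently, and record their
intersection size; repeat (default 10,000 iterations). The tail p-value gets
an add-one correction, p = (#{null >= observed} + 1) / (iterations + 1), so
it is never exactly zero — an observed overlap outside the whole null
distribution is reported at the floor value with ``p_is_floor`` set (the
"p = ~0" convention). Fold enrichment is the observed overlap divided by the
null mean.

The analytic counterpart (:func:`parevol.stats.hypergeom_overlap_moments`)
provides exact moments for validating the Monte-Carlo null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import chisq_independence

DEFAULT_ITERATIONS = 10_000


@dataclass(frozen=True)
class OverlapTest:
    """Configuration of one permutation overlap test.

    Either pass explicit sets ``set_a``/``set_b`` (sizes and observed overlap
    are derived) or the summary counts directly.
    """

    background_size: int
    size_a: int
    size_b: int
    observed: int
    iterations: int = DEFAULT_ITERATIONS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.background_size <= 0:
            raise ValueError("background must be nonempty")
        if not (0 <= self.size_a <= self.background_size):
            raise ValueError("size_a outside [0, background]")
        if not (0 <= self.size_b <= self.background_size):
            raise ValueError("size_b outside [0, background]")
        if self.observed > min(self.size_a, self.size_b):
            raise ValueError("observed overlap exceeds the smaller set")

    @classmethod
    def from_sets(cls, background, set_a, set_b, iterations=DEFAULT_ITERATIONS,
                  seed=None) -> "OverlapTest":
        bg = set(background)
        a, b = set(set_a), set(set_b)
        for name, s in (("set_a", a), ("set_b", b)):
            if not s <= bg:
                raise ValueError(f"{name} is not a subset of the background")
        return cls(len(bg), len(a), len(b), len(a & b), iterations, seed)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap against its permutation null."""

    observed: int
    null_mean: float
    null_quantiles: dict = field(repr=False)
    p_value: float
    p_is_floor: bool
    fold: float
    alternative: str
    iterations: int

    def as_row(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "fold": self.fold,
            "p": self.p_value,
            "p_is_floor": self.p_is_floor,
            "alternative": self.alternative,
            "iterations": self.iterations,
        }


def _simulate_null(test: OverlapTest, rng: np.random.Generator) -> np.ndarray:
    """Intersection sizes of two independent uniform subsets, per iteration."""
    n, m1, m2 = test.background_size, test.size_a, test.size_b
    sims = np.empty(test.iterations, dtype=np.int64)
    member_b = np.zeros(n, dtype=bool)
    for i in range(test.iterations):
        a_idx = rng.choice(n, size=m1, replace=False)
        b_idx = rng.choice(n, size=m2, replace=False)
        member_b[b_idx] = True
        sims[i] = int(member_b[a_idx].sum())
        member_b[b_idx] = False
    return sims


def permutation_overlap(
    test: OverlapTest, alternative: str = "greater",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation test of an observed overlap against the random-sets null.

    ``alternative`` is 'greater' (enrichment, default), 'less'
    (under-enrichment) or 'two_sided'.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if rng is None:
        rng = np.random.default_rng(test.seed)
    sims = _simulate_null(test, rng)
    null_mean = float(sims.mean())
    ge = int(np.sum(sims >= test.observed))
    le = int(np.sum(sims <= test.observed))
    m = test.iterations
    if alternative == "greater":
        extreme = ge
    elif alternative == "less":
        extreme = le
    else:
        extreme = min(2 * min(ge, le), m)
    p = (extreme + 1) / (m + 1)
    fold = test.observed / null_mean if null_mean > 0 else float("inf")
    qs = {q: float(np.quantile(sims, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return EnrichmentResult(
        observed=test.observed,
        null_mean=null_mean,
        null_quantiles=qs,
        p_value=float(p),
        p_is_floor=(extreme == 0),
        fold=float(fold),
        alternative=alternative,
        iterations=m,
    )


def degs_in_set_enrichment(
    gene_set, deg_set, background, iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None, alternative: str = "greater",
) -> EnrichmentResult:
    """Enrichment of DEGs within a gene set against random same-size draws.

    Each null iteration draws ``len(gene_set)`` genes from the background and
    counts how many belong to ``deg_set``; observed is the true overlap.
    Supports ``alternative='less'`` for under-enrichment (e.g. broadly
    expressed genes depleted of DEGs).
    """
    bg = list(dict.fromkeys(background))
    gs = set(gene_set)
    dg = set(deg_set)
    if not gs <= set(bg):
        raise ValueError("gene_set is not a subset of the background")
    rng = np.random.default_rng(seed)
    is_deg = np.array([g in dg for g in bg])
    n, k = len(bg), len(gs)
    sims = np.empty(iterations, dtype=np.int64)
    for i in range(iterations):
        sims[i] = int(is_deg[rng.choice(n, size=k, replace=False)].sum())
    observed = len(gs & dg)
    null_mean = float(sims.mean())
    ge = int(np.sum(sims >= observed))
    le = int(np.sum(sims <= observed))
    if alternative == "greater":
        extreme = ge
    elif alternative == "less":
        extreme = le
    else:
        extreme = min(2 * min(ge, le), iterations)
    p = (extreme + 1) / (iterations + 1)
    fold = observed / null_mean if null_mean > 0 else float("inf")
    qs = {q: float(np.quantile(sims, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return EnrichmentResult(observed, null_mean, qs, float(p), extreme == 0,
                            float(fold), alternative, iterations)


def parallelism_suite(tests: dict, seed: int | None = None) -> pd.DataFrame:
    """Run a named battery of overlap tests; one result row per test.

    ``tests`` maps test name to a dict with keys ``background``, ``set_a``,
    ``set_b`` and optionally ``iterations`` and ``alternative``. Each named
    set must be a subset of its background (misconfiguration raises an error
    naming the offending set).
    """
    rows = {}
    ss = np.random.SeedSequence(seed)
    for name, child in zip(tests, ss.spawn(len(tests))):
        cfg = tests[name]
        try:
            ot = OverlapTest.from_sets(
                cfg["background"], cfg["set_a"], cfg["set_b"],
                iterations=cfg.get("iterations", DEFAULT_ITERATIONS),
            )
        except ValueError as exc:
            raise ValueError(f"test {name!r}: {exc}") from exc
        res = permutation_overlap(
            ot, alternative=cfg.get("alternative", "greater"),
            rng=np.random.default_rng(child),
        )
        rows[name] = res.as_row()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "test_name"
    return out


def shared_proportion_chisq(
    shared_a: int, total_a: int, shared_b: int, total_b: int,
    continuity: bool = False,
):
    """Chi-square comparison of shared proportions between two gene classes.

    Builds the pooled 2x2 table (shared / not-shared) x (class A / class B)
    — e.g. cis-regulated vs trans-regulated genes — and tests independence.
    """
    table = [
        [shared_a, total_a - shared_a],
        [shared_b, total_b - shared_b],
    ]
    return chisq_independence(table, continuity=continuity)
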