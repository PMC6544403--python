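"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use the dumbest possible algorithm (per-base sets,
per-fragment loops, exhaustive enumeration) so they share no code path with
the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from epiconcord.annotation import GeneAnnotation, GeneModel


# ---------------------------------------------------------------- oracles


def brute_window_counts(fragments, window_size, chrom_sizes):
    """Per-fragment tally into windows by midpoint; dict chrom -> list."""
    out = {
        chrom: [0] * math.ceil(size / window_size) for chrom, size in chrom_sizes.items()
    }
    for chrom, start, end in fragments:
        out[chrom][((start + end) // 2) // window_size] += 1
    return out


def brute_cluster(mask, gap):
    """Linear scan over a boolean list; returns (first, last) window indices."""
    runs = []
    current = None
    gap_run = 0
    for i, m in enumerate(mask):
        if m:
            if current is None:
                current = [i, i]
            elif gap_run <= gap:
                current[1] = i
            else:
                runs.append(tuple(current))
                current = [i, i]
            gap_run = 0
        else:
            gap_run += 1
    if current is not None:
        runs.append(tuple(current))
    return runs


def base_level_region(gene: GeneModel, rule) -> set[int]:
    """Target region as an explicit set of base positions (>= 0)."""
    bases: set[int] = set()
    if rule.promoter_upstream_bp is not None:
        up, down = rule.promoter_upstream_bp, rule.promoter_downstream_bp
        if gene.strand == "+":
            lo, hi = gene.tss - up, gene.tss + down
        else:
            lo, hi = gene.tss - down, gene.tss + up
        bases |= set(range(max(0, lo), hi + 1))
    if rule.include_gene_body:
        bases |= set(range(gene.start, gene.end))
    if rule.exclude_gene_body:
        bases -= set(range(gene.start, gene.end))
    return bases


def intervals_to_bases(intervals) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out |= set(range(s, e))
    return out


def hypergeom_upper_tail(k, M, K, n) -> float:
    """P(X >= k) drawing n from M with K successes, by exhaustive summation."""
    denom = math.comb(M, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(M - K, n - i)
    return total / denom


def binom_two_sided(k, n, p) -> float:
    """Two-sided exact binomial p by enumerating outcomes no more likely
    than the observed one (the standard 'minlike' definition)."""
    def pmf(i):
        return math.comb(n, i) * p**i * (1 - p) ** (n - i)

    obs = pmf(k)
    return min(1.0, sum(pmf(i) for i in range(n + 1) if pmf(i) <= obs * (1 + 1e-10)))


def poisson_upper_tail(k, lam) -> float:
    """P(X >= k) by direct series summation of the complement."""
    return 1.0 - sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(
        [
            GeneModel("gA", "chr1", 10_000, 20_000, "+"),
            GeneModel("gB", "chr1", 40_000, 45_000, "-"),
            GeneModel("gC", "chr2", 5_000, 9_000, "+"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
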