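"""Genotype-expression association, knockout DE screen, gene-set tests.

The eQTL statistic is Spearman's rank correlation of genotype dosage
against log2 expression, reported with the nominal t-approximation
P-value; cis testing restricts genes to a +/- 1 Mb window around the SNP.
The knockout screen computes log2 fold-changes of group-mean expression
with a one-way ANOVA P-value and a linear-scale fold-change cut-off
(|log2 FC| >= log2 1.5 by default). Over-representation of a gene set
among hits uses the hypergeometric upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, GeneModel, SNPRecord

__all__ = [
    "EqtlResult",
    "spearman_eqtl",
    "cis_genes",
    "DeResult",
    "differential_expression",
    "overrepresentation_test",
]


@dataclass(frozen=True)
class EqtlResult:
    snp_id: str
    gene_id: str
    rho: float
    nominal_p: float
    n_samples: int


def spearman_eqtl(genotypes, expression, snp_id: str = "",
                  gene_id: str = "") -> EqtlResult:
    """Spearman rank correlation of genotype dosage vs expression.

    Genotypes are allele counts {0, 1, 2}; ties are handled by mid-ranks.
    Raises on degenerate input (constant genotype or expression, or fewer
    than 3 samples).
    """
    g = np.asarray(genotypes, dtype=float)
    e = np.asarray(expression, dtype=float)
    if g.size != e.size:
        raise ValueError("genotype and expression lengths differ")
    if g.size < 3:
        raise ValueError("spearman_eqtl: need >= 3 samples")
    if np.unique(g).size < 2 or np.unique(e).size < 2:
        raise ValueError("spearman_eqtl: degenerate (constant) input")
    rho, p = stats.spearmanr(g, e)
    return EqtlResult(snp_id, gene_id, float(rho), float(p), int(g.size))


def cis_genes(snp: SNPRecord, genes: Sequence[GeneModel],
              window_bp: int = 1_000_000) -> list[GeneModel]:
    """Genes whose TSS lies within ``window_bp`` of the SNP (same chromosome)."""
    return [
        g
        for g in genes
        if g.interval.chrom == snp.chrom and abs(g.tss - snp.pos) <= window_bp
    ]


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    log2_fc: float
    anova_p: float
    passes_fc: bool


def differential_expression(expr: ExpressionMatrix, group_a: str, group_b: str,
                            fc_min: float = 1.5,
                            fc_on_log2_scale: bool = False) -> list[DeResult]:
    """Per-gene log2 fold-change (group_a - group_b) with one-way ANOVA P.

    ``fc_min`` is a linear-scale fold-change by default: a gene passes iff
    ``|log2_fc| >= log2(fc_min)``. Set ``fc_on_log2_scale`` to require
    ``|log2_fc| >= fc_min`` instead. Each group needs >= 2 samples.
    """
    samples_a = expr.samples_in_group(group_a)
    samples_b = expr.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("differential_expression: each group needs >= 2 samples")
    threshold = fc_min if fc_on_log2_scale else math.log2(fc_min)
    va = expr.values[samples_a].to_numpy()
    vb = expr.values[samples_b].to_numpy()
    log2_fc = va.mean(axis=1) - vb.mean(axis=1)
    out = []
    for i, gene_id in enumerate(expr.values.index):
        if np.ptp(va[i]) == 0 and np.ptp(vb[i]) == 0:
            p = 1.0 if va[i, 0] == vb[i, 0] else 0.0
        else:
            _, p = stats.f_oneway(va[i], vb[i])
        fc = float(log2_fc[i])
        out.append(DeResult(str(gene_id), fc, float(p), abs(fc) >= threshold))
    return out


def overrepresentation_test(hit_genes, gene_set, universe) -> tuple[int, float]:
    """Hypergeometric over-representation of ``gene_set`` among ``hit_genes``.

    Returns ``(k, P[X >= k])`` for X ~ Hypergeom(|universe|, |gene_set|,
    |hit_genes|), where k is the observed overlap. Hits and set must be
    subsets of the universe.
    """
    universe = set(universe)
    hits = set(hit_genes)
    gset = set(gene_set)
    if not universe:
        raise ValueError("overrepresentation_test: empty universe")
    if not hits <= universe or not gset <= universe:
        raise ValueError("hit genes and gene set must be subsets of the universe")
    k = len(hits & gset)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(gset), len(hits)))
    return k, min(1.0, p)
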